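import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from metamine.corpus_io import parse_medline
from metamine.gene_ner import load_lexicon, mine_corpus
from metamine.synthetic_data import CorpusSpec, generate_corpus, generate_lexicon


@pytest.fixture(scope="session")
def demo_bundle():
    """One synthetic corpus with its lexicon, mentions and ground truth."""
    spec = CorpusSpec(seed=1)
    medline, truth = generate_corpus(spec)
    corpus = parse_medline(medline, label="synthetic")
    lexicon = load_lexicon(generate_lexicon(spec.n_genes, spec.aliases_per_gene, spec.seed))
    mentions = mine_corpus(corpus, lexicon)
    return {
        "spec": spec,
        "medline": medline,
        "truth": truth,
        "corpus": corpus,
        "lexicon": lexicon,
        "mentions": mentions,
    }


@pytest.fixture()
def tiny_lexicon():
    """Hand-written lexicon with the alias quirks the matcher must handle."""
    tsv = (
        "symbol\tgene_id\tdescription\taliases\n"
        "CDH1\t999\tcadherin 1\tE-cadherin|ECAD\n"
        "PTK2\t5747\tprotein tyrosine kinase 2\tFAK\n"
        "BSG\t682\tbasigin\tCD147\n"
        "MMP2\t4313\tmatrix metallopeptidase 2\t\n"
        "MMP9\t4318\tmatrix metallopeptidase 9\t\n"
        "MET\t4233\tMET receptor tyrosine kinase\tc-Met\n"
        "VEGFA\t7422\tvascular endothelial growth factor A\tVEGF-A\n"
    )
    return load_lexicon(tsv)
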