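"""Sentence-level gene-phenotype co-occurrence counting and export."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from metamine.cooccurrence import (
    CooccurrenceMatrix,
    FOUR_PHENOTYPES,
    PhenotypeLexicon,
    count_cooccurrence,
    export_bipartite_gexf,
    multi_phenotype_genes,
    phenotype_totals,
    top_gene_per_phenotype,
)
from metamine.corpus_io import parse_medline
from metamine.gene_ner import mine_corpus
from metamine.synthetic_data import CorpusSpec, generate_corpus, generate_lexicon
from metamine.gene_ner import load_lexicon


def _matrix(data, genes, phenotypes):
    return CooccurrenceMatrix(
        counts=pd.DataFrame(data, index=genes, columns=phenotypes, dtype=int)
    )


class TestCounting:
    def test_repetition_counts_once_per_sentence(self, tiny_lexicon):
        corpus = parse_medline(
            "PMID- 1\nAB  - VEGFA and VEGFA induce angiogenesis and angiogenesis.\n"
        )
        matrix = count_cooccurrence(corpus, mine_corpus(corpus, tiny_lexicon))
        assert int(matrix.counts.at["VEGFA", "angiogenesis"]) == 1

    def test_gene_without_phenotype_contributes_zero(self, tiny_lexicon):
        corpus = parse_medline("PMID- 1\nAB  - VEGFA was overexpressed in tumors.\n")
        matrix = count_cooccurrence(corpus, mine_corpus(corpus, tiny_lexicon))
        assert matrix.counts.loc["VEGFA"].sum() == 0

    def test_phenotype_matching_is_whole_word(self, tiny_lexicon):
        corpus = parse_medline("PMID- 1\nAB  - VEGFA marks invasive phenotypes.\n")
        matrix = count_cooccurrence(corpus, mine_corpus(corpus, tiny_lexicon))
        assert matrix.counts.loc["VEGFA"].sum() == 0  # 'invasive' != 'invasion'

    def test_phenotype_matching_is_case_insensitive(self, tiny_lexicon):
        corpus = parse_medline("PMID- 1\nAB  - VEGFA drives Angiogenesis strongly.\n")
        matrix = count_cooccurrence(corpus, mine_corpus(corpus, tiny_lexicon))
        assert int(matrix.counts.at["VEGFA", "angiogenesis"]) == 1

    def test_entry_bounded_by_sentence_support(self, demo_bundle):
        corpus, mentions = demo_bundle["corpus"], demo_bundle["mentions"]
        matrix = count_cooccurrence(corpus, mentions)
        lexicon = PhenotypeLexicon.default()
        gene_support, pheno_support = {}, {}
        seen = set()
        for m in mentions:
            key = (m.pmid, m.sentence_index, m.canonical_symbol)
            if key not in seen:
                seen.add(key)
                gene_support[m.canonical_symbol] = gene_support.get(m.canonical_symbol, 0) + 1
        for record in corpus:
            for sentence in record.sentences:
                for label in lexicon.detect(sentence):
                    pheno_support[label] = pheno_support.get(label, 0) + 1
        for gene in matrix.genes:
            for phenotype in matrix.phenotypes:
                assert matrix.counts.at[gene, phenotype] <= min(
                    gene_support.get(gene, 0), pheno_support.get(phenotype, 0)
                )

    def test_matches_brute_force_oracle_on_small_corpora(self):
        # nested loops over sentences with set semantics, independent of
        # the mention/matrix code path
        rng = np.random.default_rng(5)
        lexicon = load_lexicon(generate_lexicon(5, 1))
        plex = PhenotypeLexicon.default()
        for _ in range(100):
            blocks, expected = [], {}
            for pmid in range(rng.integers(1, 6)):
                sentences = []
                for _ in range(rng.integers(1, 6)):
                    genes = [f"GENE{i+1}" for i in range(5) if rng.random() < 0.4]
                    phenos = [p for p in plex.labels if rng.random() < 0.3]
                    words = genes + phenos or ["nothing"]
                    sentences.append("Observed " + " and ".join(words) + " here.")
                    for g in set(genes):
                        for p in set(phenos):
                            expected[(g, p)] = expected.get((g, p), 0) + 1
                blocks.append(f"PMID- {pmid+1}\nAB  - {' '.join(sentences)}\n")
            corpus = parse_medline("\n".join(blocks))
            matrix = count_cooccurrence(corpus, mine_corpus(corpus, lexicon), plex)
            for (g, p), count in expected.items():
                assert int(matrix.counts.at[g, p]) == count
            assert int(matrix.counts.to_numpy().sum()) == sum(expected.values())


class TestSummaries:
    def test_phenotype_totals_are_column_sums(self):
        matrix = _matrix([[5, 0], [2, 3]], ["A", "B"], ["invasion", "adhesion"])
        assert phenotype_totals(matrix) == {"invasion": 7, "adhesion": 3}
        zero = _matrix([[0]], ["A"], ["invasion"])
        assert phenotype_totals(zero) == {"invasion": 0}

    def test_totals_match_independent_summation(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 9, size=(6, 4))
        matrix = _matrix(data, [f"G{i}" for i in range(6)], list(FOUR_PHENOTYPES))
        totals = phenotype_totals(matrix)
        for j, label in enumerate(FOUR_PHENOTYPES):
            assert totals[label] == sum(int(data[i, j]) for i in range(6))

    def test_top_gene_per_phenotype(self):
        matrix = _matrix([[64, 3], [12, 3], [0, 0]], ["PTK2", "CDH1", "ZZZ"],
                         ["adhesion", "migration"])
        top = top_gene_per_phenotype(matrix)
        assert top["adhesion"] == ("PTK2", 64)
        assert top["migration"] == ("CDH1", 3)  # tie with PTK2: lexicographic

    def test_zero_column_is_absent(self):
        matrix = _matrix([[0, 1]], ["A"], ["adhesion", "invasion"])
        assert "adhesion" not in top_gene_per_phenotype(matrix)


class TestMultiPhenotypeGenes:
    def test_threshold_rule(self):
        matrix = _matrix(
            [[10, 8, 3, 0], [10, 0, 0, 0]],
            ["KEEP", "DROP"],
            list(FOUR_PHENOTYPES),
        )
        assert multi_phenotype_genes(matrix) == {"KEEP"}

    def test_identity_limit(self):
        matrix = _matrix([[1, 0], [0, 0]], ["A", "B"], ["invasion", "adhesion"])
        assert multi_phenotype_genes(matrix, min_phenotypes=1, min_freq=0) == {"A", "B"}
        assert multi_phenotype_genes(matrix, min_phenotypes=1, min_freq=1) == {"A"}

    @given(
        st.integers(0, 10), st.integers(1, 4), st.integers(0, 10), st.integers(1, 4)
    )
    def test_monotone_in_both_thresholds(self, f1, k1, f2, k2):
        rng = np.random.default_rng(17)
        matrix = _matrix(
            rng.integers(0, 12, size=(8, 4)),
            [f"G{i}" for i in range(8)],
            list(FOUR_PHENOTYPES),
        )
        lo = multi_phenotype_genes(matrix, min(k1, k2), min(f1, f2))
        hi = multi_phenotype_genes(matrix, max(k1, k2), max(f1, f2))
        assert hi <= lo


class TestGexfExport:
    def test_bipartite_shape_and_roundtrip(self, tmp_path):
        matrix = _matrix([[3], [2]], ["G1", "G2"], ["invasion"])
        path = tmp_path / "bip.gexf"
        export_bipartite_gexf(matrix, str(path))
        graph = nx.read_gexf(path)
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        assert graph.nodes["invasion"]["size"] == 2
        assert graph.edges["G1", "invasion"]["weight"] == 3.0

    def test_all_zero_matrix_has_no_edges(self, tmp_path):
        matrix = _matrix([[0]], ["G1"], ["invasion"])
        path = tmp_path / "zero.gexf"
        export_bipartite_gexf(matrix, str(path))
        graph = nx.read_gexf(path)
        assert graph.number_of_edges() == 0
        assert "G1" not in graph


class TestTsvRoundTrip:
    def test_matrix_roundtrip(self, tmp_path):
        matrix = _matrix([[1, 2], [3, 4]], ["A", "B"], ["invasion", "adhesion"])
        path = tmp_path / "m.tsv"
        with open(path, "w") as handle:
            matrix.to_tsv(handle)
        again = CooccurrenceMatrix.from_tsv(path.read_text())
        assert again.counts.equals(matrix.counts)
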