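"""Sentence-level gene-phenotype co-occurrence.

A gene and a phenotype keyword co-occur when they appear in the same
sentence; each (gene, phenotype, sentence) triple counts once no matter how
often either token repeats.  Phenotype keywords come from the classical
metastatic cascade — detachment/adhesion, migration, invasion of the matrix,
and angiogenesis — plus the umbrella term "metastasis" itself.  The
four-phenotype analyses (bipartite network, clustering heatmap) exclude
"metastasis" by default because it is the retrieval term of the whole corpus
rather than a cascade step.

Phenotype matching is case-insensitive whole-word on the configured surface
forms only: "invasion" does not match "invasive" unless the variant is added
to the surface-form list.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
import pandas as pd

from .corpus_io import Corpus
from .gene_ner import MentionEvent

DEFAULT_PHENOTYPES: tuple[str, ...] = (
    "metastasis",
    "adhesion",
    "migration",
    "invasion",
    "angiogenesis",
)
#: The four cascade phenotypes used for the bipartite and clustering views.
FOUR_PHENOTYPES: tuple[str, ...] = ("adhesion", "migration", "invasion", "angiogenesis")


@dataclass
class PhenotypeLexicon:
    """Ordered phenotype labels, each with its list of surface forms."""

    terms: list[tuple[str, tuple[str, ...]]]
    _patterns: dict[str, re.Pattern] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.terms]
        if len(labels) != len(set(labels)):
            raise ValueError("phenotype labels must be unique")
        self._patterns = {
            label: re.compile(
                r"(?<![A-Za-z0-9])(?:%s)(?![A-Za-z0-9])"
                % "|".join(re.escape(form) for form in forms),
                re.IGNORECASE,
            )
            for label, forms in self.terms
        }

    @classmethod
    def default(cls, include_metastasis: bool = True) -> "PhenotypeLexicon":
        labels = DEFAULT_PHENOTYPES if include_metastasis else FOUR_PHENOTYPES
        return cls(terms=[(label, (label,)) for label in labels])

    @classmethod
    def from_tsv(cls, stream: TextIO | str) -> "PhenotypeLexicon":
        """2-column TSV: label, pipe-separated surface forms."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        terms: list[tuple[str, tuple[str, ...]]] = []
        for line in stream:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[0].strip()
            forms = tuple(
                f.strip() for f in (parts[1].split("|") if len(parts) > 1 else []) if f.strip()
            ) or (label,)
            terms.append((label, forms))
        return cls(terms=terms)

    def to_tsv(self, stream: TextIO) -> None:
        for label, forms in self.terms:
            stream.write(f"{label}\t{'|'.join(forms)}\n")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.terms]

    def detect(self, sentence: str) -> set[str]:
        """Labels whose surface forms occur (whole-word) in the sentence."""
        return {
            label for label, pattern in self._patterns.items() if pattern.search(sentence)
        }

    def subset(self, labels: Sequence[str]) -> "PhenotypeLexicon":
        wanted = set(labels)
        return PhenotypeLexicon(terms=[t for t in self.terms if t[0] in wanted])


@dataclass
class CooccurrenceMatrix:
    """gene x phenotype sentence co-occurrence counts.

    ``counts`` is a DataFrame indexed by gene symbol with one column per
    phenotype label, in lexicon order.
    """

    counts: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, stream: TextIO) -> None:
        self.counts.to_csv(stream, sep="\t", index_label="symbol")

    @classmethod
    def from_tsv(cls, stream: TextIO | str) -> "CooccurrenceMatrix":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        df = pd.read_csv(stream, sep="\t", index_col="symbol")
        return cls(counts=df)


def count_cooccurrence(
    corpus: Corpus,
    mentions: Iterable[MentionEvent],
    phenotype_lexicon: PhenotypeLexicon | None = None,
) -> CooccurrenceMatrix:
    """Count, per sentence, each (gene, phenotype) pair present exactly once.

    Rows cover every gene with at least one mention in the corpus (rows may
    be all-zero if the gene never shares a sentence with a phenotype word);
    columns follow the phenotype lexicon order.
    """
    lexicon = phenotype_lexicon or PhenotypeLexicon.default()
    genes_in_sentence: dict[tuple[str, int], set[str]] = {}
    all_genes: set[str] = set()
    for m in mentions:
        genes_in_sentence.setdefault((m.pmid, m.sentence_index), set()).add(
            m.canonical_symbol
        )
        all_genes.add(m.canonical_symbol)
    gene_order = sorted(all_genes)
    counts = pd.DataFrame(0, index=gene_order, columns=lexicon.labels, dtype=int)
    for record in corpus.records:
        for idx, sentence in enumerate(record.sentences):
            genes = genes_in_sentence.get((record.pmid, idx))
            if not genes:
                continue
            phenotypes = lexicon.detect(sentence)
            if not phenotypes:
                continue
            for gene in genes:
                for phenotype in phenotypes:
                    counts.at[gene, phenotype] += 1
    return CooccurrenceMatrix(counts=counts)


def phenotype_totals(matrix: CooccurrenceMatrix) -> dict[str, int]:
    """Total co-occurrence frequency per phenotype (column sums)."""
    return {p: int(v) for p, v in matrix.counts.sum(axis=0).items()}


def top_gene_per_phenotype(matrix: CooccurrenceMatrix) -> dict[str, tuple[str, int]]:
    """Per phenotype, the gene with the highest co-occurrence count.

    Ties break lexicographically; all-zero columns are omitted from the
    result (no gene co-occurs with that phenotype).
    """
    result: dict[str, tuple[str, int]] = {}
    for phenotype in matrix.phenotypes:
        column = matrix.counts[phenotype]
        best = int(column.max()) if len(column) else 0
        if best <= 0:
            continue
        winner = min(g for g in column.index if column[g] == best)
        result[phenotype] = (winner, best)
    return result


def multi_phenotype_genes(
    matrix: CooccurrenceMatrix, min_phenotypes: int = 2, min_freq: int = 7
) -> set[str]:
    """Genes whose count reaches ``min_freq`` for >= ``min_phenotypes``
    distinct phenotypes — candidate regulators of several cascade steps."""
    if min_phenotypes < 1:
        raise ValueError("min_phenotypes must be >= 1")
    if min_freq < 0:
        raise ValueError("min_freq must be >= 0")
    hits = (matrix.counts >= min_freq).sum(axis=1)
    return set(hits.index[hits >= min_phenotypes])


def export_bipartite_gexf(matrix: CooccurrenceMatrix, path: str) -> None:
    """Write the gene-phenotype bipartite graph as GEXF 1.2.

    Phenotype nodes carry a ``size`` attribute (number of genes with a
    nonzero co-occurrence); edge ``weight`` is the co-occurrence frequency.
    Zero-count pairs are omitted; genes with no nonzero pair are left out.
    """
    graph = nx.Graph()
    for phenotype in matrix.phenotypes:
        column = matrix.counts[phenotype]
        graph.add_node(
            phenotype, kind="phenotype", size=int((column > 0).sum())
        )
    for gene in matrix.genes:
        row = matrix.counts.loc[gene]
        for phenotype in matrix.phenotypes:
            count = int(row[phenotype])
            if count > 0:
                if gene not in graph:
                    graph.add_node(gene, kind="gene")
                graph.add_edge(gene, phenotype, weight=float(count))
    nx.write_gexf(graph, path, version="1.2draft")
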