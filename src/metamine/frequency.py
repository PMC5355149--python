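"""Gene frequency tables: counting, ranking, filtering, cross-corpus
normalization, and shared/unique partitioning between two literature arms.

The counting unit is the sentence: a gene mentioned several times in one
sentence contributes once.  This one-per-sentence semantics is used for
frequencies and for co-occurrence alike, so a table entry is the number of
distinct sentences (across all abstracts of the corpus) in which the gene
appears.

Frequencies from corpora of different sizes are made comparable by scaling
the smaller arm's counts with the ratio of paper counts (reported rounded to
three decimals, e.g. 262/136 -> 1.926).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

from .gene_ner import MentionEvent
from .corpus_io import Corpus


@dataclass
class FrequencyTable:
    """Per-corpus gene counts; zero-count genes are simply absent.

    ``normalized`` marks tables whose values have been scaled by a corpus
    size ratio and are therefore real-valued, no longer integer counts.
    """

    corpus_label: str
    counts: dict[str, float]
    n_papers: int
    normalized: bool = False

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.counts.items() if c <= 0}
        if bad:
            raise ValueError(f"non-positive counts not allowed: {bad}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def genes(self) -> set[str]:
        return set(self.counts)


@dataclass(frozen=True)
class GeneSetPartition:
    """Disjoint decomposition of two gene sets into shared / A-only / B-only."""

    shared: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.a_only) + len(self.b_only)


def count_frequencies(mentions: Iterable[MentionEvent], corpus: Corpus) -> FrequencyTable:
    """Tally sentence-level gene incidences.

    A gene contributes at most 1 per (pmid, sentence_index), however many
    times its aliases occur in that sentence.
    """
    seen: set[tuple[str, int, str]] = set()
    counts: dict[str, int] = {}
    for m in mentions:
        key = (m.pmid, m.sentence_index, m.canonical_symbol)
        if key in seen:
            continue
        seen.add(key)
        counts[m.canonical_symbol] = counts.get(m.canonical_symbol, 0) + 1
    return FrequencyTable(
        corpus_label=corpus.label, counts=dict(counts), n_papers=corpus.n_papers
    )


def top_n(table: FrequencyTable, n: int) -> list[tuple[str, float]]:
    """Descending by count, ties broken lexicographically by symbol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def filter_min_freq(table: FrequencyTable, min_freq: float) -> FrequencyTable:
    """Retain entries with count >= min_freq (drops low-frequency genes)."""
    if min_freq < 0:
        raise ValueError("min_freq must be >= 0")
    kept = {g: c for g, c in table.counts.items() if c >= min_freq}
    return replace(table, counts=kept)


def normalization_factor(n_papers_ref: int, n_papers_target: int) -> float:
    """Corpus-size ratio, rounded to 3 decimals for reporting.

    ``n_papers_ref`` is the larger (reference) arm; the factor scales the
    target arm's frequencies onto the reference arm's scale.
    """
    if n_papers_target <= 0:
        raise ValueError("target paper count must be positive")
    if n_papers_ref <= 0:
        raise ValueError("reference paper count must be positive")
    return round(n_papers_ref / n_papers_target, 3)


def apply_normalization(table: FrequencyTable, factor: float) -> FrequencyTable:
    """Scale every count by ``factor``; result is flagged as normalized."""
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return replace(
        table,
        counts={g: c * factor for g, c in table.counts.items()},
        normalized=True,
    )


def partition_sets(genes_a: set[str], genes_b: set[str]) -> GeneSetPartition:
    """Split two gene sets into shared, A-only and B-only components."""
    a, b = set(genes_a), set(genes_b)
    return GeneSetPartition(
        shared=frozenset(a & b),
        a_only=frozenset(a - b),
        b_only=frozenset(b - a),
    )


def table_to_tsv(table: FrequencyTable, stream: TextIO) -> None:
    stream.write("symbol\tcount\n")
    for symbol, count in sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0])):
        value = f"{count:g}" if table.normalized else f"{int(count)}"
        stream.write(f"{symbol}\t{value}\n")


def table_from_tsv(
    stream: TextIO | str, corpus_label: str, n_papers: int, normalized: bool = False
) -> FrequencyTable:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    counts: dict[str, float] = {}
    header = stream.readline()
    if header.strip().lower() != "symbol\tcount":
        raise ValueError("frequency TSV must have header 'symbol\\tcount'")
    for line in stream:
        if not line.strip():
            continue
        symbol, value = line.rstrip("\n").split("\t")
        counts[symbol] = float(value) if normalized else int(float(value))
    return FrequencyTable(
        corpus_label=corpus_label, counts=counts, n_papers=n_papers, normalized=normalized
    )


def partition_to_tsv(partition: GeneSetPartition, stream: TextIO) -> None:
    stream.write("set\tsymbol\n")
    for name, members in (
        ("shared", partition.shared),
        ("a_only", partition.a_only),
        ("b_only", partition.b_only),
    ):
        for symbol in sorted(members):
            stream.write(f"{name}\t{symbol}\n")
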