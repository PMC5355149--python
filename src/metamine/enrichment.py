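"""Gene-set over-representation analysis.

For a query gene list drawn from a universe of U genes, and a gene set with
K members in that universe, the probability of seeing at least k of the set
in a query of size N is the upper tail of the hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeom(U, K, N)

Raw p-values are filtered at the configured significance level (default
0.05); Benjamini-Hochberg adjusted values are reported alongside but not
used for filtering, so the multiplicity of tested sets remains visible
without changing which sets pass.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from scipy import stats

logger = logging.getLogger(__name__)


class GmtError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise GmtError("gene set names must be unique")
        for s in self.sets:
            if not s.members <= self.universe:
                raise GmtError(f"set {s.name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def load_gmt(
    stream: TextIO | str, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read standard GMT lines (name, description, tab-separated members).

    With an explicit universe, members outside it are dropped with a warning;
    otherwise the universe defaults to the union of all members.  Sets left
    empty are rejected (skipped with a warning); duplicate names abort.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    explicit = frozenset(universe) if universe is not None else None
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtError(f"line {lineno}: GMT line needs name, description, members")
        name, description = fields[0].strip(), fields[1].strip()
        if name in seen:
            raise GmtError(f"line {lineno}: duplicate gene set name {name!r}")
        seen.add(name)
        members = {m.strip() for m in fields[2:] if m.strip()}
        if explicit is not None:
            dropped = members - explicit
            if dropped:
                logger.warning(
                    "set %s: dropping %d members outside the universe: %s",
                    name,
                    len(dropped),
                    sorted(dropped),
                )
            members &= explicit
        if not members:
            logger.warning("line %d: set %s has no (in-universe) members; rejected", lineno, name)
            continue
        sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    if explicit is not None:
        uni = explicit
    else:
        uni = frozenset().union(*(s.members for s in sets)) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=uni)


def hypergeometric_enrichment(
    query: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each set against the query.

    Query symbols outside the universe are dropped with a warning; an empty
    query after filtering is an error.  Results are sorted by ascending
    p-value (ties by set name) and carry BH-adjusted p-values computed
    across all sets of the collection.
    """
    query_set = set(query)
    outside = query_set - collection.universe
    if outside:
        logger.warning(
            "dropping %d query symbols outside the universe: %s",
            len(outside),
            sorted(outside),
        )
        query_set &= collection.universe
    if not query_set:
        raise ValueError("query is empty after restricting to the universe")
    universe_size = len(collection.universe)
    query_size = len(query_set)
    raw: list[tuple[GeneSet, int, float]] = []
    for gene_set in collection.sets:
        overlap = len(query_set & gene_set.members)
        # P(X >= overlap) for X ~ Hypergeom(M=universe, n=set size, N=query size)
        p = float(
            stats.hypergeom.sf(overlap - 1, universe_size, len(gene_set.members), query_size)
        )
        raw.append((gene_set, overlap, min(p, 1.0)))
    if raw:
        adjusted = stats.false_discovery_control([p for _, _, p in raw], method="bh")
    else:
        adjusted = []
    results = [
        EnrichmentResult(
            set_name=gene_set.name,
            overlap_count=overlap,
            query_size=query_size,
            set_size=len(gene_set.members),
            universe_size=universe_size,
            p_value=p,
            adjusted_p=float(adj),
        )
        for (gene_set, overlap, p), adj in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def filter_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Keep results with raw p <= alpha (adjusted p is reported, not filtered)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return [r for r in results if r.p_value <= alpha]


def results_to_tsv(results: Iterable[EnrichmentResult], stream: TextIO) -> None:
    stream.write("set\toverlap\tquery_size\tset_size\tuniverse_size\tp_value\tbh_p\n")
    for r in results:
        stream.write(
            f"{r.set_name}\t{r.overlap_count}\t{r.query_size}\t{r.set_size}\t"
            f"{r.universe_size}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\n"
        )
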