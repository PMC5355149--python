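"""Seeded generators for every input the pipeline consumes.

The generators emulate a corpus of short abstracts in which gene aliases
and phenotype keywords are planted in sentences at configurable rates,
plus the alias lexicon, GMT gene-set collection and PPI edge list that go
with it.  Ground truth (sentence-level frequencies, co-occurrence counts,
planted multi-phenotype genes, planted hubs) is recorded *during*
generation from the very sets of tokens placed into each sentence, so
oracle tests against it are independent of the mining code path.

Everything is a pure function of its spec + seed: identical seeds give
byte-identical files.

What is emulated and what is not: sentences are template prose ("Expression
of GENE3 correlated with invasion ...") — enough to exercise sentence
splitting, boundary-aware alias matching, case handling and the
once-per-sentence counting semantics.  There is no attempt at natural
language, publication bias, alias ambiguity across genes, or morphological
phenotype variants.  Templates deliberately avoid the sentence splitter's
abbreviation list so ground-truth sentence counts are unambiguous.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cooccurrence import DEFAULT_PHENOTYPES

_FILLERS = (
    "The cohort was reviewed retrospectively by the study board.",
    "Clinical records were collected from three liver centers.",
    "Specimens were processed under a standardized protocol.",
    "Follow-up data were available for most enrolled patients.",
)


@dataclass
class CorpusSpec:
    """Planted-signal description of a synthetic abstract corpus.

    Defaults describe the demo conditions used throughout the test suite:
    200 abstracts of 3-8 sentences over a 20-gene vocabulary, a low
    background mention rate, and a handful of gene-phenotype pairs planted
    at rates that clearly clear the multi-phenotype thresholds.
    """

    n_abstracts: int = 200
    sentences_range: tuple[int, int] = (3, 8)
    n_genes: int = 20
    aliases_per_gene: int = 2
    gene_mention_rate: float = 0.01
    phenotype_rate: float = 0.01
    pair_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    alias_usage: float = 0.3
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pair_rates:
            # default plant: 4 genes, each tied to >=2 cascade phenotypes
            self.pair_rates = {
                ("GENE1", "invasion"): 0.04,
                ("GENE1", "migration"): 0.03,
                ("GENE2", "adhesion"): 0.03,
                ("GENE2", "angiogenesis"): 0.03,
                ("GENE3", "invasion"): 0.03,
                ("GENE3", "angiogenesis"): 0.03,
                ("GENE4", "migration"): 0.03,
                ("GENE4", "adhesion"): 0.03,
                ("GENE4", "invasion"): 0.03,
            }
        self.validate()

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_abstracts < 0:
            errors.append("n_abstracts must be >= 0")
        lo, hi = self.sentences_range
        if not (1 <= lo <= hi):
            errors.append("sentences_range must satisfy 1 <= lo <= hi")
        for name in ("gene_mention_rate", "phenotype_rate", "alias_usage"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                errors.append(f"{name} must be in [0, 1]")
        genes = set(self.gene_symbols)
        for (gene, phenotype), rate in self.pair_rates.items():
            if not (0.0 <= rate <= 1.0):
                errors.append(f"pair rate for ({gene}, {phenotype}) must be in [0, 1]")
            if gene not in genes:
                errors.append(f"pair rate names unknown gene {gene!r}")
            if phenotype not in self.phenotypes:
                errors.append(f"pair rate names unknown phenotype {phenotype!r}")
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def gene_symbols(self) -> list[str]:
        return [f"GENE{i}" for i in range(1, self.n_genes + 1)]

    @property
    def planted_multiphenotype_genes(self) -> set[str]:
        by_gene: dict[str, int] = {}
        for (gene, _), rate in self.pair_rates.items():
            if rate > 0:
                by_gene[gene] = by_gene.get(gene, 0) + 1
        return {gene for gene, k in by_gene.items() if k >= 2}


@dataclass
class GroundTruth:
    """Tallies recorded while the corpus was generated."""

    true_frequencies: dict[str, int] = field(default_factory=dict)
    true_cooccurrence: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_multiphenotype_genes: set[str] = field(default_factory=set)
    planted_hubs: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "true_frequencies": dict(sorted(self.true_frequencies.items())),
            "true_cooccurrence": {
                g: dict(sorted(p.items()))
                for g, p in sorted(self.true_cooccurrence.items())
            },
            "planted_multiphenotype_genes": sorted(self.planted_multiphenotype_genes),
            "planted_hubs": sorted(self.planted_hubs),
        }
        return json.dumps(payload, indent=1) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            true_frequencies=dict(payload["true_frequencies"]),
            true_cooccurrence={
                g: dict(p) for g, p in payload["true_cooccurrence"].items()
            },
            planted_multiphenotype_genes=set(payload["planted_multiphenotype_genes"]),
            planted_hubs=set(payload["planted_hubs"]),
        )


def generate_lexicon(n_genes: int, aliases_per_gene: int = 2, seed: int = 0) -> str:
    """Synthetic lexicon TSV: GENE1..GENEn plus distinct synthetic aliases.

    The table is a deterministic function of (n_genes, aliases_per_gene);
    the seed is accepted for API symmetry with the other generators.  All
    aliases are >= 4 characters so they participate in case-insensitive
    matching, and none collides with another gene's aliases.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lines = ["symbol\tgene_id\tdescription\taliases"]
    for i in range(1, n_genes + 1):
        aliases = "|".join(f"SG{i}X{j}" for j in range(1, aliases_per_gene + 1))
        lines.append(f"GENE{i}\t{100000 + i}\tsynthetic gene {i}\t{aliases}")
    return "\n".join(lines) + "\n"


def _alias_table(spec: CorpusSpec) -> dict[str, list[str]]:
    """symbol -> non-canonical aliases, mirroring generate_lexicon."""
    return {
        f"GENE{i}": [f"SG{i}X{j}" for j in range(1, spec.aliases_per_gene + 1)]
        for i in range(1, spec.n_genes + 1)
    }


def _render_sentence(
    genes: Sequence[str], phenotypes: Sequence[str], aliases: dict[str, list[str]],
    rng: np.random.Generator, alias_usage: float, filler_index: int,
) -> str:
    surface = []
    for gene in genes:
        if aliases[gene] and rng.random() < alias_usage:
            surface.append(aliases[gene][int(rng.integers(len(aliases[gene])))])
        else:
            surface.append(gene)
    gene_phrase = " and ".join(surface)
    pheno_phrase = " and ".join(phenotypes)
    if genes and phenotypes:
        return f"Expression of {gene_phrase} correlated with {pheno_phrase} in hepatoma tissue."
    if genes:
        return f"Expression of {gene_phrase} was quantified in tumor specimens."
    if phenotypes:
        return f"Tumor {pheno_phrase} was scored by two independent pathologists."
    return _FILLERS[filler_index % len(_FILLERS)]


def generate_corpus(spec: CorpusSpec) -> tuple[str, GroundTruth]:
    """Emit a MEDLINE-format corpus plus its recorded ground truth.

    Per sentence: each planted (gene, phenotype) pair fires independently
    with its rate, each gene additionally appears with the background
    ``gene_mention_rate``, each phenotype with ``phenotype_rate``.  The
    tokens actually placed in the sentence (as sets) drive both the text
    and the truth tallies, so truth and corpus agree by construction under
    once-per-sentence counting.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aliases = _alias_table(spec)
    genes = spec.gene_symbols
    pairs = sorted(spec.pair_rates.items())
    truth = GroundTruth(
        planted_multiphenotype_genes=set(spec.planted_multiphenotype_genes)
    )
    buf = io.StringIO()
    filler_index = 0
    lo, hi = spec.sentences_range
    for k in range(spec.n_abstracts):
        pmid = str(9_000_001 + k)
        n_sentences = int(rng.integers(lo, hi + 1))
        sentences: list[str] = []
        for _ in range(n_sentences):
            fired = [(g, p) for (g, p), rate in pairs if rng.random() < rate]
            sentence_genes = {g for g, _ in fired}
            sentence_phenos = {p for _, p in fired}
            for gene in genes:
                if rng.random() < spec.gene_mention_rate:
                    sentence_genes.add(gene)
            for phenotype in spec.phenotypes:
                if rng.random() < spec.phenotype_rate:
                    sentence_phenos.add(phenotype)
            ordered_genes = sorted(sentence_genes)
            ordered_phenos = [p for p in spec.phenotypes if p in sentence_phenos]
            sentences.append(
                _render_sentence(
                    ordered_genes, ordered_phenos, aliases, rng,
                    spec.alias_usage, filler_index,
                )
            )
            if not ordered_genes and not ordered_phenos:
                filler_index += 1
            for gene in ordered_genes:
                truth.true_frequencies[gene] = truth.true_frequencies.get(gene, 0) + 1
                for phenotype in ordered_phenos:
                    row = truth.true_cooccurrence.setdefault(gene, {})
                    row[phenotype] = row.get(phenotype, 0) + 1
        buf.write(f"PMID- {pmid}\n")
        buf.write("TI  - A synthetic abstract on hepatoma biology.\n")
        buf.write(f"AB  - {' '.join(sentences)}\n\n")
    return buf.getvalue(), truth


def generate_ppi(
    n_nodes: int, n_hub: int, hub_degree_boost: float, seed: int = 0,
    base_edge_prob: float = 0.05,
) -> tuple[str, set[str]]:
    """Random interaction TSV in which designated hubs attach preferentially.

    Any pair touching a hub gets edge probability
    ``min(1, base_edge_prob * hub_degree_boost)``; other pairs use
    ``base_edge_prob``.  All rows carry the ``experimental`` evidence tag.
    Returns (edge TSV, planted hub symbols).
    """
    if not (0 <= n_hub <= n_nodes):
        raise ValueError("need 0 <= n_hub <= n_nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"GENE{i}" for i in range(1, n_nodes + 1)]
    hub_idx = set(rng.choice(n_nodes, size=n_hub, replace=False).tolist())
    hubs = {nodes[i] for i in sorted(hub_idx)}
    hub_p = min(1.0, base_edge_prob * hub_degree_boost)
    lines = ["#interactorA\tinteractorB\tsource\tevidence"]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = hub_p if (i in hub_idx or j in hub_idx) else base_edge_prob
            if rng.random() < p:
                lines.append(f"{nodes[i]}\t{nodes[j]}\tsynthetic\texperimental")
    return "\n".join(lines) + "\n", hubs


def generate_gmt(
    universe: Sequence[str],
    n_sets: int = 20,
    set_size: tuple[int, int] = (5, 15),
    enriched_query: Iterable[str] | None = None,
    overlap_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[str, list[str]]:
    """Random GMT collection, optionally with one planted enriched set.

    Without ``enriched_query`` the collection is a calibration-mode null:
    every set is a uniform draw from the universe.  With a query, the first
    set (``SET_ENRICHED``) draws ``overlap_fraction`` of its members from
    the query, so the hypergeometric test must rank it first.  Returns
    (GMT text, names of sets expected significant).
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    lo, hi = set_size
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("set_size range must fit inside the universe")
    lines: list[str] = []
    expected: list[str] = []
    if enriched_query is not None:
        query = sorted(set(enriched_query) & set(universe))
        if not query:
            raise ValueError("enriched_query shares no symbols with the universe")
        size = min(hi, max(lo, len(query)))
        n_from_query = max(1, int(round(overlap_fraction * size)))
        n_from_query = min(n_from_query, len(query))
        background = sorted(set(universe) - set(query))
        members = sorted(
            rng.choice(query, size=n_from_query, replace=False).tolist()
            + rng.choice(
                background, size=min(size - n_from_query, len(background)), replace=False
            ).tolist()
        )
        lines.append("SET_ENRICHED\tsynthetic planted set\t" + "\t".join(members))
        expected.append("SET_ENRICHED")
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        lines.append(f"SET{i}\tsynthetic random set\t" + "\t".join(members))
    return "\n".join(lines) + "\n", expected
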