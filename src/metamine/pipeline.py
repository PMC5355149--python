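"""End-to-end orchestration: mine -> frequency -> partition/normalize ->
enrich -> co-occur -> cluster -> network, with a JSON run manifest.

The configuration is a single YAML file naming the corpus arms (a main
corpus plus two optional etiology arms, e.g. HBV and HCV retrievals), the
lexicons, gene sets and edge list, and the analysis thresholds.  Defaults
carry the standard thresholds of the analysis: genes below frequency 5 are
excluded from the etiology comparison, multi-phenotype genes need
co-occurrence >= 7 with >= 2 phenotypes, enrichment is filtered at p <=
0.05, and rankings report the top 20.

Every stage is a pure function of inputs + config, so re-running with the
same inputs produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .clustering import export_heatmap_data, hierarchical_cluster, linear_normalize
from .cooccurrence import (
    FOUR_PHENOTYPES,
    PhenotypeLexicon,
    count_cooccurrence,
    export_bipartite_gexf,
    multi_phenotype_genes,
    phenotype_totals,
    top_gene_per_phenotype,
)
from .corpus_io import parse_medline
from .enrichment import (
    filter_significant,
    hypergeometric_enrichment,
    load_gmt,
    results_to_tsv,
)
from .frequency import (
    apply_normalization,
    count_frequencies,
    filter_min_freq,
    normalization_factor,
    partition_sets,
    partition_to_tsv,
    table_to_tsv,
    top_n,
)
from .gene_ner import load_lexicon, mentions_to_tsv, mine_corpus
from .ppi_network import (
    build_induced_network,
    degree_ranking,
    export_network_gexf,
    load_edges,
    ranking_to_tsv,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration failed validation; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    corpus_main: str = ""
    label_main: str = "main"
    corpus_arm_a: str | None = None
    label_arm_a: str = "arm_a"
    corpus_arm_b: str | None = None
    label_arm_b: str = "arm_b"
    lexicon: str = ""
    phenotypes: str | None = None  # None -> built-in default phenotype lexicon
    gene_sets: str | None = None
    edges: str | None = None
    min_freq: int = 5
    cooccurrence_min_freq: int = 7
    min_phenotypes: int = 2
    alpha: float = 0.05
    top_n: int = 20
    output_dir: str = "metamine_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError([f"unknown config field {k!r}" for k in sorted(unknown)])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every violation at once; an empty list means the config is valid."""
    errors: list[str] = []
    if not config.corpus_main:
        errors.append("corpus_main: path is required")
    for name in ("corpus_main", "corpus_arm_a", "corpus_arm_b", "lexicon",
                 "phenotypes", "gene_sets", "edges"):
        value = getattr(config, name)
        if name == "lexicon" and not value:
            errors.append("lexicon: path is required")
            continue
        if value and not Path(value).exists():
            errors.append(f"{name}: path does not exist: {value}")
    if (config.corpus_arm_a is None) != (config.corpus_arm_b is None):
        errors.append("corpus_arm_a/corpus_arm_b: both arms or neither")
    for name in ("min_freq", "cooccurrence_min_freq"):
        if getattr(config, name) < 0:
            errors.append(f"{name}: must be >= 0")
    if config.min_phenotypes < 1:
        errors.append("min_phenotypes: must be >= 1")
    if not (0 < config.alpha <= 1):
        errors.append("alpha: must be in (0, 1]")
    if config.top_n < 1:
        errors.append("top_n: must be >= 1")
    return errors


def _write(path: Path, writer) -> None:
    with open(path, "w") as handle:
        writer(handle)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, write the report bundle, return the run manifest.

    On a stage failure a partial manifest (completed stages only) is still
    written before :class:`StageError` propagates.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError(errors)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "metamine",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_freq": config.min_freq,
            "cooccurrence_min_freq": config.cooccurrence_min_freq,
            "min_phenotypes": config.min_phenotypes,
            "alpha": config.alpha,
            "top_n": config.top_n,
        },
        "stages": [],
        "counts": {},
    }
    state: dict[str, Any] = {}

    def stage(name: str):
        def decorator(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # record partial manifest, then abort
                manifest["failed_stage"] = name
                with open(out / "manifest.json", "w") as handle:
                    json.dump(manifest, handle, indent=1, sort_keys=True)
                raise StageError(name, exc) from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            logger.info("stage %s done (%.3fs)", name, time.perf_counter() - t0)
        return decorator

    @stage("mine")
    def _mine() -> None:
        with open(config.lexicon) as handle:
            lexicon = load_lexicon(handle)
        state["lexicon"] = lexicon
        for key, path, label in (
            ("main", config.corpus_main, config.label_main),
            ("arm_a", config.corpus_arm_a, config.label_arm_a),
            ("arm_b", config.corpus_arm_b, config.label_arm_b),
        ):
            if path is None:
                continue
            with open(path) as handle:
                corpus = parse_medline(handle, label=label)
            mentions = mine_corpus(corpus, lexicon)
            state[f"corpus_{key}"] = corpus
            state[f"mentions_{key}"] = mentions
            manifest["counts"][f"n_papers_{key}"] = corpus.n_papers
            manifest["counts"][f"n_mentions_{key}"] = len(mentions)
        _write(out / "mentions_main.tsv", lambda h: mentions_to_tsv(state["mentions_main"], h))

    @stage("frequency")
    def _frequency() -> None:
        table = count_frequencies(state["mentions_main"], state["corpus_main"])
        state["freq_main"] = table
        manifest["counts"]["n_genes_main"] = len(table)
        ranked = top_n(table, config.top_n) if len(table) else []
        manifest["counts"]["top_gene"] = ranked[0][0] if ranked else None
        _write(out / "frequencies_main.tsv", lambda h: table_to_tsv(table, h))
        with open(out / "top_genes.tsv", "w") as handle:
            handle.write("rank\tsymbol\tcount\n")
            for rank, (symbol, count) in enumerate(ranked, start=1):
                handle.write(f"{rank}\t{symbol}\t{int(count)}\n")

    @stage("partition")
    def _partition() -> None:
        if "corpus_arm_a" not in state:
            manifest["counts"]["partition"] = None
            return
        freq_a = count_frequencies(state["mentions_arm_a"], state["corpus_arm_a"])
        freq_b = count_frequencies(state["mentions_arm_b"], state["corpus_arm_b"])
        kept_a = filter_min_freq(freq_a, config.min_freq)
        kept_b = filter_min_freq(freq_b, config.min_freq)
        part = partition_sets(kept_a.genes, kept_b.genes)
        state["partition"] = part
        state["freq_arm_a"], state["freq_arm_b"] = kept_a, kept_b
        # scale the smaller arm onto the larger arm's corpus size
        if freq_a.n_papers >= freq_b.n_papers:
            factor = normalization_factor(freq_a.n_papers, freq_b.n_papers)
            normalized = apply_normalization(kept_b, factor)
            scaled_label = kept_b.corpus_label
        else:
            factor = normalization_factor(freq_b.n_papers, freq_a.n_papers)
            normalized = apply_normalization(kept_a, factor)
            scaled_label = kept_a.corpus_label
        manifest["counts"]["partition"] = {
            "shared": len(part.shared),
            "a_only": len(part.a_only),
            "b_only": len(part.b_only),
            "union": part.union_size,
        }
        manifest["counts"]["normalization_factor"] = factor
        manifest["counts"]["normalized_arm"] = scaled_label
        _write(out / "partition.tsv", lambda h: partition_to_tsv(part, h))
        _write(out / "frequencies_normalized.tsv", lambda h: table_to_tsv(normalized, h))

    @stage("enrichment")
    def _enrichment() -> None:
        if config.gene_sets is None:
            manifest["counts"]["enrichment"] = None
            return
        lexicon_universe = set(state["lexicon"].symbols)
        with open(config.gene_sets) as handle:
            collection = load_gmt(handle, universe=lexicon_universe)
        queries: dict[str, set[str]] = {"main": state["freq_main"].genes}
        if "partition" in state:
            queries[config.label_arm_a] = set(state["partition"].a_only)
            queries[config.label_arm_b] = set(state["partition"].b_only)
        summary: dict[str, int] = {}
        for name, query in queries.items():
            query &= collection.universe
            if not query:
                summary[name] = 0
                continue
            results = hypergeometric_enrichment(query, collection)
            significant = filter_significant(results, config.alpha)
            summary[name] = len(significant)
            _write(
                out / f"enrichment_{name}.tsv", lambda h, r=results: results_to_tsv(r, h)
            )
        manifest["counts"]["enrichment_significant"] = summary

    @stage("cooccurrence")
    def _cooccurrence() -> None:
        if config.phenotypes:
            with open(config.phenotypes) as handle:
                lexicon = PhenotypeLexicon.from_tsv(handle)
        else:
            lexicon = PhenotypeLexicon.default()
        state["phenotype_lexicon"] = lexicon
        matrix = count_cooccurrence(
            state["corpus_main"], state["mentions_main"], lexicon
        )
        state["cooc"] = matrix
        manifest["counts"]["phenotype_totals"] = phenotype_totals(matrix)
        manifest["counts"]["top_gene_per_phenotype"] = {
            p: list(v) for p, v in top_gene_per_phenotype(matrix).items()
        }
        _write(out / "cooccurrence.tsv", lambda h: matrix.to_tsv(h))
        export_bipartite_gexf(matrix, str(out / "cooccurrence_bipartite.gexf"))

    @stage("clustering")
    def _clustering() -> None:
        matrix = state["cooc"]
        # cascade phenotypes only: the umbrella retrieval term is excluded
        four = [p for p in matrix.phenotypes if p in FOUR_PHENOTYPES]
        sub = matrix.counts[four] if four else matrix.counts
        selected = sorted(
            multi_phenotype_genes(
                type(matrix)(counts=sub),
                min_phenotypes=config.min_phenotypes,
                min_freq=config.cooccurrence_min_freq,
            )
        )
        manifest["counts"]["multi_phenotype_genes"] = selected
        with open(out / "multi_phenotype_genes.tsv", "w") as handle:
            handle.write("symbol\n")
            for symbol in selected:
                handle.write(f"{symbol}\n")
        if len(selected) < 2:
            manifest["counts"]["clustered_rows"] = len(selected)
            return
        normalized = linear_normalize(sub.loc[selected], mode="row")
        tree = hierarchical_cluster(normalized)
        export_heatmap_data(normalized, tree, str(out / "heatmap_data.tsv"))
        manifest["counts"]["clustered_rows"] = len(selected)

    @stage("network")
    def _network() -> None:
        if config.edges is None:
            manifest["counts"]["network"] = None
            return
        with open(config.edges) as handle:
            edges = load_edges(handle)
        query = state["freq_main"].genes
        if not query:
            manifest["counts"]["network"] = {"nodes": 0, "edges": 0}
            return
        network = build_induced_network(edges, query)
        ranking = degree_ranking(network, config.top_n) if len(network) else []
        manifest["counts"]["network"] = {
            "nodes": network.graph.number_of_nodes(),
            "edges": network.graph.number_of_edges(),
        }
        export_network_gexf(network, str(out / "ppi_network.gexf"))
        _write(out / "degree_ranking.tsv", lambda h: ranking_to_tsv(ranking, h))

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest
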