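"""End-to-end orchestration: parse inputs, score similarity per cutoff and
method, resample significance per mode, intersect interactor sets, rank
mediators, test their differential expression and enrich both sets.

The report bundle is fully machine-readable (JSON index + TSV artifacts)
and regenerates byte-identically for a fixed config and seed: no
timestamps or other environment state enter the outputs.  No
multiple-testing correction is applied across the method x cutoff grid —
every combination is reported as-is.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model import GeneSetSimilarity
from .network import parse_string_links, rank_mediators, venn_summary
from .ontology import compute_ic, load_annotations, parse_obo, propagate_counts
from .resampling import MODES
from .semsim import METHODS
from .stats import diff_expression, enrich_hypergeometric, enrichment_tsv, \
    load_expression

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Parameter surface of the full analysis."""

    ontology: str
    annotations: str
    ppi: str
    seed_protein_a: str
    seed_protein_b: str
    expression: str | None = None
    groups: str | None = None
    cutoffs: list[float] = field(default_factory=lambda: [0.9, 0.95])
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    modes: list[str] = field(default_factory=lambda: list(MODES))
    n_reps: int = 1000
    namespace: str = "BP"
    seed: int = 0
    outdir: str = "report"
    n_top_mediators: int = 5
    min_links: int = 2
    min_term_size: int = 3
    universe: str = "corpus"  # or "network"

    def __post_init__(self) -> None:
        for cutoff in self.cutoffs:
            if not 0.0 < cutoff < 1.0:
                raise ValueError(f"cutoff {cutoff} outside (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")
        if self.universe not in ("corpus", "network"):
            raise ValueError("universe must be 'corpus' or 'network'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            payload = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """Everything one run produced: a JSON-ready index plus text artifacts.

    ``data`` is the report index; ``artifacts`` maps relative file names to
    text payloads.  ``write`` materialises both under an output directory.
    """

    data: dict
    artifacts: dict[str, str]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report = outdir / "report.json"
        report.write_text(
            json.dumps(self.data, sort_keys=True, indent=2,
                       default=_jsonable) + "\n",
            encoding="utf-8")
        for name, payload in sorted(self.artifacts.items()):
            (outdir / name).write_text(payload, encoding="utf-8")
        return report


def _jsonable(value):
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serialisable: {type(value).__name__}")


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Guard()


def _combo_seed(root_seed: int, *key: int) -> int:
    """Deterministic independent sub-seed for a (cutoff, ...) combination."""
    state = np.random.SeedSequence(entropy=root_seed,
                                   spawn_key=tuple(key)).generate_state(1)
    return int(state[0] % (2 ** 31))


def _cutoff_label(cutoff: float) -> str:
    return f"ics{cutoff:g}"


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and return (not yet write) the bundle.

    Stage order: parse ontology/annotations -> per-cutoff interactor
    extraction -> per-method set similarity -> per-mode Monte Carlo ->
    common interactors and mediator ranking -> enrichment of both sets ->
    differential expression of the top mediator candidates.
    """
    with _stage("ontology"):
        dag = parse_obo(config.ontology)
        direct = load_annotations(config.annotations)
        corpus = propagate_counts(dag, direct)
        compute_ic(corpus, config.namespace)  # fail early if empty

    expr = None
    if config.expression:
        with _stage("expression"):
            if not config.groups:
                raise ValueError("expression given without a groups file")
            expr = load_expression(config.expression, config.groups)

    data: dict = {
        "run_info": {
            "package": "semlink",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        },
        "cutoffs": {},
    }
    artifacts: dict[str, str] = {}
    candidate_pool: list[str] = []

    for c_idx, cutoff in enumerate(config.cutoffs):
        label = _cutoff_label(cutoff)
        with _stage(f"network@{label}"):
            net = parse_string_links(config.ppi, cutoff)
            seed_a, seed_b = config.seed_protein_a, config.seed_protein_b
            if seed_a not in net or seed_b not in net:
                raise ValueError(
                    f"seed protein(s) absent from the network at "
                    f"cutoff {cutoff}")
            set_a = net.interactors(seed_a)
            set_b = net.interactors(seed_b)
            venn = venn_summary(net, seed_a, seed_b)

        with _stage(f"similarity@{label}"):
            universe = (sorted(net.nodes - {seed_a, seed_b})
                        if config.universe == "network" else None)
            model = GeneSetSimilarity.from_network(
                net, seed_a, seed_b, corpus, namespace=config.namespace,
                universe=universe)
            results = model.fit(methods=config.methods, modes=config.modes,
                                n_reps=config.n_reps,
                                seed=_combo_seed(config.seed, c_idx))

        with _stage(f"mediators@{label}"):
            anchors = {seed_b} | set(venn["common"])
            ranking = rank_mediators(net, anchors,
                                     min_links=config.min_links)
            artifacts[f"mediators_{label}.tsv"] = ranking.to_tsv()
            for candidate in ranking.top(config.n_top_mediators):
                if candidate not in candidate_pool:
                    candidate_pool.append(candidate)

        with _stage(f"enrichment@{label}"):
            enrichment = {}
            for side, genes in (("a", set_a), ("b", set_b)):
                rows = enrich_hypergeometric(
                    genes, corpus, min_term_size=config.min_term_size)
                artifacts[f"enrichment_{label}_{side}.tsv"] = \
                    enrichment_tsv(rows)
                enrichment[side] = [dataclasses.asdict(r) for r in rows[:20]]

        methods_data = {}
        for method in config.methods:
            sim = results.similarities[method]
            artifacts[f"similarity_matrix_{label}_{method}.tsv"] = \
                sim.to_tsv()
            mc_data = {}
            for mode in config.modes:
                mc = results.mc[(method, mode)]
                artifacts[f"random_scores_{label}_{method}_{mode}.tsv"] = \
                    mc.scores_tsv()
                mc_data[mode] = mc.to_dict()
            entry = sim.summary_dict(cutoff)
            entry["mc"] = mc_data
            methods_data[method] = entry

        artifacts[f"interactors_{label}_a.txt"] = \
            "\n".join(sorted(set_a)) + "\n"
        artifacts[f"interactors_{label}_b.txt"] = \
            "\n".join(sorted(set_b)) + "\n"

        data["cutoffs"][label] = {
            "cutoff": cutoff,
            "venn": venn,
            "methods": methods_data,
            "mediators": [{"candidate": c, "n_links": n,
                           "linked_anchors": list(links)}
                          for c, n, links in ranking.rows],
            "enrichment": enrichment,
        }

    de_data = {}
    if expr is not None:
        with _stage("differential_expression"):
            for candidate in candidate_pool:
                if candidate not in expr.values.index:
                    logger.info("mediator candidate %r absent from the "
                                "expression matrix", candidate)
                    de_data[candidate] = {"status": "absent"}
                    continue
                u, p, direction = diff_expression(expr, candidate)
                de_data[candidate] = {"status": "tested", "U": u, "p": p,
                                      "direction": direction}
    data["differential_expression"] = de_data
    return ReportBundle(data=data, artifacts=artifacts)
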