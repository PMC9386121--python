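"""Synthetic ontologies, corpora, PPI networks and expression matrices.

Every generator is a pure function of its parameters and a seed, and each
emits exactly the dialects the package's parsers consume, so the whole
pipeline is testable without downloads.  The PPI generator plants the study
design the analysis targets: two seed proteins whose interactor sets are
functionally coherent (annotated near a shared theme term) to a tunable
degree, a configurable overlap wired to both seeds, an optional hub
adjacent to the second seed and all shared interactors, and background
noise edges constrained so no decoy out-links the hub.  Edge confidence
scores are drawn in (0.9, 1.0] so both study cutoffs (0.9 and 0.95) are
exercised nontrivially.
"""

from __future__ import annotations

import json
import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import PPINetwork
from .ontology import (AnnotationCorpus, IS_A, PART_OF, OntologyDAG,
                       OntologyTerm, _NAMESPACE_LONG, propagate_counts)
from .stats import ExpressionMatrix

logger = logging.getLogger(__name__)

SEED_A = "SEED_A"
SEED_B = "SEED_B"
HUB_ID = "HUB00001"


@dataclass
class TruthRecord:
    """Ground truth planted by the generators.

    ``coherence`` is the probability that an interactor was drawn from the
    theme neighbourhood rather than uniformly (0 means fully random sets);
    ``effect_size`` is the planted expression shift in sigma units.
    """

    seed_proteins: tuple[str, str] | None = None
    planted_common: frozenset[str] = frozenset()
    planted_hub: str | None = None
    coherence: float = 0.0
    de_gene: str | None = None
    effect_size: float = 0.0
    interactors_a: frozenset[str] = frozenset()
    interactors_b: frozenset[str] = frozenset()
    theme_term: str | None = None

    def to_dict(self) -> dict:
        return {
            "seed_proteins": list(self.seed_proteins)
            if self.seed_proteins else None,
            "planted_common": sorted(self.planted_common),
            "planted_hub": self.planted_hub,
            "coherence": self.coherence,
            "de_gene": self.de_gene,
            "effect_size": self.effect_size,
            "interactors_a": sorted(self.interactors_a),
            "interactors_b": sorted(self.interactors_b),
            "theme_term": self.theme_term,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "TruthRecord":
        return cls(
            seed_proteins=tuple(payload["seed_proteins"])
            if payload.get("seed_proteins") else None,
            planted_common=frozenset(payload.get("planted_common", ())),
            planted_hub=payload.get("planted_hub"),
            coherence=payload.get("coherence", 0.0),
            de_gene=payload.get("de_gene"),
            effect_size=payload.get("effect_size", 0.0),
            interactors_a=frozenset(payload.get("interactors_a", ())),
            interactors_b=frozenset(payload.get("interactors_b", ())),
            theme_term=payload.get("theme_term"),
        )


# ---------------------------------------------------------------------------
# Ontology and corpus
# ---------------------------------------------------------------------------

def generate_dag(n_terms: int, max_parents: int = 2,
                 part_of_fraction: float = 0.2, seed: int = 0,
                 namespace: str = "BP") -> OntologyDAG:
    """Single-root acyclic term graph grown by preferential attachment-free
    random wiring: each new term attaches to 1..max_parents earlier terms,
    each edge being part_of with the stated probability."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if not 0.0 <= part_of_fraction <= 1.0:
        raise ValueError("part_of_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"T{i:05d}" for i in range(n_terms)]
    terms = [OntologyTerm(term_id=ids[0], name="synthetic root",
                          namespace=namespace)]
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, max_parents + 1))
        n_par = min(n_par, i)
        parent_idx = rng.choice(i, size=n_par, replace=False)
        parents = tuple(
            (ids[int(j)],
             PART_OF if rng.random() < part_of_fraction else IS_A)
            for j in sorted(parent_idx))
        terms.append(OntologyTerm(term_id=ids[i], name=f"synthetic term {i}",
                                  namespace=namespace, parents=parents))
    return OntologyDAG(terms)


def generate_corpus(dag: OntologyDAG, n_genes: int, mean_annots: float = 4.0,
                    seed: int = 0) -> AnnotationCorpus:
    """Annotation corpus with per-gene annotation counts 1 + Poisson(mean-1).

    Each gene receives that many distinct uniformly chosen terms; the
    universe is all genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_annots < 1.0:
        raise ValueError("mean_annots must be >= 1")
    rng = np.random.default_rng(seed)
    term_ids = sorted(t.term_id for t in dag.active_terms())
    direct = {}
    for i in range(n_genes):
        count = 1 + int(rng.poisson(mean_annots - 1.0))
        count = min(count, len(term_ids))
        chosen = rng.choice(len(term_ids), size=count, replace=False)
        direct[f"G{i:05d}"] = {term_ids[int(j)] for j in chosen}
    return propagate_counts(dag, direct)


# ---------------------------------------------------------------------------
# PPI network with planted structure
# ---------------------------------------------------------------------------

def _theme_pool(dag: OntologyDAG, direct_by_term: dict[str, set[str]],
                theme: str) -> set[str]:
    """Genes directly annotated to the theme term, its descendants, or terms
    sharing a parent with it (the configurable 'theme proximity')."""
    nearby = {theme} | set(dag.descendants(theme))
    theme_parents = {p for p, _ in dag.terms[theme].parents}
    if theme_parents:
        for term in dag.active_terms():
            if any(p in theme_parents for p, _ in term.parents):
                nearby.add(term.term_id)
    pool: set[str] = set()
    for term_id in nearby:
        pool |= direct_by_term.get(term_id, set())
    return pool


def _edge_score(rng: np.random.Generator) -> float:
    # uniform in (0.9, 1.0]
    return 1.0 - rng.random() * 0.1


def generate_ppi(dag: OntologyDAG, corpus: AnnotationCorpus,
                 coherence: float = 0.9, n_interactors_a: int = 20,
                 n_interactors_b: int = 25, n_common: int = 3,
                 hub: bool = True, n_background_edges: int = 100,
                 seed: int = 0) -> tuple[PPINetwork, TruthRecord]:
    """Two-seed PPI network with planted coherent interactor sets.

    Interactors are corpus genes: with probability ``coherence`` drawn from
    the shared theme neighbourhood, else uniformly.  ``n_common`` of them
    are wired to both seeds.  The optional hub is wired to the second seed
    and every common interactor; background edges avoid the seeds and never
    give a decoy more than two anchor links, so the planted hub uniquely
    maximises anchor adjacency.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0, 1]")
    if n_common > min(n_interactors_a, n_interactors_b):
        raise ValueError("n_common exceeds an interactor set size")
    total = n_interactors_a + n_interactors_b - n_common
    universe = sorted(corpus.universe)
    if total > len(universe):
        raise ValueError("corpus universe too small for the requested sets")
    rng = np.random.default_rng(seed)

    direct_by_term: dict[str, set[str]] = defaultdict(set)
    for gene, terms in corpus.direct.items():
        for term_id in terms:
            direct_by_term[term_id].add(gene)

    # shared theme: first shuffled non-root term whose neighbourhood is big
    # enough; fall back to the largest neighbourhood otherwise
    theme = None
    pool: set[str] = set()
    candidates = [t.term_id for t in dag.active_terms()
                  if t.parents]  # non-root
    candidates.sort()
    rng.shuffle(candidates)
    best: tuple[int, str] | None = None
    for term_id in candidates:
        candidate_pool = _theme_pool(dag, direct_by_term, term_id)
        if len(candidate_pool) >= total:
            theme, pool = term_id, candidate_pool
            break
        if best is None or len(candidate_pool) > best[0]:
            best = (len(candidate_pool), term_id)
    if theme is None:
        theme = best[1] if best else None
        pool = (_theme_pool(dag, direct_by_term, theme) if theme else set())
        logger.warning("theme neighbourhood smaller than the interactor "
                       "demand; coherent draws will be topped up uniformly")

    chosen: list[str] = []
    chosen_set: set[str] = set()
    pool_sorted = sorted(pool)
    while len(chosen) < total:
        if coherence > 0.0 and rng.random() < coherence:
            options = [g for g in pool_sorted if g not in chosen_set]
            if not options:
                options = [g for g in universe if g not in chosen_set]
        else:
            options = [g for g in universe if g not in chosen_set]
        pick = options[int(rng.integers(len(options)))]
        chosen.append(pick)
        chosen_set.add(pick)

    common = chosen[:n_common]
    a_only = chosen[n_common:n_interactors_a]
    b_only = chosen[n_interactors_a:]
    set_a = frozenset(common) | frozenset(a_only)
    set_b = frozenset(common) | frozenset(b_only)

    net = PPINetwork()
    for gene in sorted(set_a):
        net.add_edge(SEED_A, gene, _edge_score(rng))
    for gene in sorted(set_b):
        net.add_edge(SEED_B, gene, _edge_score(rng))

    anchors = frozenset(common) | {SEED_B}
    hub_id = None
    if hub:
        hub_id = HUB_ID
        net.add_edge(hub_id, SEED_B, _edge_score(rng))
        for gene in sorted(common):
            net.add_edge(hub_id, gene, _edge_score(rng))
        # the hub is, by construction, itself an interactor of seed B
        set_b = set_b | {hub_id}

    # background noise: random edges among interactors plus extra bystander
    # genes; never incident to a seed or the hub, and capped at two anchor
    # links per decoy so the hub stays the unique top mediator
    extra = [g for g in universe if g not in chosen_set]
    rng.shuffle(extra)
    node_pool = sorted(chosen_set | set(extra[:max(total, 30)]))
    # count anchor adjacency already wired (e.g. a B-interactor's edge to
    # the seed) so the <=2 cap applies to the total, not just the noise
    anchor_links: dict[str, int] = defaultdict(int)
    for node in node_pool:
        anchor_links[node] = len(net.interactors(node) & anchors)
    added = 0
    attempts = 0
    while added < n_background_edges and attempts < 20 * n_background_edges:
        attempts += 1
        i, j = rng.integers(len(node_pool)), rng.integers(len(node_pool))
        a, b = node_pool[int(i)], node_pool[int(j)]
        if a == b or net.score(a, b) is not None:
            continue
        if (b in anchors and anchor_links[a] >= 2) or \
           (a in anchors and anchor_links[b] >= 2):
            continue
        net.add_edge(a, b, _edge_score(rng))
        if b in anchors:
            anchor_links[a] += 1
        if a in anchors:
            anchor_links[b] += 1
        added += 1

    truth = TruthRecord(
        seed_proteins=(SEED_A, SEED_B),
        planted_common=frozenset(common),
        planted_hub=hub_id,
        coherence=coherence,
        interactors_a=set_a,
        interactors_b=set_b,
        theme_term=theme,
    )
    return net, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(n_genes: int = 200, n_case: int = 10,
                        n_control: int = 10, de_gene_effect: float = 2.0,
                        seed: int = 0, genes: list[str] | None = None,
                        de_gene: str | None = None
                        ) -> tuple[ExpressionMatrix, TruthRecord]:
    """Gaussian expression matrix with one planted shifted gene.

    Background values are i.i.d. Normal(0, 1); the designated gene (first
    gene by default) is shifted by ``de_gene_effect`` sigma in cases.  An
    effect of 0 plants nothing.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups need at least one sample")
    if genes is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    if not genes:
        raise ValueError("need at least one gene")
    if de_gene_effect != 0.0:
        if de_gene is None:
            de_gene = genes[0]
        elif de_gene not in genes:
            raise ValueError(f"de_gene {de_gene!r} not among the genes")
    else:
        de_gene = None
    rng = np.random.default_rng(seed)
    samples = ([f"case{i:02d}" for i in range(n_case)]
               + [f"ctrl{i:02d}" for i in range(n_control)])
    values = rng.normal(size=(len(genes), len(samples)))
    if de_gene is not None:
        values[genes.index(de_gene), :n_case] += de_gene_effect
    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    truth = TruthRecord(de_gene=de_gene, effect_size=de_gene_effect)
    return ExpressionMatrix(values=frame, groups=groups), truth


# ---------------------------------------------------------------------------
# Writers (exact dialects the parsers consume)
# ---------------------------------------------------------------------------

def write_obo(dag: OntologyDAG, path: str | os.PathLike) -> None:
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(dag.terms):
        term = dag.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        if term.name:
            lines.append(f"name: {term.name}")
        lines.append(
            f"namespace: {_NAMESPACE_LONG.get(term.namespace, term.namespace)}")
        for parent_id, relation in term.parents:
            if relation == IS_A:
                lines.append(f"is_a: {parent_id}")
            else:
                lines.append(f"relationship: part_of {parent_id}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_annotations(direct: dict[str, frozenset[str] | set[str]],
                      path: str | os.PathLike) -> None:
    lines = ["gene\tterm_id"]
    for gene in sorted(direct):
        for term_id in sorted(direct[gene]):
            lines.append(f"{gene}\t{term_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_string_links(net: PPINetwork, path: str | os.PathLike) -> None:
    lines = ["protein1\tprotein2\tcombined_score"]
    lines += [f"{a}\t{b}\t{score:.6f}" for a, b, score in net.edges()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_expression(expr: ExpressionMatrix, expr_path: str | os.PathLike,
                     groups_path: str | os.PathLike) -> None:
    expr.values.to_csv(expr_path, sep="\t", float_format="%.8g")
    lines = [f"{sample}\t{expr.groups[sample]}" for sample in expr.samples]
    Path(groups_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth(truth: TruthRecord, path: str | os.PathLike) -> None:
    Path(path).write_text(truth.to_json() + "\n", encoding="utf-8")


def _child_seeds(seed: int, count: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(count)
    return [int(s % (2 ** 31)) for s in state]


def simulate_study(outdir: str | os.PathLike, seed: int = 0,
                   n_terms: int = 200, n_genes: int = 300,
                   mean_annots: float = 4.0, coherence: float = 0.9,
                   n_interactors_a: int = 20, n_interactors_b: int = 25,
                   n_common: int = 3, hub: bool = True,
                   n_background_edges: int = 150, de_effect: float = 2.0,
                   n_case: int = 10, n_control: int = 10) -> dict:
    """Emit a complete, mutually consistent synthetic study to ``outdir``.

    Writes the ontology, annotations, PPI edge list, expression matrix,
    group file, the merged truth record and a ready-to-run pipeline config.
    The planted hub doubles as the differentially expressed gene, mirroring
    the mediator-confirmation step.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag_seed, corpus_seed, ppi_seed, expr_seed = _child_seeds(seed, 4)
    dag = generate_dag(n_terms, seed=dag_seed)
    corpus = generate_corpus(dag, n_genes, mean_annots=mean_annots,
                             seed=corpus_seed)
    net, ppi_truth = generate_ppi(
        dag, corpus, coherence=coherence, n_interactors_a=n_interactors_a,
        n_interactors_b=n_interactors_b, n_common=n_common, hub=hub,
        n_background_edges=n_background_edges, seed=ppi_seed)
    expr_genes = sorted(corpus.universe)
    de_gene = None
    if hub and de_effect != 0.0:
        expr_genes.append(HUB_ID)
        de_gene = HUB_ID
    expr, expr_truth = generate_expression(
        n_case=n_case, n_control=n_control, de_gene_effect=de_effect,
        seed=expr_seed, genes=expr_genes, de_gene=de_gene)
    truth = TruthRecord(
        seed_proteins=ppi_truth.seed_proteins,
        planted_common=ppi_truth.planted_common,
        planted_hub=ppi_truth.planted_hub,
        coherence=coherence,
        de_gene=expr_truth.de_gene,
        effect_size=expr_truth.effect_size,
        interactors_a=ppi_truth.interactors_a,
        interactors_b=ppi_truth.interactors_b,
        theme_term=ppi_truth.theme_term,
    )
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "ppi": outdir / "ppi.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    write_obo(dag, paths["ontology"])
    write_annotations(corpus.direct, paths["annotations"])
    write_string_links(net, paths["ppi"])
    write_expression(expr, paths["expression"], paths["groups"])
    write_truth(truth, paths["truth"])
    config_lines = [
        f"ontology: {paths['ontology']}",
        f"annotations: {paths['annotations']}",
        f"ppi: {paths['ppi']}",
        f"expression: {paths['expression']}",
        f"groups: {paths['groups']}",
        f"seed_protein_a: {SEED_A}",
        f"seed_protein_b: {SEED_B}",
        "cutoffs: [0.9, 0.95]",
        "namespace: BP",
        "n_reps: 200",
        f"seed: {seed}",
        f"outdir: {outdir / 'report'}",
    ]
    paths["config"].write_text("\n".join(config_lines) + "\n",
                               encoding="utf-8")
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "dag": dag, "corpus": corpus, "network": net, "expression": expr}
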