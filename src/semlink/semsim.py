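"""Term-, gene- and set-level GO semantic similarity under five measures.

Four measures are information-content based and score a term pair through
its most informative common ancestor (MICA), with IC(MICA) = m and
p_m = exp(-m):

    resnik  m / max_ic                    (max-IC normalised to [0, 1])
    lin     2m / (IC1 + IC2)              (1 when t1 = t2)
    jiang   1 - min(1, IC1 + IC2 - 2m)    (distance-to-similarity transform)
    rel     lin * (1 - p_m)               (Schlicker's relevance weighting)

The fifth ("wang") is graph-based: each term spreads a semantic
contribution S over its ancestor closure, discounted per edge by a
relation-specific weight (is_a 0.8, part_of 0.6), and two terms are
compared by the overlap of their S-profiles.

Gene-level similarity is the best-match average (BMA) over the term-pair
matrix of the two genes' annotation sets; the set-level Semantic Similarity
Score (SSS) is the BMA over the gene-pair matrix of two gene sets.
"""

from __future__ import annotations

import io
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationCorpus, ICTable, OntologyDAG, IS_A, PART_OF

logger = logging.getLogger(__name__)

#: The five supported measures.
METHODS: tuple[str, ...] = ("resnik", "lin", "jiang", "rel", "wang")
IC_METHODS: frozenset[str] = frozenset({"resnik", "lin", "jiang", "rel"})

#: Matrix-to-scalar combination rules (best-match average is the default).
COMBINE_RULES: tuple[str, ...] = ("bma", "max", "avg", "rcmax")


@dataclass(frozen=True)
class WangWeights:
    """Semantic-contribution factors of the graph-based measure."""

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for w in (self.w_is_a, self.w_part_of):
            if not 0.0 < w < 1.0:
                raise ValueError(f"edge weight {w} outside (0, 1)")

    def weight(self, relation: str) -> float:
        return self.w_is_a if relation == IS_A else self.w_part_of


DEFAULT_WANG_WEIGHTS = WangWeights()


# ---------------------------------------------------------------------------
# Term-level similarity
# ---------------------------------------------------------------------------

def mica(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms.

    Ancestor closures include the terms themselves, so a term subsuming the
    other (or t1 == t2) can be its own MICA.  Ties on IC are broken by the
    lexicographically smallest term id.
    """
    common = dag.closure(t1) & dag.closure(t2)
    scored = [(term, ic.ic[term]) for term in common if term in ic.ic]
    if not scored:
        raise ValueError(f"no common ancestor with defined IC for "
                         f"{t1!r} and {t2!r} (cross-namespace?)")
    best_ic = max(value for _, value in scored)
    best_term = min(term for term, value in scored if value == best_ic)
    return best_term, best_ic


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def term_sim_ic(dag: OntologyDAG, ic: ICTable, t1: str, t2: str,
                method: str) -> float:
    """IC-based term similarity (resnik / lin / jiang / rel), in [0, 1]."""
    if method not in IC_METHODS:
        raise ValueError(f"unknown IC method {method!r}")
    for term in (t1, t2):
        if term not in ic.ic:
            raise ValueError(f"term unannotated: {term!r}")
    _, m = mica(dag, ic, t1, t2)
    ic1, ic2 = ic.ic[t1], ic.ic[t2]
    if method == "resnik":
        value = m / ic.max_ic if ic.max_ic > 0 else 0.0
    elif method == "jiang":
        value = 1.0 - min(1.0, ic1 + ic2 - 2.0 * m)
    else:  # lin or rel
        if t1 == t2:
            lin = 1.0
        elif ic1 + ic2 == 0.0:
            lin = 0.0
        else:
            lin = 2.0 * m / (ic1 + ic2)
        value = lin if method == "lin" else lin * (1.0 - math.exp(-m))
    return _clip01(value)


def _wang_svalues(dag: OntologyDAG, term: str, weights: WangWeights
                  ) -> dict[str, float]:
    """S-values of a term over its ancestor closure (closure includes term).

    S_t(t) = 1; for an ancestor a, S_t(a) = max over children c of a inside
    the closure of w(a->c) * S_t(c), i.e. the best weight-discounted path
    down to t.
    """
    closure = dag.closure(term)
    svalues: dict[str, float] = {term: 1.0}

    def sval(node: str) -> float:
        known = svalues.get(node)
        if known is not None:
            return known
        best = 0.0
        for child_id, relation in dag.children(node):
            if child_id in closure:
                candidate = weights.weight(relation) * sval(child_id)
                if candidate > best:
                    best = candidate
        svalues[node] = best
        return best

    for node in closure:
        sval(node)
    return svalues


def term_sim_wang(dag: OntologyDAG, t1: str, t2: str,
                  weights: WangWeights = DEFAULT_WANG_WEIGHTS) -> float:
    """Graph-based term similarity: overlap of S-value profiles, in [0, 1].

    Disjoint ancestor closures (cross-namespace terms) score 0 rather than
    raising.
    """
    s1 = _wang_svalues(dag, t1, weights)
    s2 = _wang_svalues(dag, t2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    numerator = sum(s1[a] + s2[a] for a in common)
    denominator = sum(s1.values()) + sum(s2.values())
    return _clip01(numerator / denominator)


# ---------------------------------------------------------------------------
# Matrix combination
# ---------------------------------------------------------------------------

def bma(matrix) -> float:
    """Best-match average of a similarity matrix.

    (sum of row maxima + sum of column maxima) / (n_rows + n_cols).
    """
    return combine(matrix, "bma")


def combine(matrix, rule: str = "bma") -> float:
    """Collapse an n x m similarity matrix to a scalar.

    ``bma`` is the default throughout; ``max``, ``avg`` and ``rcmax`` are
    exposed as alternatives.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("combine requires a non-empty 2-D matrix")
    if rule == "bma":
        return float((m.max(axis=1).sum() + m.max(axis=0).sum())
                     / (m.shape[0] + m.shape[1]))
    if rule == "max":
        return float(m.max())
    if rule == "avg":
        return float(m.mean())
    if rule == "rcmax":
        return float(max(m.max(axis=1).mean(), m.max(axis=0).mean()))
    raise ValueError(f"unknown combine rule {rule!r}")


def _bma_small(rows: list[list[float]]) -> float:
    # pure-python BMA for the small term-level matrices on the hot path
    n = len(rows)
    m = len(rows[0])
    total = sum(max(row) for row in rows)
    for j in range(m):
        best = 0.0
        for row in rows:
            if row[j] > best:
                best = row[j]
        total += best
    return total / (n + m)


# ---------------------------------------------------------------------------
# Engine: caches for one (DAG, IC, method) context
# ---------------------------------------------------------------------------

class SimilarityEngine:
    """Caches term- and gene-level similarities for one analysis context.

    One engine binds a DAG, an IC table (required for IC-based methods), a
    method and a namespace.  Gene-level results are keyed by annotation-term
    tuples, so an engine must not be shared across corpora whose gene ids
    map to different annotations.  Engines hold no random state; reusing one
    never affects reproducibility.
    """

    def __init__(self, dag: OntologyDAG, ic: ICTable | None = None,
                 method: str = "wang",
                 weights: WangWeights = DEFAULT_WANG_WEIGHTS,
                 namespace: str | None = None,
                 combine_rule: str = "bma"):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        if method in IC_METHODS and ic is None:
            raise ValueError(f"method {method!r} requires an IC table")
        if combine_rule not in COMBINE_RULES:
            raise ValueError(f"unknown combine rule {combine_rule!r}")
        self.dag = dag
        self.ic = ic
        self.method = method
        self.weights = weights
        self.namespace = namespace if namespace is not None else (
            ic.namespace if ic is not None else None)
        self.combine_rule = combine_rule
        self._term_cache: dict[tuple[str, str], float] = {}
        self._pair_cache: dict[tuple, float] = {}
        self._sval_cache: dict[str, dict[str, float]] = {}
        self._gene_terms: dict[str, tuple[str, ...] | None] = {}

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        value = self._term_cache.get(key)
        if value is None:
            if self.method == "wang":
                s1 = self._svalues(t1)
                s2 = self._svalues(t2)
                common = s1.keys() & s2.keys()
                if not common:
                    value = 0.0
                else:
                    value = _clip01(sum(s1[a] + s2[a] for a in common)
                                    / (sum(s1.values()) + sum(s2.values())))
            else:
                value = term_sim_ic(self.dag, self.ic, t1, t2, self.method)
            self._term_cache[key] = value
        return value

    def _svalues(self, term: str) -> dict[str, float]:
        cached = self._sval_cache.get(term)
        if cached is None:
            cached = _wang_svalues(self.dag, term, self.weights)
            self._sval_cache[term] = cached
        return cached

    def usable_terms(self, terms: Iterable[str]) -> tuple[str, ...]:
        """Sorted subset of ``terms`` the method can score.

        Namespace-filtered; IC-based methods additionally require a defined
        IC (annotated term).
        """
        kept = []
        for t in terms:
            term = self.dag.terms.get(t)
            if term is None or term.obsolete:
                continue
            if self.namespace is not None and term.namespace != self.namespace:
                continue
            if self.method in IC_METHODS and t not in self.ic.ic:
                continue
            kept.append(t)
        return tuple(sorted(kept))

    def corpus_terms(self, corpus: AnnotationCorpus, gene: str
                     ) -> tuple[str, ...] | None:
        """Usable annotation terms of a gene, cached; None if unusable."""
        if gene in self._gene_terms:
            return self._gene_terms[gene]
        terms = self.usable_terms(corpus.direct.get(gene, ()))
        result = terms if terms else None
        self._gene_terms[gene] = result
        return result

    def gene_sim(self, terms_a: Sequence[str], terms_b: Sequence[str]) -> float:
        """BMA term-matrix similarity between two annotation-term tuples."""
        if not terms_a or not terms_b:
            raise ValueError("gene similarity requires non-empty term sets")
        ta, tb = tuple(terms_a), tuple(terms_b)
        key = (ta, tb) if ta <= tb else (tb, ta)
        value = self._pair_cache.get(key)
        if value is None:
            rows = [[self.term_sim(x, y) for y in tb] for x in ta]
            if self.combine_rule == "bma":
                value = _bma_small(rows)
            else:
                value = combine(rows, self.combine_rule)
            self._pair_cache[key] = value
        return value


def gene_sim(terms_a: Iterable[str], terms_b: Iterable[str], method: str,
             dag: OntologyDAG, ic: ICTable | None = None,
             weights: WangWeights = DEFAULT_WANG_WEIGHTS) -> float:
    """Gene-level similarity: BMA over the term-pair similarity matrix."""
    engine = SimilarityEngine(dag, ic, method, weights)
    return engine.gene_sim(tuple(sorted(terms_a)), tuple(sorted(terms_b)))


# ---------------------------------------------------------------------------
# Set-level similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityResult:
    """Gene x gene similarity matrix between two sets plus its SSS summary.

    ``sss`` is the best-match average of ``matrix`` (rows: set A genes,
    columns: set B genes).  Genes lacking usable annotations were dropped;
    their ids are kept for the record.
    """

    method: str
    matrix: np.ndarray
    sss: float
    set_a: list[str]
    set_b: list[str]
    dropped_a: tuple[str, ...] = ()
    dropped_b: tuple[str, ...] = ()

    def to_tsv(self, target: str | os.PathLike | IO[str] | None = None
               ) -> str | None:
        """Write the matrix as a heatmap-ready TSV with gene headers."""
        frame = pd.DataFrame(self.matrix, index=self.set_a, columns=self.set_b)
        if target is None:
            buffer = io.StringIO()
            frame.to_csv(buffer, sep="\t", float_format="%.6g")
            return buffer.getvalue()
        frame.to_csv(target, sep="\t", float_format="%.6g")
        return None

    def summary_dict(self, cutoff: float | None = None) -> dict:
        summary = {
            "method": self.method,
            "cutoff": cutoff,
            "sss": self.sss,
            "n_a": len(self.set_a),
            "n_b": len(self.set_b),
            "dropped_a": len(self.dropped_a),
            "dropped_b": len(self.dropped_b),
        }
        return summary

    def to_json(self, cutoff: float | None = None) -> str:
        return json.dumps(self.summary_dict(cutoff), sort_keys=True)


def _ordered_unique(genes: Iterable[str]) -> list[str]:
    if isinstance(genes, (set, frozenset)):
        return sorted(genes)
    return list(dict.fromkeys(genes))


def set_sim(set_a: Iterable[str], set_b: Iterable[str],
            corpus: AnnotationCorpus, dag: OntologyDAG | None = None,
            ic: ICTable | None = None, method: str = "wang", *,
            namespace: str | None = None,
            weights: WangWeights = DEFAULT_WANG_WEIGHTS,
            combine_rule: str = "bma",
            engine: SimilarityEngine | None = None) -> SimilarityResult:
    """Set-to-set similarity: SSS = BMA over the gene-pair matrix.

    Genes without usable annotations are dropped (logged with a count);
    unordered inputs are sorted for determinism.  Shared genes may appear in
    both sets — no de-overlapping is performed.
    """
    if engine is None:
        engine = SimilarityEngine(dag if dag is not None else corpus.dag,
                                  ic, method, weights, namespace=namespace,
                                  combine_rule=combine_rule)

    def usable(genes: Iterable[str], label: str
               ) -> tuple[list[str], list[tuple[str, ...]], tuple[str, ...]]:
        kept_genes, kept_terms, dropped = [], [], []
        for gene in _ordered_unique(genes):
            terms = engine.corpus_terms(corpus, gene)
            if terms is None:
                dropped.append(gene)
            else:
                kept_genes.append(gene)
                kept_terms.append(terms)
        if dropped:
            logger.info("set %s: dropped %d unannotated gene(s)",
                        label, len(dropped))
        return kept_genes, kept_terms, tuple(dropped)

    genes_a, terms_a, dropped_a = usable(set_a, "A")
    genes_b, terms_b, dropped_b = usable(set_b, "B")
    if not genes_a or not genes_b:
        raise ValueError("all genes unannotated on one side; "
                         "cannot compute set similarity")
    matrix = np.empty((len(genes_a), len(genes_b)))
    for i, ta in enumerate(terms_a):
        row = matrix[i]
        for j, tb in enumerate(terms_b):
            row[j] = engine.gene_sim(ta, tb)
    return SimilarityResult(
        method=engine.method, matrix=matrix,
        sss=combine(matrix, engine.combine_rule),
        set_a=genes_a, set_b=genes_b,
        dropped_a=dropped_a, dropped_b=dropped_b,
    )
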