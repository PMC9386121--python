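"""Monte Carlo significance for an observed set-to-set similarity score.

The null replaces one or both gene sets with uniformly drawn same-size sets
from the annotated universe and recomputes the SSS.  The empirical p-value
is the fraction of random scores STRICTLY greater than the observed score
(so p = 0 is attainable); an optional add-one (Phipson–Smyth) correction is
available but off by default.

Reproducibility: one root seed; each randomization mode draws from its own
deterministic substream, ``SeedSequence(seed, spawn_key=(mode_index,))``,
so the three modes are mutually independent yet each is identical whether
run alone or through :func:`run_all_modes`.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from .ontology import AnnotationCorpus, ICTable, OntologyDAG
from .semsim import (DEFAULT_WANG_WEIGHTS, SimilarityEngine, WangWeights,
                     set_sim)

logger = logging.getLogger(__name__)

#: Randomization modes, in substream order.
MODES: tuple[str, ...] = ("randomize_a", "randomize_b", "randomize_both")


def empirical_p(random_scores: Sequence[float], observed: float,
                add_one: bool = False) -> float:
    """Fraction of random scores strictly greater than the observed one."""
    scores = np.asarray(random_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empirical p requires at least one random score")
    exceed = int(np.count_nonzero(scores > observed))
    if add_one:
        return (exceed + 1) / (scores.size + 1)
    return exceed / scores.size


def sample_random_set(universe: Iterable[str], size: int,
                      rng: np.random.Generator) -> frozenset[str]:
    """Uniform sample of ``size`` genes without replacement.

    The universe is sorted before drawing so the result depends only on its
    contents and the generator state.
    """
    pool = universe if isinstance(universe, list) else sorted(universe)
    if size > len(pool):
        raise ValueError(f"requested {size} genes from a universe of "
                         f"{len(pool)}")
    if size == 0:
        return frozenset()
    idx = rng.choice(len(pool), size=size, replace=False)
    return frozenset(pool[i] for i in idx)


@dataclass
class MCResult:
    """Observed SSS, its resampled null scores, and the empirical p-value."""

    observed_sss: float
    mode: str
    random_scores: np.ndarray
    p_value: float
    n_reps: int
    seed: int
    method: str = "wang"

    def to_dict(self) -> dict:
        return {
            "observed_sss": self.observed_sss,
            "mode": self.mode,
            "p_value": self.p_value,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "method": self.method,
            "null_mean": float(np.mean(self.random_scores)),
            "null_sd": float(np.std(self.random_scores)),
        }

    def to_json(self, include_scores: bool = False) -> str:
        payload = self.to_dict()
        if include_scores:
            payload["random_scores"] = [float(s) for s in self.random_scores]
        return json.dumps(payload, sort_keys=True)

    def scores_tsv(self, target: str | os.PathLike | IO[str] | None = None
                   ) -> str | None:
        """One-column TSV of the random scores (density-plot ready)."""
        text = "sss\n" + "".join(f"{s:.6g}\n" for s in self.random_scores)
        if target is None:
            return text
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w", encoding="utf-8") as handle:
                handle.write(text)
        return None


def _mode_rng(seed: int, mode: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(MODES.index(mode),)))


def mc_significance(set_a: Iterable[str], set_b: Iterable[str],
                    universe: Iterable[str], corpus: AnnotationCorpus,
                    dag: OntologyDAG | None = None,
                    ic: ICTable | None = None, method: str = "wang",
                    mode: str = "randomize_both", n_reps: int = 1000,
                    seed: int = 0, *,
                    namespace: str | None = None,
                    weights: WangWeights = DEFAULT_WANG_WEIGHTS,
                    add_one: bool = False,
                    engine: SimilarityEngine | None = None) -> MCResult:
    """Monte Carlo p-value for the similarity of two gene sets.

    Per repetition the selected set(s) are replaced by uniform same-size
    draws from ``universe`` and the SSS is recomputed.  Passing a shared
    ``engine`` reuses similarity caches across calls without affecting the
    result.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    set_a = list(_sorted_unique(set_a))
    set_b = list(_sorted_unique(set_b))
    pool = sorted(universe)
    if len(pool) < max(len(set_a), len(set_b)):
        raise ValueError("universe smaller than an observed set")
    if engine is None:
        engine = SimilarityEngine(dag if dag is not None else corpus.dag,
                                  ic, method, weights, namespace=namespace)
    observed = set_sim(set_a, set_b, corpus, engine=engine).sss
    rng = _mode_rng(seed, mode)
    scores = np.empty(n_reps)
    for rep in range(n_reps):
        rand_a = (sample_random_set(pool, len(set_a), rng)
                  if mode in ("randomize_a", "randomize_both") else set_a)
        rand_b = (sample_random_set(pool, len(set_b), rng)
                  if mode in ("randomize_b", "randomize_both") else set_b)
        scores[rep] = set_sim(rand_a, rand_b, corpus, engine=engine).sss
    return MCResult(
        observed_sss=observed, mode=mode, random_scores=scores,
        p_value=empirical_p(scores, observed, add_one=add_one),
        n_reps=n_reps, seed=seed, method=engine.method,
    )


def run_all_modes(set_a: Iterable[str], set_b: Iterable[str],
                  universe: Iterable[str], corpus: AnnotationCorpus,
                  dag: OntologyDAG | None = None, ic: ICTable | None = None,
                  method: str = "wang", n_reps: int = 1000, seed: int = 0,
                  **kwargs) -> dict[str, MCResult]:
    """Run :func:`mc_significance` for all three randomization modes.

    Deterministic per seed; each mode's result is identical to running it
    alone with the same root seed.
    """
    return {mode: mc_significance(set_a, set_b, universe, corpus, dag, ic,
                                  method, mode, n_reps, seed, **kwargs)
            for mode in MODES}


def _sorted_unique(genes: Iterable[str]) -> list[str]:
    if isinstance(genes, (set, frozenset)):
        return sorted(genes)
    return list(dict.fromkeys(genes))
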