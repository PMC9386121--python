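"""Model/Results interface for the gene-set functional-similarity analysis.

:class:`GeneSetSimilarity` binds two gene sets to an annotation corpus (or
extracts the sets from a PPI network as the interactors of two seed
proteins); :meth:`GeneSetSimilarity.fit` computes the semantic similarity
score under the requested measures and its Monte Carlo significance under
the requested randomization modes, returning a
:class:`GeneSetSimilarityResults` with a summary table.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import PPINetwork
from .ontology import AnnotationCorpus, ICTable, compute_ic
from .resampling import MODES, MCResult, mc_significance
from .semsim import (DEFAULT_WANG_WEIGHTS, IC_METHODS, METHODS,
                     SimilarityEngine, SimilarityResult, WangWeights,
                     set_sim)

logger = logging.getLogger(__name__)


class GeneSetSimilarity:
    """Functional-similarity model for two gene sets.

    Parameters
    ----------
    set_a, set_b
        The gene sets to compare (e.g. the interactor sets of two seed
        proteins).  Shared genes may appear in both sets.
    corpus
        Annotation corpus; its DAG and namespace define the similarity
        substrate and the default resampling universe.
    namespace
        Ontology namespace used throughout (default BP).
    universe
        Optional resampling universe override (e.g. the network node set);
        defaults to all genes annotated in the namespace.
    """

    def __init__(self, set_a: Iterable[str], set_b: Iterable[str],
                 corpus: AnnotationCorpus, namespace: str = "BP",
                 wang_weights: WangWeights = DEFAULT_WANG_WEIGHTS,
                 universe: Iterable[str] | None = None):
        self.set_a = sorted(set(set_a))
        self.set_b = sorted(set(set_b))
        if not self.set_a or not self.set_b:
            raise ValueError("both gene sets must be nonempty")
        self.corpus = corpus
        self.namespace = namespace
        self.wang_weights = wang_weights
        self.universe = (sorted(set(universe)) if universe is not None
                         else sorted(corpus.annotated_genes(namespace)))
        self.seed_proteins: tuple[str, str] | None = None
        self._ic: ICTable | None = None

    @classmethod
    def from_network(cls, network: PPINetwork, seed_a: str, seed_b: str,
                     corpus: AnnotationCorpus, **kwargs
                     ) -> "GeneSetSimilarity":
        """Build the model from the interactor sets of two seed proteins."""
        model = cls(network.interactors(seed_a), network.interactors(seed_b),
                    corpus, **kwargs)
        model.seed_proteins = (seed_a, seed_b)
        return model

    @property
    def ic(self) -> ICTable:
        if self._ic is None:
            self._ic = compute_ic(self.corpus, self.namespace)
        return self._ic

    def fit(self, methods: Sequence[str] = METHODS,
            modes: Sequence[str] = MODES, n_reps: int = 1000,
            seed: int = 0) -> "GeneSetSimilarityResults":
        """Compute SSS per method and Monte Carlo p-values per mode."""
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        unknown = set(modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")
        similarities: dict[str, SimilarityResult] = {}
        mc: dict[tuple[str, str], MCResult] = {}
        for method in methods:
            ic = self.ic if method in IC_METHODS else None
            engine = SimilarityEngine(self.corpus.dag, ic, method,
                                      self.wang_weights,
                                      namespace=self.namespace)
            similarities[method] = set_sim(self.set_a, self.set_b,
                                           self.corpus, engine=engine)
            for mode in modes:
                mc[(method, mode)] = mc_significance(
                    self.set_a, self.set_b, self.universe, self.corpus,
                    method=method, mode=mode, n_reps=n_reps, seed=seed,
                    engine=engine)
        return GeneSetSimilarityResults(
            model=self, similarities=similarities, mc=mc,
            methods=tuple(methods), modes=tuple(modes), n_reps=n_reps,
            seed=seed)


class GeneSetSimilarityResults:
    """Fitted similarity scores, their resampled nulls and p-values."""

    def __init__(self, model: GeneSetSimilarity,
                 similarities: dict[str, SimilarityResult],
                 mc: dict[tuple[str, str], MCResult],
                 methods: tuple[str, ...], modes: tuple[str, ...],
                 n_reps: int, seed: int):
        self.model = model
        self.similarities = similarities
        self.mc = mc
        self.methods = methods
        self.modes = modes
        self.n_reps = n_reps
        self.seed = seed

    def sss(self, method: str) -> float:
        return self.similarities[method].sss

    def p_value(self, method: str, mode: str = "randomize_both") -> float:
        return self.mc[(method, mode)].p_value

    def summary_frame(self) -> pd.DataFrame:
        """One row per method: SSS, set sizes, per-mode p and null mean."""
        rows = []
        for method in self.methods:
            sim = self.similarities[method]
            row = {
                "method": method,
                "sss": sim.sss,
                "n_a": len(sim.set_a),
                "n_b": len(sim.set_b),
            }
            for mode in self.modes:
                result = self.mc[(method, mode)]
                row[f"p[{mode}]"] = result.p_value
                row[f"null_mean[{mode}]"] = float(
                    np.mean(result.random_scores))
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")

    def summary(self) -> str:
        """Human-readable summary table."""
        frame = self.summary_frame()
        header = ("Gene-set functional similarity "
                  f"(namespace {self.model.namespace}, "
                  f"n_reps={self.n_reps}, seed={self.seed})")
        if self.model.seed_proteins:
            a, b = self.model.seed_proteins
            header += f"\nseed proteins: {a} vs {b}"
        rule = "=" * max(len(line) for line in header.splitlines())
        return f"{header}\n{rule}\n{frame.to_string(float_format='%.4f')}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GeneSetSimilarityResults methods={self.methods} "
                f"modes={self.modes} n_reps={self.n_reps}>")
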