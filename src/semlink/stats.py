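"""Differential expression and gene-set over-representation statistics.

The mediator-confirmation step is a Wilcoxon rank-sum (Mann–Whitney U) test
of a candidate gene's expression between a case and a control group —
rank-based, so the pipeline is agnostic to expression units.  Interactor
sets are additionally characterised by hypergeometric over-representation
of ontology terms with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationCorpus

logger = logging.getLogger(__name__)

ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}

#: Largest |x|*|y| for which the exact null distribution of U is used.
EXACT_LIMIT = 400


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a two-group design.

    ``groups`` maps every sample to ``case`` or ``control``; both groups
    must be nonempty and the matrix may not contain missing values.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        labels = {self.groups[s] for s in self.values.columns}
        bad = labels - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if labels != {"case", "control"}:
            raise ValueError("both case and control groups must be nonempty")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]

    def gene_values(self, gene: str, label: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"unknown gene {gene!r}")
        return self.values.loc[gene, self.group_samples(label)].to_numpy(float)


def load_expression(expr_source: str | os.PathLike | IO[str],
                    groups_source: str | os.PathLike | IO[str]
                    ) -> ExpressionMatrix:
    """Read an expression TSV (gene id column + sample header) and a
    two-column ``sample<TAB>group`` file."""
    values = pd.read_csv(expr_source, sep="\t", index_col=0)
    groups_frame = pd.read_csv(groups_source, sep="\t", header=None,
                               names=["sample", "group"], comment="#")
    if list(groups_frame.iloc[0]) == ["sample", "group"]:
        groups_frame = groups_frame.iloc[1:]
    groups = dict(zip(groups_frame["sample"], groups_frame["group"]))
    return ExpressionMatrix(values=values, groups=groups)


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                     alternative: str = "two_sided") -> tuple[float, float]:
    """Mann–Whitney U test with midrank ties.

    Exact p when |x|*|y| <= 400 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (U for x, p).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        # every observation tied: U at its null mean, no evidence either way
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if not has_ties and x.size * y.size <= EXACT_LIMIT
              else "asymptotic")
    result = sps.mannwhitneyu(x, y, alternative=ALTERNATIVES[alternative],
                              method=method, use_continuity=True)
    return float(result.statistic), float(result.pvalue)


def diff_expression(expr: ExpressionMatrix, gene: str,
                    alternative: str = "two_sided"
                    ) -> tuple[float, float, int]:
    """Case-vs-control rank-sum test for one gene.

    Returns (U, p, direction) with direction the sign of the case-minus-
    control median difference.
    """
    case = expr.gene_values(gene, "case")
    control = expr.gene_values(gene, "control")
    u, p = wilcoxon_ranksum(case, control, alternative)
    direction = int(np.sign(np.median(case) - np.median(control)))
    return u, p, direction


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, never below raw)."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result.

    k of the n set genes are annotated to the term (propagated), against K
    of the N universe genes; ``p`` is the hypergeometric upper tail
    P(X >= k) and ``p_adj`` its BH adjustment across tested terms.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float


def enrich_hypergeometric(gene_set: Iterable[str], corpus: AnnotationCorpus,
                          min_term_size: int = 3) -> list[EnrichmentRow]:
    """Hypergeometric ORA of a gene set against the corpus universe.

    Terms with propagated universe count below ``min_term_size`` are not
    tested.  Rows sorted by p ascending, ties by term id.
    """
    usable = sorted(set(gene_set) & corpus.universe)
    dropped = len(set(gene_set)) - len(usable)
    if dropped:
        logger.info("enrichment: dropped %d gene(s) outside the universe",
                    dropped)
    if not usable:
        raise ValueError("no usable genes in the set for enrichment")
    n = len(usable)
    N = len(corpus.universe)
    usable_set = set(usable)
    tested: list[tuple[str, int, int, float]] = []
    for term_id in sorted(corpus.propagated_counts):
        K = corpus.propagated_counts[term_id]
        if K < min_term_size:
            continue
        k = len(usable_set & corpus.term_genes.get(term_id, frozenset()))
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        tested.append((term_id, k, K, p))
    adjusted = adjust_bh([p for _, _, _, p in tested])
    rows = [EnrichmentRow(term_id=t, k=k, K=K, n=n, N=N, p=p,
                          p_adj=float(q))
            for (t, k, K, p), q in zip(tested, adjusted)]
    rows.sort(key=lambda row: (row.p, row.term_id))
    return rows


def enrichment_tsv(rows: Sequence[EnrichmentRow],
                   target: str | os.PathLike | IO[str] | None = None
                   ) -> str | None:
    """Write enrichment rows as a TSV table."""
    lines = ["term_id\tk\tK\tn\tN\tp\tp_adj"]
    lines += [f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t"
              f"{r.p_adj:.6g}" for r in rows]
    text = "\n".join(lines) + "\n"
    if target is None:
        return text
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as handle:
            handle.write(text)
    return None
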