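"""Rank tests, correlation and multiplicity control used throughout.

Thin, contract-enforcing wrappers around scipy; all p-values two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "spearman",
    "bh_adjust",
    "compare_gene_by_group",
    "resolve_gene_alias",
    "significance_stars",
    "GENE_ALIASES",
]

#: Protein-name aliases for immune-checkpoint genes.
GENE_ALIASES: Mapping[str, str] = {
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "PD-L1": "CD274",
    "PDL1": "CD274",
    "CTLA-4": "CTLA4",
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    df: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite test statistic")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi-square(k-1).

    All-identical data yields H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("each group needs at least 1 observation")
    n = int(sum(a.size for a in arrays))
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", n, df=len(groups) - 1)
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), "kruskal_wallis", n, df=len(groups) - 1)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U (rank-sum) test.

    Exact enumeration for small tie-free samples (n <= 25 per group),
    normal approximation with tie/continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if not ties and max(x.size, y.size) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_rank_sum", x.size + y.size)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def resolve_gene_alias(gene: str, universe: Sequence[str]) -> str:
    """Map protein-style checkpoint names onto the expression universe."""
    if gene in universe:
        return gene
    alias = GENE_ALIASES.get(gene) or GENE_ALIASES.get(gene.upper())
    if alias is not None and alias in universe:
        return alias
    candidates = [alias] if alias else []
    raise KeyError(
        f"gene {gene!r} not in expression matrix"
        + (f"; tried aliases {candidates}" if candidates else "")
    )


def compare_gene_by_group(
    expr: ExpressionMatrix,
    gene: str,
    groups: Mapping[str, str] | pd.Series,
) -> tuple[TestResult, pd.DataFrame]:
    """Test one gene's expression across sample groups.

    Uses the rank-sum test for 2 groups and Kruskal-Wallis for >= 3;
    alias names (PD-1, PD-L1, CTLA-4) are resolved automatically.

    Returns the test result plus per-group summaries (n, median, mean).
    """
    groups = pd.Series(groups)
    symbol = resolve_gene_alias(gene, expr.gene_ids)
    missing = groups.index.difference(expr.sample_ids)
    if len(missing):
        raise KeyError(f"group labels for unknown samples: {missing.tolist()}")
    vals = expr.values.loc[symbol, groups.index]
    by = [vals[groups == g].to_numpy() for g in sorted(groups.unique())]
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    if len(by) == 2:
        res = wilcoxon_rank_sum(by[0], by[1])
    else:
        res = kruskal_wallis(by)
    summary = pd.DataFrame(
        {
            "group": sorted(groups.unique()),
            "n": [len(v) for v in by],
            "median": [float(np.median(v)) for v in by],
            "mean": [float(np.mean(v)) for v in by],
        }
    ).set_index("group")
    return res, summary
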