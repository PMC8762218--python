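"""Resampling-based consensus clustering with CDF/delta-area k selection.

For each candidate k, samples are repeatedly subsampled and clustered;
the consensus matrix records, for every sample pair, the fraction of
co-sampled resamples in which the pair co-clustered. The number of
clusters is chosen from the change in area under the consensus CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .stats import kruskal_wallis

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "cdf_delta_area",
    "cluster_expression_summary",
]

# Elbow threshold for the relative delta-area rule. Over-partitioned
# k-means keeps adding ~0.10 relative area per extra k on structureless
# data, so the cutoff must sit clearly above that floor.
DELTA_AREA_THRESHOLD = 0.25


@dataclass
class ConsensusResult:
    """Output of :func:`consensus_cluster`."""

    consensus_matrices: dict[int, pd.DataFrame]
    cdf_per_k: dict[int, tuple[np.ndarray, np.ndarray]]
    delta_area_per_k: dict[int, float]
    selected_k: int
    partition: pd.Series
    n_resamples: int
    subsample_fraction: float
    base_method: str
    seed: int
    partitions_per_k: dict[int, pd.Series] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.partition.value_counts().sort_index()


def _base_cluster(X: np.ndarray, k: int, method: str, rng: np.random.Generator) -> np.ndarray:
    if method == "kmeans":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-cluster warnings on tiny resamples
            _, labels = kmeans2(X, k, minit="++", seed=rng, iter=30)
        return labels
    if method == "hierarchical":
        Z = linkage(X, method="average")
        return fcluster(Z, t=k, criterion="maxclust")
    raise ValueError(f"unknown base_method {method!r}")


def consensus_cluster(
    features: pd.DataFrame | ExpressionMatrix,
    k_range: Sequence[int] = range(2, 7),
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    base_method: str = "kmeans",
    seed: int = 0,
    standardize: bool = True,
    delta_area_threshold: float = DELTA_AREA_THRESHOLD,
) -> ConsensusResult:
    """Consensus-cluster samples and select k by the delta-area elbow.

    Parameters
    ----------
    features
        Samples x features matrix, or an :class:`ExpressionMatrix`
        (genes x samples; transposed and z-scored per gene internally).
    k_range
        Candidate cluster counts, each in [2, n_samples - 1].
    n_resamples, subsample_fraction
        Number of subsampling rounds and the fraction of samples drawn
        (without replacement) per round.
    base_method
        'kmeans' (on standardized features) or 'hierarchical'
        (average linkage).
    standardize
        Z-score each feature before clustering so high-variance features
        do not dominate distances.

    Notes
    -----
    Resample ``r`` at a given k uses a generator keyed on ``seed ^ r``,
    so reruns with the same seed are identical.
    """
    if isinstance(features, ExpressionMatrix):
        mat = features.values.T
    else:
        mat = pd.DataFrame(features)
    sample_ids = mat.index
    X = mat.to_numpy(dtype=float)
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    ks = sorted(int(k) for k in k_range)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if n < ks[-1] + 1:
        raise ValueError("need at least k_max + 1 samples")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    m_sub = max(ks[-1] + 1, int(round(subsample_fraction * n)))
    matrices: dict[int, pd.DataFrame] = {}
    partitions: dict[int, pd.Series] = {}
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for r in range(n_resamples):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed ^ r, spawn_key=(k,)))
            idx = rng.choice(n, size=m_sub, replace=False)
            labels = _base_cluster(X[idx], k, base_method, rng)
            co_sample[np.ix_(idx, idx)] += 1
            for lab in np.unique(labels):
                members = idx[labels == lab]
                co_cluster[np.ix_(members, members)] += 1
        never = (co_sample == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            raise RuntimeError(
                "some sample pairs were never co-sampled; increase n_resamples "
                "or subsample_fraction"
            )
        with np.errstate(invalid="ignore"):
            M = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        matrices[k] = pd.DataFrame(M, index=sample_ids, columns=sample_ids)
        partitions[k] = _cut_consensus(M, k, sample_ids)

    cdf_per_k, delta_area, selected_k = cdf_delta_area(matrices, threshold=delta_area_threshold)
    return ConsensusResult(
        consensus_matrices=matrices,
        cdf_per_k=cdf_per_k,
        delta_area_per_k=delta_area,
        selected_k=selected_k,
        partition=partitions[selected_k],
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        base_method=base_method,
        seed=seed,
        partitions_per_k=partitions,
    )


def _cut_consensus(M: np.ndarray, k: int, sample_ids: pd.Index) -> pd.Series:
    # final partition: average-linkage cut of the consensus dissimilarity
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=sample_ids, name="cluster")


def _cdf_and_area(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    xs = np.sort(values)
    grid = np.concatenate([[0.0], np.unique(xs), [1.0]])
    cdf = np.searchsorted(xs, grid, side="right") / xs.size
    area = float(np.sum(np.diff(grid) * cdf[:-1]))
    return grid, cdf, area


def cdf_delta_area(
    consensus_matrices: Mapping[int, pd.DataFrame],
    threshold: float = DELTA_AREA_THRESHOLD,
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], dict[int, float], int]:
    """Consensus CDFs, relative delta-area per k and the selected k.

    A(k) is the area under the empirical CDF of the upper-triangle
    consensus values. Delta(k_min) = A(k_min); for subsequent k,
    Delta(k) = (A(k) - A(k-1)) / A(k-1). The selected k is the largest
    one whose delta-area stays above ``threshold`` (elbow rule).
    """
    ks = sorted(consensus_matrices)
    if len(ks) == 1:
        warnings.warn("single k supplied; selection is trivial", stacklevel=2)
    cdf_per_k: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    for k in ks:
        M = consensus_matrices[k].to_numpy()
        iu = np.triu_indices(M.shape[0], 1)
        grid, cdf, area = _cdf_and_area(M[iu])
        cdf_per_k[k] = (grid, cdf)
        areas[k] = area
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    above = [k for k in ks if delta[k] >= threshold]
    selected = above[-1] if above else ks[0]
    return cdf_per_k, delta, selected


def cluster_expression_summary(
    expr: ExpressionMatrix,
    partition: pd.Series,
    genes: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster medians plus a Kruskal-Wallis test for each gene.

    Genes absent from the matrix are skipped (returned separately), not
    fatal. Output has one row per (gene, cluster).
    """
    missing = partition.index.difference(expr.sample_ids)
    if len(missing):
        raise KeyError(f"partition labels for unknown samples: {missing.tolist()}")
    found = [g for g in genes if g in expr.gene_ids]
    skipped = [g for g in genes if g not in expr.gene_ids]
    clusters = sorted(partition.unique())
    rows = []
    for gene in found:
        vals = expr.values.loc[gene, partition.index]
        by = [vals[partition == c].to_numpy() for c in clusters]
        res = kruskal_wallis(by)
        for c, v in zip(clusters, by):
            rows.append(
                {
                    "gene": gene,
                    "cluster": c,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "cluster", "n", "median", "statistic", "p_value"])
    return table, skipped
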