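"""Single-sample gene-set scoring.

The rank-based running-sum score used here follows the single-sample
enrichment construction: within one sample, genes are ranked by
expression; walking down the ranked list, in-set genes contribute
rank-weighted increments and out-of-set genes uniform decrements, and
the score is the sum of the running-sum deviations over all positions.
Stromal/immune scoring reuses the same engine on two signatures, with
the combined score defined as their exact sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust, kruskal_wallis, significance_stars

__all__ = [
    "EnrichmentScores",
    "EstimateScores",
    "ssgsea_score",
    "estimate_scores",
    "pathway_activity",
    "immune_landscape_table",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_OVERLAP = 5


@dataclass
class EnrichmentScores:
    """Samples x signatures matrix of single-sample enrichment values."""

    scores: pd.DataFrame
    method: str
    alpha: float
    normalized: bool
    dropped_sets: list[str]

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class EstimateScores:
    """Per-sample stromal, immune and combined enrichment scores.

    The combined score is the exact sum of the two components; high
    values indicate heavy stromal/immune infiltration (low purity).
    """

    table: pd.DataFrame  # columns: stromal_score, immune_score, estimate_score

    def __post_init__(self) -> None:
        expected = self.table["stromal_score"] + self.table["immune_score"]
        if not np.array_equal(expected.to_numpy(), self.table["estimate_score"].to_numpy()):
            raise ValueError("estimate_score must equal stromal_score + immune_score")


def _single_sample_scores(
    x: np.ndarray,
    gene_index: pd.Index,
    memberships: dict[str, np.ndarray],
    alpha: float,
) -> dict[str, float]:
    """Running-sum scores of one sample for each gene set.

    ``memberships`` maps set name -> boolean mask over ``gene_index``.
    """
    n = x.size
    if np.all(x == x[0]):
        raise ValueError("sample has all-tied expression; ranking undefined")
    ranks = rankdata(x)  # ascending, ties averaged: highest expression ~ n
    order = np.argsort(-x, kind="stable")
    weights = np.abs(ranks[order]) ** alpha
    out: dict[str, float] = {}
    for name, mask in memberships.items():
        in_set = mask[order]
        n_in = int(in_set.sum())
        w_in = np.where(in_set, weights, 0.0)
        denom = w_in.sum()
        step = w_in / denom - (~in_set) / (n - n_in)
        out[name] = float(np.cumsum(step).sum())
    return out


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    normalize: bool = True,
) -> EnrichmentScores:
    """Score every sample against every gene set.

    Parameters
    ----------
    alpha
        Rank-weight exponent (0 gives unweighted steps).
    min_overlap
        Sets with fewer than this many genes in the expression universe
        are dropped (logged), not scored.
    normalize
        If True, divide the whole score matrix by its (max - min),
        putting scores of different signatures on a shared scale.

    Scores depend on expression only through within-sample ranks, so any
    monotone per-sample transform leaves them unchanged.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = expr.gene_ids
    memberships: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, members in sets:
        mask = np.asarray(genes.isin(members))
        n_in = int(mask.sum())
        if n_in < min_overlap or n_in == len(genes):
            dropped.append(name)
            logger.warning(
                "gene set %r dropped (overlap %d, min %d)", name, n_in, min_overlap
            )
            continue
        memberships[name] = mask
    if not memberships:
        raise ValueError("no gene set passed the minimum-overlap filter")
    values = expr.values.to_numpy(dtype=float)
    rows = []
    for j, sample in enumerate(expr.sample_ids):
        rows.append(_single_sample_scores(values[:, j], genes, memberships, alpha))
    scores = pd.DataFrame(rows, index=expr.sample_ids)[list(memberships)]
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return EnrichmentScores(
        scores=scores,
        method="ssgsea",
        alpha=alpha,
        normalized=normalize,
        dropped_sets=dropped,
    )


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EstimateScores:
    """Stromal + immune single-sample scores and their exact sum."""
    coll = GeneSetCollection(
        {"stromal": list(stromal_set), "immune": list(immune_set)}, category="custom"
    )
    enr = ssgsea_score(expr, coll, alpha=alpha, min_overlap=min_overlap, normalize=False)
    if enr.dropped_sets:
        raise ValueError(f"signature(s) below minimum overlap: {enr.dropped_sets}")
    table = pd.DataFrame(
        {
            "stromal_score": enr.scores["stromal"],
            "immune_score": enr.scores["immune"],
        }
    )
    table["estimate_score"] = table["stromal_score"] + table["immune_score"]
    return EstimateScores(table)


def pathway_activity(
    expr: ExpressionMatrix,
    pathway_sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EnrichmentScores:
    """Per-sample pathway scores for downstream cluster contrasts.

    Served by the same single-sample running-sum engine used for the
    immune signatures.
    """
    return ssgsea_score(expr, pathway_sets, alpha=alpha, min_overlap=min_overlap, normalize=True)


def immune_landscape_table(scores: EnrichmentScores, partition: pd.Series) -> pd.DataFrame:
    """Compare each signature's scores across sample clusters.

    Returns one row per signature with per-cluster medians, the
    Kruskal-Wallis p, its BH-adjusted value and significance stars
    (* <0.05, ** <0.01, *** <0.001 on the adjusted p).
    """
    partition = pd.Series(partition)
    missing = partition.index.difference(scores.sample_ids)
    if len(missing):
        raise KeyError(f"partition labels for unknown samples: {missing.tolist()}")
    clusters = sorted(partition.unique())
    rows = []
    for name in scores.signature_names:
        vals = scores.scores.loc[partition.index, name]
        by = [vals[partition == c].to_numpy() for c in clusters]
        res = kruskal_wallis(by)
        row: dict = {"signature": name}
        for c, v in zip(clusters, by):
            row[f"median_cluster_{c}"] = float(np.median(v))
        row["statistic"] = res.statistic
        row["p_value"] = res.p_value
        rows.append(row)
    table = pd.DataFrame(rows).set_index("signature")
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    table["stars"] = [significance_stars(p) for p in table["p_adj"]]
    return table
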