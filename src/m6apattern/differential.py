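"""Cluster-contrast DEG screening with empirical-Bayes variance
moderation, and univariate proportional-hazards screening of the DEGs
down to a prognostic panel.

The moderation follows the standard hierarchical model for gene-wise
residual variances: s2_g ~ s2 * chisq(d_g)/d_g with a scaled-inverse-
chisquare prior (d0, s0^2) estimated by moment matching on log s2_g
(trigamma inversion), giving the posterior variance
stilde2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g) used in the moderated F.

The univariate Cox screen uses a vectorized Newton solver (Efron ties)
so thousands of genes fit in seconds; it is validated against lifelines
in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

from .io import CohortClinical, ExpressionMatrix
from .stats import bh_adjust

__all__ = [
    "DegResult",
    "PrognosticPanel",
    "moderated_anova",
    "select_degs",
    "cox_screen",
    "univariate_cox_batch",
]

logger = logging.getLogger(__name__)

DEG_P_THRESHOLD = 1e-4
COX_P_THRESHOLD = 1e-3


@dataclass
class DegResult:
    """Moderated one-way ANOVA results per gene."""

    table: pd.DataFrame  # index gene; columns: F, p, p_adj, mean_cluster_*
    d0: float
    s0_squared: float
    residual_df: float
    excluded_genes: list[str] = field(default_factory=list)


@dataclass
class PrognosticPanel:
    """Genes surviving the univariate Cox screen."""

    table: pd.DataFrame  # index gene; columns: beta, hr, p
    p_threshold: float
    full_table: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __post_init__(self) -> None:
        if len(self.table) and not (self.table["p"] < self.p_threshold).all():
            raise ValueError("panel contains genes above the p threshold")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances."""
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_anova(expr: ExpressionMatrix, partition: pd.Series) -> DegResult:
    """Empirical-Bayes moderated one-way ANOVA of every gene across
    sample clusters.

    Expression should be on log scale. Genes with zero variance across
    all samples are excluded (logged). Returns per-gene moderated F,
    raw p from F(k-1, d0 + d_g), BH-adjusted p and per-cluster means.
    """
    partition = pd.Series(partition)
    missing = partition.index.difference(expr.sample_ids)
    if len(missing):
        raise KeyError(f"partition labels for unknown samples: {missing.tolist()}")
    clusters = sorted(partition.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    sizes = partition.value_counts()
    if (sizes < 2).any():
        raise ValueError("every cluster needs >= 2 samples")
    X = expr.values[partition.index].to_numpy(dtype=float)  # genes x n
    n = X.shape[1]
    k = len(clusters)
    total_var = X.var(axis=1)
    keep = total_var > 0
    excluded = expr.gene_ids[~keep].tolist()
    if excluded:
        logger.warning("%d zero-variance genes excluded", len(excluded))
    X = X[keep]
    genes = expr.gene_ids[keep]

    group_masks = [(partition == c).to_numpy() for c in clusters]
    counts = np.array([m.sum() for m in group_masks])
    means = np.stack([X[:, m].mean(axis=1) for m in group_masks], axis=1)  # g x k
    grand = X.mean(axis=1)
    ssb = ((means - grand[:, None]) ** 2 * counts[None, :]).sum(axis=1)
    # residual SS: subtract each sample's group mean
    fitted = np.zeros_like(X)
    for j, m in enumerate(group_masks):
        fitted[:, m] = means[:, [j]]
    rss = ((X - fitted) ** 2).sum(axis=1)
    d = float(n - k)
    s2 = rss / d
    d0, s0_sq = _fit_variance_prior(s2, d)
    d0_eff = min(d0, 1e7)
    s2_post = (d0_eff * s0_sq + d * s2) / (d0_eff + d)
    F = (ssb / (k - 1)) / s2_post
    p = sps.f.sf(F, k - 1, d0_eff + d)
    table = pd.DataFrame({"F": F, "p": p}, index=genes)
    table["p_adj"] = bh_adjust(p)
    for j, c in enumerate(clusters):
        table[f"mean_cluster_{c}"] = means[:, j]
    return DegResult(
        table=table,
        d0=d0,
        s0_squared=s0_sq,
        residual_df=d,
        excluded_genes=excluded,
    )


def select_degs(result: DegResult, p_threshold: float = DEG_P_THRESHOLD) -> list[str]:
    """Genes whose raw moderated-F p falls below the threshold."""
    return result.table.index[result.table["p"] < p_threshold].tolist()


# ---------------------------------------------------------------------------
# univariate Cox screening


def univariate_cox_batch(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Fit an independent univariate Cox model per column of X.

    Newton-Raphson on the Efron partial likelihood, vectorized across
    columns. Covariates are standardized internally for stability and
    the coefficients mapped back to the original scale. Returns a frame
    with columns beta, se, z, p, converged (one row per column).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, g = X.shape
    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[order]

    sd = X_s.std(axis=0, ddof=0)
    valid = sd > 0
    Z = np.where(valid[None, :], (X_s - X_s.mean(axis=0)) / np.where(valid, sd, 1.0), 0.0)

    uniq_times = np.unique(t_s[e_s == 1])
    first_risk = np.searchsorted(t_s, uniq_times, side="left")
    death_blocks = [np.flatnonzero((t_s == t) & (e_s == 1)) for t in uniq_times]

    beta = np.zeros(g)
    converged = np.zeros(g, dtype=bool)
    se = np.full(g, np.nan)
    for _ in range(max_iter):
        eta = np.clip(Z * beta[None, :], -200, 200)
        w = np.exp(eta)
        wz = w * Z
        wzz = wz * Z
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum(wz[::-1], axis=0)[::-1]
        S2 = np.cumsum(wzz[::-1], axis=0)[::-1]
        U = np.zeros(g)
        info = np.zeros(g)
        for fr, deaths in zip(first_risk, death_blocks):
            d_count = deaths.size
            s0, s1, s2 = S0[fr], S1[fr], S2[fr]
            dz = Z[deaths]
            D0 = w[deaths].sum(axis=0)
            D1 = wz[deaths].sum(axis=0)
            D2 = wzz[deaths].sum(axis=0)
            U += dz.sum(axis=0)
            for l in range(d_count):
                f = l / d_count
                den = s0 - f * D0
                num1 = s1 - f * D1
                num2 = s2 - f * D2
                r = num1 / den
                U -= r
                info += num2 / den - r * r
        step = np.where(info > 0, U / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta_new = beta + step
        done = np.abs(step) < tol
        beta = beta_new
        if done.all():
            converged[:] = True
            break
    else:
        converged = np.abs(step) < 1e-4
    eta = np.clip(Z * beta[None, :], -200, 200)
    # final information for standard errors
    w = np.exp(eta)
    wz = w * Z
    wzz = wz * Z
    S0 = np.cumsum(w[::-1], axis=0)[::-1]
    S1 = np.cumsum(wz[::-1], axis=0)[::-1]
    S2 = np.cumsum(wzz[::-1], axis=0)[::-1]
    info = np.zeros(g)
    for fr, deaths in zip(first_risk, death_blocks):
        d_count = deaths.size
        s0, s1, s2 = S0[fr], S1[fr], S2[fr]
        D0 = w[deaths].sum(axis=0)
        D1 = wz[deaths].sum(axis=0)
        D2 = wzz[deaths].sum(axis=0)
        for l in range(d_count):
            f = l / d_count
            den = s0 - f * D0
            num1 = s1 - f * D1
            num2 = s2 - f * D2
            r = num1 / den
            info += num2 / den - r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        se_std = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
    # back to original covariate scale
    beta_orig = np.where(valid, beta / np.where(valid, sd, 1.0), np.nan)
    se = np.where(valid, se_std / np.where(valid, sd, 1.0), np.nan)
    converged = converged & valid & np.isfinite(se)
    z = beta_orig / se
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"beta": beta_orig, "se": se, "z": z, "p": p, "converged": converged}
    )


def cox_screen(
    expr: ExpressionMatrix,
    clinical: CohortClinical,
    genes: list[str],
    p_threshold: float = COX_P_THRESHOLD,
) -> PrognosticPanel:
    """Univariate proportional-hazards screen over a gene list.

    Each gene's continuous (log-scale) expression is fit as the single
    covariate; genes with Wald p < ``p_threshold`` form the panel.
    Non-converged fits are dropped with a warning.
    """
    missing = [gn for gn in genes if gn not in expr.gene_ids]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    clin = clinical.aligned_to(list(expr.sample_ids))
    X = expr.values.loc[genes].to_numpy(dtype=float).T  # samples x genes
    res = univariate_cox_batch(clin.os_time, clin.os_event, X)
    res.index = pd.Index(genes, name="gene")
    bad = res.index[~res["converged"]].tolist()
    if bad:
        logger.warning("%d gene(s) dropped for non-convergence: %s", len(bad), bad[:10])
    ok = res[res["converged"]].copy()
    ok["hr"] = np.exp(ok["beta"])
    full = ok[["beta", "se", "hr", "z", "p"]]
    kept = full[full["p"] < p_threshold]
    return PrognosticPanel(
        table=kept[["beta", "hr", "p"]].copy(),
        p_threshold=p_threshold,
        full_table=full,
    )
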