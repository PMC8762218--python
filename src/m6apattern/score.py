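"""PCA-based per-sample signature score over the prognostic gene panel,
its survival dichotomization, and the downstream integrations (external
projection, mutation burden, clinical covariates, regulator network).

The score of a sample is the sum of its projections on the first two
principal components of the (z-scored) panel-gene expression — the
GGI-style construction. Component signs are oriented deterministically
(the largest-|loading| gene of each component is made positive), so
reruns are bit-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import PrognosticPanel, univariate_cox_batch
from .io import CohortClinical, ExpressionMatrix, MutationTable
from .registry import RegulatorRegistry
from .stats import bh_adjust, spearman
from .survival import CutpointResult, cox_fit, optimal_cutpoint, survival_by_groups

__all__ = [
    "ScoreResult",
    "TmbProfile",
    "RegulatorNetwork",
    "compute_m6ascore",
    "dichotomize_score",
    "independent_prognostic_analysis",
    "validate_external",
    "tmb_integration",
    "regulator_network",
    "attribute_flow_table",
]

logger = logging.getLogger(__name__)

EXOME_MB = 38.0


@dataclass
class ScoreResult:
    """Per-sample two-component PCA score and the trained projection."""

    scores: pd.DataFrame  # index sample; columns pc1_score, pc2_score, m6ascore
    loadings: pd.DataFrame  # index gene; columns pc1, pc2 (unit norm)
    variance_explained: np.ndarray  # fraction per component
    center: pd.Series
    scale: pd.Series
    z_scored: bool
    orientation: tuple[bool, bool]  # whether each component was sign-flipped
    group: pd.Series | None = None  # 'high' / 'low', set by dichotomize_score
    cutoff: float | None = None

    @property
    def m6ascore(self) -> pd.Series:
        return self.scores["m6ascore"]


@dataclass
class TmbProfile:
    """Per-sample non-silent mutation burden and its grouping."""

    table: pd.DataFrame  # index sample; columns: count[, per_mb], tmb_group
    cutpoint: CutpointResult

    def __post_init__(self) -> None:
        if (self.table["count"] < 0).any():
            raise ValueError("mutation counts must be >= 0")


@dataclass
class RegulatorNetwork:
    """Regulator co-expression edges plus per-gene prognosis classes."""

    nodes: pd.DataFrame  # index symbol; columns: role, prognosis, present
    edges: pd.DataFrame  # columns: gene_a, gene_b, rho, p_adj, sign
    adj_p_threshold: float


def compute_m6ascore(
    expr: ExpressionMatrix,
    panel: PrognosticPanel | list[str],
    z_score: bool = True,
) -> ScoreResult:
    """Score each sample as the sum of its PC1 and PC2 projections over
    the panel genes.

    Panel-gene expression is centered (and, by default, z-scored) across
    samples; the components come from an SVD of the sample x gene
    matrix. At least 3 panel genes must be present and carry variance.
    """
    genes = panel.genes if isinstance(panel, PrognosticPanel) else list(panel)
    present = [g for g in genes if g in expr.gene_ids]
    if len(present) < 3:
        raise ValueError(
            f"need >= 3 panel genes in the expression matrix; found {len(present)}"
        )
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples")
    M = expr.values.loc[present].T  # samples x genes
    sd = M.std(axis=0, ddof=1)
    usable = sd[sd > 0].index.tolist()
    if len(usable) < len(present):
        logger.warning("dropping %d zero-variance panel genes", len(present) - len(usable))
    if len(usable) < 3:
        raise ValueError("panel carries no variance (fewer than 3 non-constant genes)")
    M = M[usable]
    center = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1) if z_score else pd.Series(1.0, index=M.columns)
    Xc = (M - center) / scale
    U, S, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    loadings = Vt[:2].T.copy()  # genes x 2
    flipped = [False, False]
    for c in range(2):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
            flipped[c] = True
    proj = Xc.to_numpy() @ loadings
    total_var = float((S**2).sum())
    var_exp = (S[:2] ** 2 / total_var) if total_var > 0 else np.zeros(2)
    scores = pd.DataFrame(
        {
            "pc1_score": proj[:, 0],
            "pc2_score": proj[:, 1],
        },
        index=expr.sample_ids,
    )
    scores["m6ascore"] = scores["pc1_score"] + scores["pc2_score"]
    return ScoreResult(
        scores=scores,
        loadings=pd.DataFrame(loadings, index=usable, columns=["pc1", "pc2"]),
        variance_explained=np.asarray(var_exp),
        center=center,
        scale=scale,
        z_scored=z_score,
        orientation=(flipped[0], flipped[1]),
    )


def dichotomize_score(
    score: ScoreResult,
    clinical: CohortClinical,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Split samples at the survival-optimal score cutoff and contrast
    the two groups (KM + log-rank).

    The group labels and cutoff are recorded on the ScoreResult. The
    naive log-rank p ignores cutoff selection; pass ``n_permutations``
    for a selection-corrected permutation p.
    """
    clin = clinical.aligned_to(list(score.scores.index))
    marker = score.m6ascore.to_numpy()
    cut = optimal_cutpoint(
        marker,
        clin.os_time,
        clin.os_event,
        minprop=minprop,
        n_permutations=n_permutations,
        seed=seed,
    )
    group = pd.Series(
        np.where(marker <= cut.cutoff, "low", "high"),
        index=score.scores.index,
        name="group",
    )
    score.group = group
    score.cutoff = cut.cutoff
    km = survival_by_groups(clin.os_time, clin.os_event, group.to_numpy())
    return {"groups": group, "cutpoint": cut, "km": km}


_GENDER_CODES = {"female": 0.0, "male": 1.0}


def _covariate_frame(clinical: CohortClinical, samples: pd.Index) -> pd.DataFrame:
    tbl = clinical.table.loc[samples]
    cov = pd.DataFrame(index=samples)
    cov["age"] = pd.to_numeric(tbl.get("age"), errors="coerce")
    cov["gender"] = tbl.get("gender").map(_GENDER_CODES) if "gender" in tbl else np.nan
    cov["grade"] = pd.to_numeric(tbl.get("grade"), errors="coerce")
    cov["stage"] = pd.to_numeric(tbl.get("stage"), errors="coerce")
    return cov


def independent_prognostic_analysis(score: ScoreResult, clinical: CohortClinical) -> dict:
    """Univariate and multivariate proportional-hazards assessments of
    the score.

    The multivariate model includes age, gender, grade, stage and the
    score (complete-case); hazard ratios are per unit of score, with no
    internal rescaling.
    """
    samples = score.scores.index
    clin = clinical.aligned_to(list(samples))
    uni = cox_fit(
        clin.os_time,
        clin.os_event,
        pd.DataFrame({"m6ascore": score.m6ascore.to_numpy()}, index=samples),
    )
    cov = _covariate_frame(clinical, samples)
    cov["m6ascore"] = score.m6ascore
    complete = cov.dropna()
    if len(complete) < len(cov):
        logger.warning(
            "multivariate model uses %d/%d complete cases", len(complete), len(cov)
        )
    clin_cc = clinical.aligned_to(list(complete.index))
    multi = cox_fit(clin_cc.os_time, clin_cc.os_event, complete)
    return {"univariate": uni, "multivariate": multi, "n_complete": len(complete)}


def validate_external(
    score_model: ScoreResult,
    expr_external: ExpressionMatrix,
    clinical_external: CohortClinical,
    minprop: float = 0.1,
) -> dict:
    """Project a held-out cohort through the trained components and
    repeat the survival contrast.

    Loadings, centering and scaling are frozen from training; only the
    dichotomization cutoff is re-estimated on the external cohort. At
    least 3 trained panel genes must be present; the coverage fraction
    is logged when genes are missing.
    """
    trained = score_model.loadings.index
    present = [g for g in trained if g in expr_external.gene_ids]
    missing = [g for g in trained if g not in expr_external.gene_ids]
    if len(present) < 3:
        raise ValueError(f"external cohort shares only {len(present)} panel genes; missing: {missing}")
    coverage = len(present) / len(trained)
    if missing:
        logger.warning("external panel coverage %.2f; missing genes: %s", coverage, missing)
    M = expr_external.values.loc[present].T
    Xc = (M - score_model.center[present]) / score_model.scale[present]
    proj = Xc.to_numpy() @ score_model.loadings.loc[present].to_numpy()
    scores = pd.DataFrame(
        {"pc1_score": proj[:, 0], "pc2_score": proj[:, 1]},
        index=expr_external.sample_ids,
    )
    scores["m6ascore"] = scores["pc1_score"] + scores["pc2_score"]
    clin = clinical_external.aligned_to(list(scores.index))
    cut = optimal_cutpoint(scores["m6ascore"].to_numpy(), clin.os_time, clin.os_event, minprop=minprop)
    group = pd.Series(
        np.where(scores["m6ascore"] <= cut.cutoff, "low", "high"),
        index=scores.index,
        name="group",
    )
    km = survival_by_groups(clin.os_time, clin.os_event, group.to_numpy())
    return {
        "scores": scores,
        "groups": group,
        "cutpoint": cut,
        "km": km,
        "coverage": coverage,
        "missing_genes": missing,
    }


def tmb_integration(
    score: ScoreResult,
    muts: MutationTable,
    clinical: CohortClinical,
    per_mb: bool = False,
    minprop: float = 0.1,
) -> dict:
    """Correlate the score with non-silent mutation burden and stratify
    survival jointly by burden and score group.

    Samples without any mutation record are excluded (logged). Requires
    ``dichotomize_score`` to have been run (score groups present).
    """
    if score.group is None:
        raise ValueError("run dichotomize_score first (score groups are required)")
    ns = muts.non_silent()
    counts = ns.groupby("sample_id").size()
    samples = score.scores.index.intersection(counts.index)
    excluded = score.scores.index.difference(counts.index)
    if len(excluded):
        logger.warning("%d sample(s) without mutation data excluded", len(excluded))
    if len(samples) < 10:
        raise ValueError("too few samples with mutation data")
    clin = clinical.aligned_to(list(samples))
    burden = counts.loc[samples].astype(int)
    rho, p = spearman(score.m6ascore.loc[samples].to_numpy(), burden.to_numpy())
    cut = optimal_cutpoint(
        burden.to_numpy().astype(float), clin.os_time, clin.os_event, minprop=minprop
    )
    tmb_group = pd.Series(
        np.where(burden <= cut.cutoff, "lowTMB", "highTMB"), index=samples, name="tmb_group"
    )
    table = pd.DataFrame({"count": burden, "tmb_group": tmb_group})
    if per_mb:
        table["per_mb"] = table["count"] / EXOME_MB
    profile = TmbProfile(table=table, cutpoint=cut)
    joint = tmb_group + "/" + score.group.loc[samples]
    km = survival_by_groups(clin.os_time, clin.os_event, joint.to_numpy())
    tmb_km = survival_by_groups(clin.os_time, clin.os_event, tmb_group.to_numpy())
    return {
        "profile": profile,
        "spearman_rho": rho,
        "spearman_p": p,
        "tmb_km": tmb_km,
        "joint_km": km,
        "joint_groups": joint,
    }


def regulator_network(
    expr: ExpressionMatrix,
    clinical: CohortClinical,
    registry: RegulatorRegistry,
    adj_p_threshold: float = 0.05,
    prognosis_p: float = 0.05,
) -> RegulatorNetwork:
    """Pairwise regulator co-expression network with per-gene prognosis
    classes.

    Edges keep pairs whose Spearman correlation survives BH adjustment
    below ``adj_p_threshold``. Each present regulator is classified by a
    univariate proportional-hazards fit: risk (HR > 1), protective
    (HR < 1) at ``prognosis_p``, otherwise ns.
    """
    present = [g for g in registry.symbols if g in expr.gene_ids]
    absent = [g for g in registry.symbols if g not in expr.gene_ids]
    if absent:
        logger.warning("regulators absent from expression: %s", absent)
    clin = clinical.aligned_to(list(expr.sample_ids))
    X = expr.values.loc[present]
    rows = []
    for a, b in itertools.combinations(present, 2):
        rho, p = spearman(X.loc[a].to_numpy(), X.loc[b].to_numpy())
        rows.append({"gene_a": a, "gene_b": b, "rho": rho, "p": p})
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = bh_adjust(pairs["p"].to_numpy())
    edges = pairs[pairs["p_adj"] < adj_p_threshold].copy()
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    edges = edges[["gene_a", "gene_b", "rho", "p_adj", "sign"]].reset_index(drop=True)

    fit = univariate_cox_batch(
        clin.os_time, clin.os_event, X.to_numpy(dtype=float).T
    )
    fit.index = pd.Index(present)
    prognosis = pd.Series("ns", index=pd.Index(registry.symbols, name="symbol"), dtype=object)
    for g in present:
        if not fit.loc[g, "converged"] or not fit.loc[g, "p"] < prognosis_p:
            continue
        prognosis[g] = "risk" if fit.loc[g, "beta"] > 0 else "protective"
    nodes = registry.as_frame()
    nodes["prognosis"] = prognosis
    nodes["present"] = nodes.index.isin(present)
    nodes.loc[~nodes["present"], "prognosis"] = "absent"
    return RegulatorNetwork(nodes=nodes, edges=edges, adj_p_threshold=adj_p_threshold)


def attribute_flow_table(
    m6aclusters: pd.Series,
    gene_clusters: pd.Series,
    score_groups: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format membership of every sample in the three labelings,
    plus the three-way cross-tabulation.

    All three labelings must cover exactly the same samples.
    """
    a, b, c = (pd.Series(x) for x in (m6aclusters, gene_clusters, score_groups))
    if not (set(a.index) == set(b.index) == set(c.index)):
        raise ValueError("labelings do not cover identical sample sets")
    table = pd.DataFrame(
        {
            "m6acluster": a,
            "gene_cluster": b.loc[a.index],
            "score_group": c.loc[a.index],
        }
    )
    table.index.name = "sample_id"
    counts = (
        table.groupby(["m6acluster", "gene_cluster", "score_group"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return table, counts
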