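"""Synthetic cohorts with known ground truth.

A cohort couples (i) a log2-scale expression matrix in which a 22-gene
regulator panel carries planted sample clusters, (ii) survival times
whose hazard is exponential in a latent per-sample score, (iii) a
MAF-like mutation table whose per-sample burden is (anti-)correlated
with that score, (iv) copy-number calls for the regulators, and
(v) signature collections (23 immune-cell sets, stromal/immune sets,
pathway sets) with designated sets planted high in the poor-prognosis
cluster.

One user seed drives independent, component-keyed generator streams, so
every sub-table is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CnvCalls,
    CohortClinical,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    Unit,
    write_clinical,
    write_cnv_calls,
    write_expression,
    write_gmt,
    write_maf,
)
from .registry import load_regulator_registry

__all__ = [
    "SimulationConfig",
    "SignatureFixtures",
    "SyntheticCohort",
    "simulate_cohort",
    "make_signature_fixtures",
    "truth_report",
    "preset_config",
]

IMMUNE_CELL_TYPES = (
    "Activated_B_cell",
    "Activated_CD4_T_cell",
    "Activated_CD8_T_cell",
    "Activated_dendritic_cell",
    "CD56bright_natural_killer_cell",
    "CD56dim_natural_killer_cell",
    "Eosinophil",
    "Gamma_delta_T_cell",
    "Immature_B_cell",
    "Immature_dendritic_cell",
    "Macrophage",
    "Mast_cell",
    "MDSC",
    "Memory_B_cell",
    "Monocyte",
    "Natural_killer_T_cell",
    "Natural_killer_cell",
    "Neutrophil",
    "Plasmacytoid_dendritic_cell",
    "Regulatory_T_cell",
    "T_follicular_helper_cell",
    "Type_1_T_helper_cell",
    "Type_2_T_helper_cell",
)

#: immune sets planted high in the poor-prognosis cluster analog
PLANTED_IMMUNE_SETS = ("Type_2_T_helper_cell", "Natural_killer_cell", "Mast_cell")

PATHWAY_NAMES = (
    "PATHWAY_FOXO_LIKE",
    "PATHWAY_ERBB_LIKE",
    "PATHWAY_CELL_CYCLE",
    "PATHWAY_APOPTOSIS",
    "PATHWAY_WNT",
    "PATHWAY_TGFB",
    "PATHWAY_MAPK",
    "PATHWAY_JAK_STAT",
    "PATHWAY_P53",
    "PATHWAY_ADHESION",
    "PATHWAY_METABOLISM",
    "PATHWAY_HYPOXIA",
)

PLANTED_PATHWAYS = ("PATHWAY_FOXO_LIKE",)

IMMUNE_SET_SIZE = 10
ESTIMATE_SET_SIZE = 15
PATHWAY_SET_SIZE = 15


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 150
    n_genes: int = 1200
    n_regulators: int = 22
    n_clusters: int = 3
    cluster_shift: float = 2.0  # log2 units per regulator, relative to sigma=1
    n_signal_genes: int = 300
    hazard_beta: float = 0.7  # log-hazard per unit latent score
    censor_rate: float = 0.3
    tmb_rho: float = -0.5  # slope of log mutation mean in latent score
    immune_shift: float = 1.5  # planted signature elevation (log2 units)
    pathway_shift: float = 1.5
    sigma: float = 1.0
    baseline_hazard: float = 1.0 / 500.0  # per day
    latent_noise: float = 0.5
    cluster_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0.0 < self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie strictly inside (0, 1)")
        props = self.proportions
        if len(props) != self.n_clusters or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1, one per cluster")

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.cluster_proportions is not None:
            return tuple(self.cluster_proportions)
        return tuple(1.0 / self.n_clusters for _ in range(self.n_clusters))


@dataclass
class SignatureFixtures:
    """Disjoint signature collections drawn from the simulated universe."""

    immune: GeneSetCollection  # 23 sets
    estimate_stromal: GeneSetCollection  # 1 set
    estimate_immune: GeneSetCollection  # 1 set
    pathways: GeneSetCollection  # >= 10 sets

    @property
    def stromal_genes(self) -> list[str]:
        return next(iter(self.estimate_stromal.sets.values()))

    @property
    def immune_estimate_genes(self) -> list[str]:
        return next(iter(self.estimate_immune.sets.values()))


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: CohortClinical
    mutations: MutationTable
    cnv: CnvCalls
    signatures: SignatureFixtures
    truth: pd.DataFrame  # index sample_id; columns: cluster, latent_score
    config: SimulationConfig
    signal_genes: list[str] = field(default_factory=list)  # latent-coupled DEG analogs

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all components as plain-text files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "clinical": out / "clinical.tsv",
            "mutations": out / "mutations.maf",
            "cnv": out / "cnv_calls.tsv",
            "immune_sets": out / "immune_cells.gmt",
            "estimate_sets": out / "estimate.gmt",
            "pathway_sets": out / "pathways.gmt",
            "truth": out / "truth.tsv",
        }
        write_expression(self.expression, paths["expression"])
        write_clinical(self.clinical, paths["clinical"])
        write_maf(self.mutations, paths["mutations"])
        write_cnv_calls(self.cnv, paths["cnv"])
        write_gmt(self.signatures.immune, paths["immune_sets"])
        both = GeneSetCollection(
            {
                **self.signatures.estimate_stromal.sets,
                **self.signatures.estimate_immune.sets,
            },
            category="custom",
        )
        write_gmt(both, paths["estimate_sets"])
        write_gmt(self.signatures.pathways, paths["pathway_sets"])
        self.truth.to_csv(paths["truth"], sep="\t", index_label="sample_id")
        return paths


def _stream(seed: int, component: int) -> np.random.Generator:
    """Independent generator stream keyed on (seed, component index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(component,)))


_STREAMS = {
    "clusters": 0,
    "expression": 1,
    "latent": 2,
    "survival": 3,
    "mutations": 4,
    "cnv": 5,
    "clinical": 6,
}


def _cluster_tiers(n_clusters: int) -> np.ndarray:
    """Per-cluster latent centers: first cluster lowest, second highest.

    Mirrors the planted pattern in which the A-analog has all regulators
    low and the B-analog all high, with remaining clusters in between.
    """
    base = np.linspace(-1.0, 1.0, n_clusters)
    tiers = np.empty(n_clusters)
    tiers[0] = base[0]
    if n_clusters > 1:
        tiers[1] = base[-1]
    tiers[2:] = base[1:-1]
    return tiers


def _gene_universe(cfg: SimulationConfig) -> tuple[list[str], dict[str, slice]]:
    """Gene names plus the index layout of the planted blocks."""
    registry = load_regulator_registry()
    reg = registry.symbols[: cfg.n_regulators]
    n_immune = len(IMMUNE_CELL_TYPES) * IMMUNE_SET_SIZE
    n_estimate = 2 * ESTIMATE_SET_SIZE
    n_pathway = len(PATHWAY_NAMES) * PATHWAY_SET_SIZE
    needed = len(reg) + n_immune + n_estimate + n_pathway + cfg.n_signal_genes
    if needed > cfg.n_genes:
        raise ValueError(
            f"gene universe too small: need >= {needed} genes, have {cfg.n_genes}"
        )
    others = [f"G{i:05d}" for i in range(cfg.n_genes - len(reg))]
    genes = reg + others
    layout = {}
    pos = len(reg)
    layout["regulators"] = slice(0, len(reg))
    layout["immune"] = slice(pos, pos + n_immune)
    pos += n_immune
    layout["estimate_stromal"] = slice(pos, pos + ESTIMATE_SET_SIZE)
    pos += ESTIMATE_SET_SIZE
    layout["estimate_immune"] = slice(pos, pos + ESTIMATE_SET_SIZE)
    pos += ESTIMATE_SET_SIZE
    layout["pathways"] = slice(pos, pos + n_pathway)
    pos += n_pathway
    layout["signal"] = slice(pos, pos + cfg.n_signal_genes)
    return genes, layout


def make_signature_fixtures(cfg: SimulationConfig) -> SignatureFixtures:
    """Allocate disjoint signature gene sets over the simulated universe.

    23 immune-cell sets, one stromal and one immune (combined-score)
    set, and 12 pathway sets; designated sets are the ones the expression
    simulator elevates in the poor-prognosis cluster analog.
    """
    genes, layout = _gene_universe(cfg)
    immune_block = genes[layout["immune"]]
    immune_sets = {
        name: immune_block[i * IMMUNE_SET_SIZE : (i + 1) * IMMUNE_SET_SIZE]
        for i, name in enumerate(IMMUNE_CELL_TYPES)
    }
    pathway_block = genes[layout["pathways"]]
    pathway_sets = {
        name: pathway_block[i * PATHWAY_SET_SIZE : (i + 1) * PATHWAY_SET_SIZE]
        for i, name in enumerate(PATHWAY_NAMES)
    }
    return SignatureFixtures(
        immune=GeneSetCollection(immune_sets, category="immune_cell"),
        estimate_stromal=GeneSetCollection(
            {"STROMAL_SIGNATURE": genes[layout["estimate_stromal"]]},
            category="estimate_stromal",
        ),
        estimate_immune=GeneSetCollection(
            {"IMMUNE_SIGNATURE": genes[layout["estimate_immune"]]},
            category="estimate_immune",
        ),
        pathways=GeneSetCollection(pathway_sets, category="pathway"),
    )


def _calibrate_censoring(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censoring
    fraction: mean_i rc / (rate_i + rc) = target (monotone; bisection)."""

    def frac(rc: float) -> float:
        return float(np.mean(rc / (event_rates + rc)))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from the generative model.

    Regulator genes: Normal(mu_g + tier_c * cluster_shift, sigma) in
    log2 space. Latent score: tier_c + Normal(0, latent_noise). Survival:
    Exponential with hazard h0 * exp(hazard_beta * score), independently
    exponentially censored at a rate calibrated to ``censor_rate``.
    Mutation counts: Poisson with log-mean linear in the score
    (slope ``tmb_rho``).
    """
    genes, layout = _gene_universe(cfg)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    tiers = _cluster_tiers(cfg.n_clusters)
    cluster_names = [chr(ord("A") + i) for i in range(cfg.n_clusters)]

    rng_cl = _stream(cfg.seed, _STREAMS["clusters"])
    cluster_idx = rng_cl.choice(cfg.n_clusters, size=n, p=list(cfg.proportions))

    rng_lat = _stream(cfg.seed, _STREAMS["latent"])
    latent = tiers[cluster_idx] + rng_lat.normal(0.0, cfg.latent_noise, size=n)

    rng_ex = _stream(cfg.seed, _STREAMS["expression"])
    n_genes = len(genes)
    mu = rng_ex.normal(6.0, 1.0, size=n_genes)
    X = mu[:, None] + rng_ex.normal(0.0, cfg.sigma, size=(n_genes, n))

    # planted regulator clusters
    X[layout["regulators"]] += cfg.cluster_shift * tiers[cluster_idx][None, :]

    # signal genes track the latent score (alternating sign loadings)
    sig = layout["signal"]
    n_sig = sig.stop - sig.start
    loadings = rng_ex.uniform(0.5, 1.0, size=n_sig) * np.where(np.arange(n_sig) % 2, -1.0, 1.0)
    X[sig] += loadings[:, None] * latent[None, :]

    # planted signature elevation in the poor-prognosis cluster analog (index 1)
    poor = (cluster_idx == 1).astype(float)
    fixtures = make_signature_fixtures(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name in PLANTED_IMMUNE_SETS:
        rows = [gene_pos[g] for g in fixtures.immune.sets[name]]
        X[rows] += cfg.immune_shift * poor[None, :]
    X[layout["estimate_stromal"]] += cfg.immune_shift * poor[None, :]
    X[layout["estimate_immune"]] += 0.5 * cfg.immune_shift * poor[None, :]
    for name in PLANTED_PATHWAYS:
        rows = [gene_pos[g] for g in fixtures.pathways.sets[name]]
        X[rows] += cfg.pathway_shift * poor[None, :]

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=sample_ids), Unit.LOG2_TPM
    )

    # survival
    rng_sv = _stream(cfg.seed, _STREAMS["survival"])
    rates = cfg.baseline_hazard * np.exp(cfg.hazard_beta * latent)
    t_event = rng_sv.exponential(1.0 / rates)
    cens_rate = _calibrate_censoring(rates, cfg.censor_rate)
    t_cens = rng_sv.exponential(1.0 / cens_rate, size=n)
    os_time = np.maximum(np.minimum(t_event, t_cens), 1.0)
    os_event = (t_event <= t_cens).astype(int)

    rng_cov = _stream(cfg.seed, _STREAMS["clinical"])
    clinical = CohortClinical(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": np.round(rng_cov.normal(65, 10, size=n)).astype(int),
                "gender": rng_cov.choice(["female", "male"], size=n),
                "grade": rng_cov.integers(1, 5, size=n),
                "stage": rng_cov.integers(1, 5, size=n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # mutations: Poisson burden, log-mean linear in latent score
    rng_mu = _stream(cfg.seed, _STREAMS["mutations"])
    log_mean = np.log(8.0) + cfg.tmb_rho * latent
    counts = rng_mu.poisson(np.exp(log_mean))
    records = []
    classes = np.array(
        ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Silent"]
    )
    class_p = np.array([0.70, 0.08, 0.07, 0.15])
    for s, c in zip(sample_ids, counts):
        if c == 0:
            continue
        hit_genes = rng_mu.choice(genes, size=c, replace=True)
        hit_classes = rng_mu.choice(classes, size=c, p=class_p)
        for g, vc in zip(hit_genes, hit_classes):
            records.append((s, g, vc, "SNP"))
    mutations = MutationTable(
        pd.DataFrame(
            records, columns=["sample_id", "gene_symbol", "variant_classification", "variant_type"]
        )
    )

    # regulator CNV calls with gene-specific gain/loss propensities
    rng_cn = _stream(cfg.seed, _STREAMS["cnv"])
    reg_genes = genes[layout["regulators"]]
    gain_p = rng_cn.uniform(0.02, 0.25, size=len(reg_genes))
    loss_p = rng_cn.uniform(0.02, 0.25, size=len(reg_genes))
    u = rng_cn.random(size=(len(reg_genes), n))
    calls = np.where(u < gain_p[:, None], 1, np.where(u < (gain_p + loss_p)[:, None], -1, 0))
    cnv = CnvCalls(
        pd.DataFrame(calls, index=reg_genes, columns=sample_ids),
        provenance={"source": "simulated", "gain_p": gain_p.tolist(), "loss_p": loss_p.tolist()},
    )

    truth = pd.DataFrame(
        {
            "cluster": [cluster_names[i] for i in cluster_idx],
            "latent_score": latent,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        mutations=mutations,
        cnv=cnv,
        signatures=fixtures,
        truth=truth,
        config=cfg,
        signal_genes=list(genes[sig]),
    )


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-sample planted labels and latent scores (for recovery tests)."""
    return cohort.truth.copy()


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named simulation presets: 'planted' (default effects) or 'null'
    (no cluster structure, no hazard signal, no planted signatures)."""
    if name == "planted":
        cfg = SimulationConfig(seed=seed)
    elif name == "null":
        cfg = SimulationConfig(
            cluster_shift=0.0,
            hazard_beta=0.0,
            tmb_rho=0.0,
            immune_shift=0.0,
            pathway_shift=0.0,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides)
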