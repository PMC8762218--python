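"""End-to-end orchestration: simulate/ingest -> regulator summaries ->
consensus clusters -> enrichment -> DEG/Cox screen -> gene clusters ->
score -> survival/TMB stratification, with a machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, io, registry, score as score_mod, simulate, survival
from .consensus import cluster_expression_summary, consensus_cluster

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``preset`` (synthetic cohort) or the explicit input paths
    must be provided. The config serializes losslessly to/from YAML.
    """

    out_dir: str = "run"
    preset: str | None = "planted"
    seed: int = 0
    n_samples: int = 150
    # explicit inputs (used when preset is None)
    expression_path: str | None = None
    expression_unit: str = "TPM"
    clinical_path: str | None = None
    mutations_path: str | None = None
    cnv_path: str | None = None
    immune_gmt: str | None = None
    estimate_gmt: str | None = None
    pathway_gmt: str | None = None
    # thresholds
    deg_p: float = differential.DEG_P_THRESHOLD
    cox_p: float = differential.COX_P_THRESHOLD
    adj_p: float = 0.05
    minprop: float = 0.1
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 500
    subsample_fraction: float = 0.8
    ssgsea_alpha: float = enrichment.DEFAULT_ALPHA
    min_overlap: int = enrichment.DEFAULT_MIN_OVERLAP
    auc_horizons_years: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("deg_p", 0, 1),
            ("cox_p", 0, 1),
            ("adj_p", 0, 1),
            ("minprop", 0, 0.5),
            ("subsample_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.preset is None and not (self.expression_path and self.clinical_path):
            raise ValueError("either a preset or expression+clinical paths are required")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["auc_horizons_years"] = list(self.auc_horizons_years)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "auc_horizons_years" in d:
            d["auc_horizons_years"] = tuple(d["auc_horizons_years"])
        return cls(**d)

    def config_hash(self) -> str:
        # out_dir is a location, not an analysis parameter: excluded so
        # identical analyses hash identically wherever they are written
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d["auc_horizons_years"] = list(self.auc_horizons_years)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    counts: dict = field(default_factory=dict)
    selected_k: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def validate(self) -> None:
        c = self.counts
        if "panel_genes" in c and "degs" in c and c["panel_genes"] > c["degs"]:
            raise ValueError("panel larger than DEG list")
        if "degs" in c and "genes" in c and c["degs"] > c["genes"]:
            raise ValueError("more DEGs than genes tested")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(cfg: PipelineConfig):
    if cfg.preset is not None:
        sim_cfg = simulate.preset_config(cfg.preset, seed=cfg.seed, n_samples=cfg.n_samples)
        cohort = simulate.simulate_cohort(sim_cfg)
        return (
            cohort.expression,
            cohort.clinical,
            cohort.mutations,
            cohort.cnv,
            cohort.signatures.immune,
            cohort.signatures.stromal_genes,
            cohort.signatures.immune_estimate_genes,
            cohort.signatures.pathways,
            cohort,
        )
    expr = io.log_transform(io.read_expression(cfg.expression_path, cfg.expression_unit))
    clinical = io.read_clinical(cfg.clinical_path)
    muts = io.read_maf(cfg.mutations_path) if cfg.mutations_path else None
    cnv = io.read_cnv_calls(cfg.cnv_path) if cfg.cnv_path else None
    immune = io.read_gmt(cfg.immune_gmt, "immune_cell") if cfg.immune_gmt else None
    stromal = immune_est = None
    if cfg.estimate_gmt:
        est = io.read_gmt(cfg.estimate_gmt)
        names = est.names
        stromal = est.sets[names[0]]
        immune_est = est.sets[names[1]] if len(names) > 1 else None
    pathways = io.read_gmt(cfg.pathway_gmt, "pathway") if cfg.pathway_gmt else None
    return expr, clinical, muts, cnv, immune, stromal, immune_est, pathways, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing all intermediates under
    ``cfg.out_dir``. Identical config + seed gives identical outputs.

    A stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report = RunReport(config_hash=cfg.config_hash())
    reg = registry.load_regulator_registry()
    t0 = time.time()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)
        report.stages.append(name)

    try:
        stage("ingest")
        (expr, clinical, muts, cnv, immune_sets, stromal_genes, immune_est_genes,
         pathway_sets, cohort) = _load_inputs(cfg)
        clinical = clinical.aligned_to(list(expr.sample_ids))
        report.counts["samples"] = expr.n_samples
        report.counts["genes"] = expr.n_genes
        if cohort is not None:
            cohort.write(out / "inputs")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    try:
        stage("regulator_summary")
        present_reg = [g for g in reg.symbols if g in expr.gene_ids]
        if cnv is not None:
            cnv_freq = registry.cnv_frequency(cnv, [g for g in reg.symbols if g in cnv.calls.index])
            cnv_freq.to_csv(out / "regulator_cnv_frequency.tsv", sep="\t", index_label="gene")
        if muts is not None:
            count, frac = registry.mutation_frequency(muts, reg.symbols, expr.n_samples)
            report.counts["regulator_mutated_samples"] = count
            pd.DataFrame(
                [{"mutated_samples": count, "fraction": frac, "n_samples": expr.n_samples}]
            ).to_csv(out / "regulator_mutation_frequency.tsv", sep="\t", index=False)
        net = score_mod.regulator_network(expr, clinical, reg)
        net.nodes.to_csv(out / "regulator_network_nodes.tsv", sep="\t", index_label="symbol")
        net.edges.to_csv(out / "regulator_network_edges.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("regulator_summary", exc) from exc

    try:
        stage("m6acluster")
        reg_expr = expr.subset_genes(present_reg)
        cc = consensus_cluster(
            reg_expr,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_resamples=cfg.n_resamples,
            subsample_fraction=cfg.subsample_fraction,
            seed=cfg.seed,
        )
        m6aclusters = cc.partition.map(lambda i: chr(ord("A") + i - 1))
        report.selected_k["m6acluster"] = cc.selected_k
        report.counts["m6acluster_sizes"] = m6aclusters.value_counts().sort_index().to_dict()
        m6aclusters.rename("m6acluster").to_csv(out / "m6aclusters.tsv", sep="\t")
        pd.DataFrame(cc.delta_area_per_k, index=["delta_area"]).T.to_csv(
            out / "m6acluster_delta_area.tsv", sep="\t", index_label="k"
        )
        summary, _ = cluster_expression_summary(expr, m6aclusters, present_reg)
        summary.to_csv(out / "regulator_cluster_summary.tsv", sep="\t", index=False)
        sbg = survival.survival_by_groups(clinical.os_time, clinical.os_event, m6aclusters.to_numpy())
        sbg["pairwise"].to_csv(out / "m6acluster_pairwise_logrank.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("m6acluster", exc) from exc

    try:
        stage("enrichment")
        if immune_sets is not None:
            imm = enrichment.ssgsea_score(
                expr, immune_sets, alpha=cfg.ssgsea_alpha, min_overlap=cfg.min_overlap
            )
            imm.scores.to_csv(out / "immune_cell_scores.tsv", sep="\t", index_label="sample_id")
            report.counts["immune_sets_scored"] = len(imm.signature_names)
            landscape = enrichment.immune_landscape_table(imm, m6aclusters)
            landscape.to_csv(out / "immune_landscape_m6acluster.tsv", sep="\t")
        if stromal_genes is not None and immune_est_genes is not None:
            est = enrichment.estimate_scores(expr, stromal_genes, immune_est_genes)
            est.table.to_csv(out / "estimate_scores.tsv", sep="\t", index_label="sample_id")
        if pathway_sets is not None:
            pw = enrichment.pathway_activity(
                expr, pathway_sets, alpha=cfg.ssgsea_alpha, min_overlap=cfg.min_overlap
            )
            pw.scores.to_csv(out / "pathway_scores.tsv", sep="\t", index_label="sample_id")
            pw_expr = io.ExpressionMatrix(pw.scores.T, io.Unit.LOG2_TPM)
            pw_deg = differential.moderated_anova(pw_expr, m6aclusters)
            pw_deg.table.to_csv(out / "pathway_contrast_m6acluster.tsv", sep="\t", index_label="pathway")
    except Exception as exc:
        raise StageError("enrichment", exc) from exc

    try:
        stage("deg_screen")
        deg = differential.moderated_anova(expr, m6aclusters)
        deg.table.to_csv(out / "deg_table.tsv", sep="\t", index_label="gene")
        degs = differential.select_degs(deg, cfg.deg_p)
        report.counts["degs"] = len(degs)
        pd.Series(degs, name="gene").to_csv(out / "degs.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("deg_screen", exc) from exc

    try:
        stage("cox_screen")
        if degs:
            panel = differential.cox_screen(expr, clinical, degs, cfg.cox_p)
            panel.full_table.to_csv(out / "cox_screen_full.tsv", sep="\t", index_label="gene")
            panel.table.to_csv(out / "prognostic_panel.tsv", sep="\t", index_label="gene")
        else:
            panel = differential.PrognosticPanel(
                table=pd.DataFrame(columns=["beta", "hr", "p"]), p_threshold=cfg.cox_p
            )
        report.counts["panel_genes"] = len(panel.genes)
    except Exception as exc:
        raise StageError("cox_screen", exc) from exc

    gene_clusters = None
    if len(panel.genes) >= 2:
        try:
            stage("gene_cluster")
            panel_expr = expr.subset_genes(panel.genes)
            gc = consensus_cluster(
                panel_expr,
                k_range=range(cfg.k_min, cfg.k_max + 1),
                n_resamples=cfg.n_resamples,
                subsample_fraction=cfg.subsample_fraction,
                seed=cfg.seed + 1,
            )
            gene_clusters = gc.partition.map(lambda i: chr(ord("A") + i - 1))
            report.selected_k["gene_cluster"] = gc.selected_k
            report.counts["gene_cluster_sizes"] = (
                gene_clusters.value_counts().sort_index().to_dict()
            )
            gene_clusters.rename("gene_cluster").to_csv(out / "gene_clusters.tsv", sep="\t")
        except Exception as exc:
            raise StageError("gene_cluster", exc) from exc
    else:
        report.warnings.append("gene_cluster skipped: panel has < 2 genes")

    if len(panel.genes) >= 3:
        try:
            stage("score")
            sc = score_mod.compute_m6ascore(expr, panel)
            dich = score_mod.dichotomize_score(sc, clinical, minprop=cfg.minprop)
            sc.scores.assign(group=sc.group).to_csv(out / "m6ascore.tsv", sep="\t", index_label="sample_id")
            sc.loadings.to_csv(out / "m6ascore_loadings.tsv", sep="\t", index_label="gene")
            prog = score_mod.independent_prognostic_analysis(sc, clinical)
            prog["univariate"].summary.to_csv(out / "cox_univariate.tsv", sep="\t", index_label="term")
            prog["multivariate"].summary.to_csv(out / "cox_multivariate.tsv", sep="\t", index_label="term")
            roc = survival.td_auc(
                sc.m6ascore.to_numpy(),
                clinical.os_time,
                clinical.os_event,
                horizons_years=cfg.auc_horizons_years,
                orient=True,
            )
            pd.DataFrame(
                {"horizon": list(roc.auc), "auc": list(roc.auc.values())}
            ).to_csv(out / "td_auc.tsv", sep="\t", index=False)
            report.counts["auc_flipped"] = int(roc.flipped)
            if muts is not None:
                tmb = score_mod.tmb_integration(sc, muts, clinical)
                tmb["profile"].table.to_csv(out / "tmb_profile.tsv", sep="\t", index_label="sample_id")
                pd.DataFrame(
                    [{"spearman_rho": tmb["spearman_rho"], "p": tmb["spearman_p"]}]
                ).to_csv(out / "tmb_correlation.tsv", sep="\t", index=False)
            if gene_clusters is not None:
                flow, flow_counts = score_mod.attribute_flow_table(
                    m6aclusters, gene_clusters, sc.group
                )
                flow.to_csv(out / "attribute_flow.tsv", sep="\t")
                flow_counts.to_csv(out / "attribute_flow_counts.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("score", exc) from exc
    else:
        report.warnings.append("score skipped: panel has < 3 genes")

    report.to_json(out / "report.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def summarize(run_dir: str | Path) -> str:
    """One-page text digest built purely from stored artifacts."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"missing artifact: {report_path}")
    with open(report_path, encoding="utf-8") as fh:
        report = json.load(fh)
    lines = [f"run: {run_dir}", f"config hash: {report['config_hash']}"]
    for name, k in report.get("selected_k", {}).items():
        lines.append(f"selected k ({name}): {k}")
    for key in ("samples", "genes", "degs", "panel_genes"):
        if key in report["counts"]:
            lines.append(f"{key}: {report['counts'][key]}")
    for key in ("m6acluster_sizes", "gene_cluster_sizes"):
        if key in report["counts"]:
            sizes = ", ".join(f"{k}={v}" for k, v in report["counts"][key].items())
            lines.append(f"{key.replace('_sizes', '')} sizes: {sizes}")
    cox_path = run_dir / "cox_univariate.tsv"
    if cox_path.exists():
        cox = pd.read_csv(cox_path, sep="\t", index_col=0)
        for term, row in cox.iterrows():
            lines.append(
                f"univariate HR[{term}] = {row['hr']:.3f} "
                f"({row['ci_lo']:.3f}-{row['ci_hi']:.3f}), p = {row['p']:.3g}"
            )
    auc_path = run_dir / "td_auc.tsv"
    if auc_path.exists():
        auc = pd.read_csv(auc_path, sep="\t")
        pretty = ", ".join(
            f"{h / 365.25:.0f}y={a:.3f}" for h, a in zip(auc["horizon"], auc["auc"])
        )
        lines.append(f"time-dependent AUC: {pretty}")
    if report.get("warnings"):
        lines.append("warnings: " + "; ".join(report["warnings"]))
    return "\n".join(lines)
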