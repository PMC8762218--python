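import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m6apattern import (
    CohortClinical,
    ExpressionMatrix,
    SimulationConfig,
    attribute_flow_table,
    compute_m6ascore,
    cox_screen,
    dichotomize_score,
    independent_prognostic_analysis,
    moderated_anova,
    regulator_network,
    select_degs,
    simulate_cohort,
    spearman,
    tmb_integration,
    validate_external,
)
from m6apattern.io import Unit


def _expr(arr, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), Unit.LOG2_TPM)


@pytest.fixture(scope="module")
def scored_cohort():
    cohort = simulate_cohort(SimulationConfig(seed=23, n_samples=200))
    deg = moderated_anova(cohort.expression, cohort.truth["cluster"])
    panel = cox_screen(cohort.expression, cohort.clinical, select_degs(deg))
    sc = compute_m6ascore(cohort.expression, panel)
    return cohort, panel, sc


class TestComputeScore:
    def test_rank_one_data_pc2_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 2, size=6)
        b = rng.normal(size=20)
        arr = np.outer(a, b)
        sc = compute_m6ascore(_expr(arr), [f"g{i}" for i in range(6)], z_score=False)
        np.testing.assert_allclose(sc.scores["pc2_score"], 0.0, atol=1e-9)
        np.testing.assert_allclose(sc.scores["m6ascore"], sc.scores["pc1_score"], atol=1e-9)

    def test_duplicated_samples_leave_scores_unchanged(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(8, 15))
        genes = [f"g{i}" for i in range(8)]
        base = compute_m6ascore(_expr(arr), genes, z_score=False)
        doubled = np.concatenate([arr, arr], axis=1)
        samples = [f"s{i}" for i in range(15)] + [f"d{i}" for i in range(15)]
        dup = compute_m6ascore(_expr(doubled, samples=samples), genes, z_score=False)
        np.testing.assert_allclose(
            dup.scores["m6ascore"].to_numpy()[:15],
            base.scores["m6ascore"].to_numpy(),
            atol=1e-8,
        )

    def test_planted_recovery(self, scored_cohort):
        cohort, _, sc = scored_cohort
        rho, _ = spearman(sc.m6ascore.to_numpy(), cohort.truth["latent_score"].to_numpy())
        assert abs(rho) >= 0.7

    def test_bitwise_determinism(self, scored_cohort):
        cohort, panel, sc = scored_cohort
        again = compute_m6ascore(cohort.expression, panel)
        assert (again.scores.to_numpy() == sc.scores.to_numpy()).all()
        assert (again.loadings.to_numpy() == sc.loadings.to_numpy()).all()

    def test_gene_and_sample_order_invariance(self, scored_cohort):
        cohort, panel, sc = scored_cohort
        rng = np.random.default_rng(2)
        vals = cohort.expression.values
        shuffled = vals.iloc[rng.permutation(len(vals)), rng.permutation(vals.shape[1])]
        sc2 = compute_m6ascore(ExpressionMatrix(shuffled, Unit.LOG2_TPM), panel)
        np.testing.assert_allclose(
            sc2.scores.loc[sc.scores.index, "m6ascore"], sc.scores["m6ascore"], atol=1e-8
        )

    def test_loadings_unit_norm(self, scored_cohort):
        _, _, sc = scored_cohort
        norms = np.linalg.norm(sc.loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_too_few_genes_errors(self, scored_cohort):
        cohort, _, _ = scored_cohort
        with pytest.raises(ValueError, match=">= 3"):
            compute_m6ascore(cohort.expression, ["WTAP", "FTO"])

    def test_zero_variance_panel_errors(self):
        arr = np.ones((4, 10))
        with pytest.raises(ValueError, match="variance"):
            compute_m6ascore(_expr(arr), [f"g{i}" for i in range(4)])

    def test_score_is_pc1_plus_pc2_exact(self, scored_cohort):
        _, _, sc = scored_cohort
        assert (
            sc.scores["m6ascore"] == sc.scores["pc1_score"] + sc.scores["pc2_score"]
        ).all()


def _protective_cohort(seed=0, n=250):
    """Expression panel aligned with the latent score; negative hazard
    coefficient, so high score = protective."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n)
    arr = np.vstack([latent + rng.normal(0, 0.3, size=n) for _ in range(5)])
    expr = _expr(arr, genes=[f"p{i}" for i in range(5)], samples=[f"s{i}" for i in range(n)])
    t = rng.exponential(np.exp(0.8 * latent)) * 365 + 1
    c = rng.exponential(2.0, size=n) * 365 + 1
    clin = CohortClinical(
        pd.DataFrame(
            {"os_time": np.minimum(t, c), "os_event": (t <= c).astype(int)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
    )
    return expr, clin, latent


class TestDichotomize:
    def test_protective_score_high_group_survives_longer(self):
        expr, clin, latent = _protective_cohort()
        sc = compute_m6ascore(expr, [f"p{i}" for i in range(5)])
        # orientation check: the panel tracks latent positively by construction
        assert spearman(sc.m6ascore.to_numpy(), latent)[0] > 0.9
        res = dichotomize_score(sc, clin)
        med = np.median(clin.os_time)
        s_high = res["km"]["curves"]["high"].survival_at([med])[0]
        s_low = res["km"]["curves"]["low"].survival_at([med])[0]
        assert s_high > s_low
        assert res["km"]["global"].p_value < 1e-4

    def test_group_sizes_respect_minprop(self, scored_cohort):
        cohort, _, sc = scored_cohort
        res = dichotomize_score(sc, cohort.clinical, minprop=0.15)
        n = len(sc.scores)
        assert min(res["cutpoint"].n_low, res["cutpoint"].n_high) >= int(np.ceil(0.15 * n))

    def test_null_naive_anticonservative_permutation_calibrated(self):
        rng = np.random.default_rng(3)
        naive, perm = [], []
        for seed in range(8):
            expr, clin, _ = _protective_cohort(seed=100 + seed, n=60)
            noise = _expr(rng.normal(size=(5, 60)), genes=[f"p{i}" for i in range(5)],
                          samples=list(expr.sample_ids))
            sc = compute_m6ascore(noise, [f"p{i}" for i in range(5)])
            res = dichotomize_score(sc, clin, n_permutations=40, seed=seed)
            naive.append(res["cutpoint"].p_naive)
            perm.append(res["cutpoint"].p_permutation)
        assert np.mean(np.array(naive) < 0.05) >= 0.25  # selection bias visible
        assert np.mean(np.array(perm) < 0.05) <= 0.25  # corrected p roughly calibrated


class TestIndependentPrognosis:
    def test_score_significant_covariates_noise(self, scored_cohort):
        cohort, _, sc = scored_cohort
        res = independent_prognostic_analysis(sc, cohort.clinical)
        assert res["univariate"].summary.loc["m6ascore", "p"] < 1e-4
        assert res["multivariate"].summary.loc["m6ascore", "p"] < 1e-3

    def test_permuted_score_null(self, scored_cohort):
        cohort, panel, sc = scored_cohort
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(15):
            import copy

            shuffled = copy.deepcopy(sc)
            shuffled.scores["m6ascore"] = rng.permutation(sc.scores["m6ascore"].to_numpy())
            res = independent_prognostic_analysis(shuffled, cohort.clinical)
            ps.append(res["multivariate"].summary.loc["m6ascore", "p"])
        assert np.mean(np.array(ps) < 0.05) <= 0.3

    def test_hr_per_unit_of_score(self, scored_cohort):
        cohort, _, sc = scored_cohort
        res = independent_prognostic_analysis(sc, cohort.clinical)
        row = res["univariate"].summary.loc["m6ascore"]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]), rel=1e-12)


class TestValidateExternal:
    def test_training_projection_identity(self, scored_cohort):
        cohort, _, sc = scored_cohort
        res = validate_external(sc, cohort.expression, cohort.clinical)
        np.testing.assert_allclose(
            res["scores"]["m6ascore"], sc.scores["m6ascore"], atol=1e-10
        )

    def test_replication_direction(self, scored_cohort):
        cohort, panel, sc = scored_cohort
        train = dichotomize_score(sc, cohort.clinical)
        external = simulate_cohort(SimulationConfig(seed=77, n_samples=200))
        res = validate_external(sc, external.expression, external.clinical)
        med_t = np.median(cohort.clinical.os_time)
        med_e = np.median(external.clinical.os_time)
        train_dir = np.sign(
            train["km"]["curves"]["high"].survival_at([med_t])[0]
            - train["km"]["curves"]["low"].survival_at([med_t])[0]
        )
        ext_dir = np.sign(
            res["km"]["curves"]["high"].survival_at([med_e])[0]
            - res["km"]["curves"]["low"].survival_at([med_e])[0]
        )
        assert train_dir == ext_dir

    def test_partial_panel_coverage(self, scored_cohort):
        cohort, _, sc = scored_cohort
        keep = list(sc.loadings.index[: max(3, len(sc.loadings) // 2)])
        fillers = [g for g in cohort.expression.gene_ids if g not in sc.loadings.index][:5]
        sub = cohort.expression.subset_genes(keep + fillers)
        res = validate_external(sc, sub, cohort.clinical)
        assert res["coverage"] == pytest.approx(len(keep) / len(sc.loadings))

    def test_insufficient_overlap_errors(self, scored_cohort):
        cohort, _, sc = scored_cohort
        fillers = [g for g in cohort.expression.gene_ids if g not in sc.loadings.index][:5]
        sub = cohort.expression.subset_genes(list(sc.loadings.index[:2]) + fillers)
        with pytest.raises(ValueError, match="panel genes"):
            validate_external(sc, sub, cohort.clinical)


class TestTmbIntegration:
    def test_burden_sign_consistent_with_construction(self, scored_cohort):
        cohort, _, sc = scored_cohort
        dichotomize_score(sc, cohort.clinical)
        res = tmb_integration(sc, cohort.mutations, cohort.clinical)
        rho_latent, _ = spearman(
            sc.m6ascore.to_numpy(), cohort.truth["latent_score"].to_numpy()
        )
        # burden is anti-correlated with latent, so its correlation with
        # the score must carry the opposite sign of score-vs-latent
        assert np.sign(res["spearman_rho"]) == -np.sign(rho_latent)
        assert abs(res["spearman_rho"]) > 0.3

    def test_four_way_stratification(self):
        # mild anti-correlation so every burden x score cell is populated
        cohort = simulate_cohort(SimulationConfig(seed=31, n_samples=200, tmb_rho=-0.1))
        deg = moderated_anova(cohort.expression, cohort.truth["cluster"])
        panel = cox_screen(cohort.expression, cohort.clinical, select_degs(deg))
        sc = compute_m6ascore(cohort.expression, panel)
        dichotomize_score(sc, cohort.clinical)
        res = tmb_integration(sc, cohort.mutations, cohort.clinical)
        assert len(res["joint_km"]["curves"]) == 4
        assert res["joint_km"]["global"].p_value <= 1.0

    def test_per_mb_constant(self, scored_cohort):
        cohort, _, sc = scored_cohort
        dichotomize_score(sc, cohort.clinical)
        res = tmb_integration(sc, cohort.mutations, cohort.clinical, per_mb=True)
        t = res["profile"].table
        np.testing.assert_allclose(t["per_mb"], t["count"] / 38.0)

    def test_requires_groups(self, scored_cohort):
        cohort, panel, _ = scored_cohort
        fresh = compute_m6ascore(cohort.expression, panel)
        with pytest.raises(ValueError, match="dichotomize"):
            tmb_integration(fresh, cohort.mutations, cohort.clinical)


class TestRegulatorNetwork:
    def test_coregulated_block_positive_edges(self, planted_cohort, registry):
        net = regulator_network(planted_cohort.expression, planted_cohort.clinical, registry)
        assert len(net.edges) > 0
        assert (net.edges["sign"] == 1).mean() > 0.9  # shared cluster tier drives + corr
        assert len(net.edges) <= 22 * 21 // 2

    def test_protective_gene_classified(self, registry):
        rng = np.random.default_rng(5)
        n = 300
        latent = rng.normal(size=n)
        genes = registry.symbols
        arr = rng.normal(5, 1, size=(22, n))
        idx = genes.index("ALKBH5")
        arr[idx] = 5 - latent + rng.normal(0, 0.2, size=n)  # anti-risk expression
        expr = _expr(arr, genes=genes, samples=[f"s{i}" for i in range(n)])
        t = rng.exponential(np.exp(-0.8 * latent)) * 365 + 1
        clin = CohortClinical(
            pd.DataFrame(
                {"os_time": t, "os_event": np.ones(n, dtype=int)},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        net = regulator_network(expr, clin, registry)
        assert net.nodes.loc["ALKBH5", "prognosis"] == "protective"

    def test_missing_regulator_flagged(self, planted_cohort, registry):
        expr = planted_cohort.expression
        sub = ExpressionMatrix(expr.values.drop(index="FTO"), expr.unit)
        net = regulator_network(sub, planted_cohort.clinical, registry)
        assert net.nodes.loc["FTO", "prognosis"] == "absent"
        assert not net.nodes.loc["FTO", "present"]
        assert "FTO" not in set(net.edges["gene_a"]) | set(net.edges["gene_b"])


class TestAttributeFlow:
    def test_row_count_and_margins(self, scored_cohort):
        cohort, _, sc = scored_cohort
        if sc.group is None:
            dichotomize_score(sc, cohort.clinical)
        gene_clusters = cohort.truth["cluster"]  # stand-in labeling
        table, counts = attribute_flow_table(cohort.truth["cluster"], gene_clusters, sc.group)
        assert len(table) == len(cohort.truth)
        margins = counts.groupby("m6acluster")["n"].sum()
        expected = cohort.truth["cluster"].value_counts()
        for c in margins.index:
            assert margins[c] == expected[c]

    def test_modal_path_links_clusters_to_score_groups(self, scored_cohort):
        cohort, _, sc = scored_cohort
        if sc.group is None:
            dichotomize_score(sc, cohort.clinical)
        table, _ = attribute_flow_table(cohort.truth["cluster"], cohort.truth["cluster"], sc.group)
        ct = pd.crosstab(table["m6acluster"], table["score_group"])
        chi2 = sps.chi2_contingency(ct)
        assert chi2.pvalue < 1e-6  # planted structure links the labelings

    def test_mismatched_samples_error(self, scored_cohort):
        cohort, _, sc = scored_cohort
        if sc.group is None:
            dichotomize_score(sc, cohort.clinical)
        with pytest.raises(ValueError, match="identical sample sets"):
            attribute_flow_table(
                cohort.truth["cluster"].iloc[:-1], cohort.truth["cluster"], sc.group
            )
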