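import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinewas import (
    BetaMatrix,
    ModelSpec,
    SimConfig,
    concat_matrices,
    fit_cpg_cluster_ols,
    genomic_inflation,
    run_unpaired_ewas,
    simulate_cohort,
)


def sandwich_oracle(y, X, clusters, contrast):
    """Brute-force CR1 cluster sandwich: explicit bread/meat matrix algebra."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    beta = bread @ X.T @ y
    e = y - X @ beta
    meat = np.zeros((k, k))
    labels = np.unique(clusters)
    G = len(labels)
    for g in labels:
        idx = np.asarray(clusters) == g
        s = X[idx].T @ e[idx]
        meat += np.outer(s, s)
    V = (G / (G - 1)) * ((n - 1) / (n - k)) * bread @ meat @ bread
    eff = contrast @ beta
    se = np.sqrt(contrast @ V @ contrast)
    t = eff / se
    p = 2 * stats.t.sf(abs(t), df=G - 1)
    return eff, se, p


class TestClusterSandwich:
    def test_matches_matrix_algebra_oracle_on_randomized_data(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            G = rng.integers(4, 12)
            sizes = rng.integers(1, 4, size=G)
            n = sizes.sum()
            k = rng.integers(2, min(6, n - 1) + 1)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            y = rng.standard_normal(n)
            clusters = np.repeat(np.arange(G), sizes)
            c = np.zeros(k)
            c[rng.integers(k)] = 1.0
            fit = fit_cpg_cluster_ols(y, X, clusters, c)
            eff, se, p = sandwich_oracle(y, X, clusters, c)
            assert fit.effect == pytest.approx(eff, rel=1e-8)
            assert fit.se == pytest.approx(se, rel=1e-8)
            assert fit.p == pytest.approx(p, rel=1e-8)

    def test_hand_set_four_cluster_example(self):
        # 4 clusters × 2 observations, single binary covariate
        X = np.column_stack([np.ones(8), [0, 0, 1, 1, 0, 1, 0, 1]])
        y = np.array([0.2, 0.3, 0.8, 0.7, 0.25, 0.9, 0.35, 0.6])
        clusters = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        c = np.array([0.0, 1.0])
        fit = fit_cpg_cluster_ols(y, X, clusters, c)
        eff, se, p = sandwich_oracle(y, X, clusters, c)
        assert (fit.effect, fit.se, fit.p) == pytest.approx((eff, se, p), rel=1e-10)
        assert fit.n_clusters == 4

    def test_singleton_clusters_equal_hc1(self):
        """One observation per cluster: CR1 collapses to the HC1 sandwich."""
        rng = np.random.default_rng(2)
        n, k = 30, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = rng.standard_normal(n)
        clusters = np.arange(n)
        c = np.array([0.0, 1.0, 0.0])
        fit = fit_cpg_cluster_ols(y, X, clusters, c)
        bread = np.linalg.inv(X.T @ X)
        beta = bread @ X.T @ y
        e = y - X @ beta
        hc1 = (n / (n - k)) * bread @ (X.T * e**2) @ X @ bread
        # CR1 scale with G=n: (n/(n-1))*((n-1)/(n-k)) = n/(n-k), the HC1 scale
        assert fit.se == pytest.approx(np.sqrt(c @ hc1 @ c), rel=1e-10)

    def test_matches_statsmodels_cluster_covariance(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        G, per = 10, 3
        n = G * per
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [0.5, 0.2, -0.1] + rng.standard_normal(n)
        clusters = np.repeat(np.arange(G), per)
        fit = fit_cpg_cluster_ols(y, X, clusters, np.array([0, 1, 0.0]))
        res = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": clusters, "use_correction": True},
            use_t=True,
        )
        assert fit.effect == pytest.approx(res.params[1], rel=1e-10)
        assert fit.se == pytest.approx(res.bse[1], rel=1e-8)
        assert fit.p == pytest.approx(res.pvalues[1], rel=1e-6)

    def test_constant_outcome_is_degenerate(self):
        X = np.column_stack([np.ones(6), [0, 1, 0, 1, 0, 1]])
        fit = fit_cpg_cluster_ols(
            np.full(6, 0.5), X, [0, 0, 1, 1, 2, 2], np.array([0.0, 1.0])
        )
        assert fit.flag == "degenerate"
        assert fit.effect == 0.0
        assert np.isnan(fit.p)

    def test_fewer_than_two_clusters_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="clusters"):
            fit_cpg_cluster_ols(np.arange(4.0), X, [0, 0, 0, 0], np.array([1.0]))


class TestRunUnpairedEwas:
    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = SimConfig(n_pairs_by_group=(10, 5, 5), n_probes=80, seed=4)
        return simulate_cohort(cfg)

    def test_suggestive_and_experiment_wide_flags(self, cohort):
        m = cohort.matrices["blood_18"]
        res = run_unpaired_ewas(m, cohort.sheet, ModelSpec("cross_sectional", tissue="blood"))
        # flag thresholds are strict inequalities at 5e-05 and 9e-08
        assert (res["suggestive"] == (res["p"] < 5e-05)).all()
        assert (res["experiment_wide"] == (res["p"] < 9e-08)).all()
        fake = res.iloc[0:1].copy()
        fake["p"] = 3e-05
        assert (fake["p"] < 5e-05).all() and not (fake["p"] < 9e-08).any()

    def test_sample_order_invariance(self, cohort):
        m = cohort.matrices["blood_18"]
        res1 = run_unpaired_ewas(m, cohort.sheet, ModelSpec("cross_sectional", tissue="blood"))
        shuffled = BetaMatrix(m.values.sample(frac=1, axis=1, random_state=9))
        res2 = run_unpaired_ewas(
            shuffled, cohort.sheet.sample(frac=1, random_state=10),
            ModelSpec("cross_sectional", tissue="blood"),
        )
        pd.testing.assert_frame_equal(res1, res2)

    def test_two_group_no_covariate_effect_equals_mean_difference(self):
        """With a single-sex sheet, no smoking and no cells, the exposure
        effect must equal the raw difference of group means."""
        rng = np.random.default_rng(5)
        n_pairs = 8
        rows = []
        for f in range(n_pairs):
            for twin, exp in (("A", True), ("B", False)):
                rows.append(
                    {"sample_id": f"F{f}{twin}_blood18", "individual_id": f"F{f}{twin}",
                     "family_id": f"F{f}", "group": 1, "exposed": exp, "sex": "F",
                     "age": 18, "tissue": "blood", "smoking_pack_years": 0.0}
                )
        sheet = pd.DataFrame(rows)
        vals = rng.random((5, len(sheet)))
        m = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)],
                                    columns=sheet["sample_id"]))
        res = run_unpaired_ewas(m, sheet, ModelSpec("cross_sectional", tissue="blood"))
        exposed_cols = sheet.loc[sheet["exposed"], "sample_id"]
        unexposed_cols = sheet.loc[~sheet["exposed"], "sample_id"]
        expected = m.values[exposed_cols].mean(axis=1) - m.values[unexposed_cols].mean(axis=1)
        np.testing.assert_allclose(res["effect"].to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_longitudinal_contrast_recovers_planted_effect(self):
        cfg = SimConfig(
            seed=1, n_probes=300, effect_probes=tuple(range(30)), effect_delta=0.05,
            subject_sd=0.3, age_drift_sd=0.05, noise_sd=0.05,
        )
        r = simulate_cohort(cfg)
        m = concat_matrices([r.matrices[k] for k in ("buccal_5", "buccal_10", "buccal_18")])
        res = run_unpaired_ewas(m, r.sheet, ModelSpec("longitudinal"))
        planted = r.truth["is_effect"].to_numpy()
        est = res.loc[planted, "effect"].mean()
        truth = r.truth.loc[planted, "realized_delta_long"].mean()
        assert abs(est - truth) < 0.01
        assert "effect_childhood" in res.columns

    def test_missing_age_stratum_rejected(self, cohort):
        sheet = cohort.sheet[cohort.sheet["age"] != 5]
        m = concat_matrices([cohort.matrices[k] for k in ("buccal_10", "buccal_18")])
        with pytest.raises(ValueError, match="age 5"):
            run_unpaired_ewas(m, sheet, ModelSpec("longitudinal"))

    def test_per_probe_complete_case_matches_single_fit(self, cohort):
        """A probe with missing entries is fit complete-case, matching a
        direct call on the reduced data."""
        m = cohort.matrices["blood_18"]
        vals = m.values.copy()
        vals.iloc[0, :5] = np.nan
        res = run_unpaired_ewas(BetaMatrix(vals), cohort.sheet,
                                ModelSpec("cross_sectional", tissue="blood"))
        assert res.loc[0, "n_samples"] == m.shape[1] - 5
        # complete probes unaffected
        res_full = run_unpaired_ewas(m, cohort.sheet, ModelSpec("cross_sectional", tissue="blood"))
        np.testing.assert_allclose(res.loc[1:, "p"], res_full.loc[1:, "p"], rtol=1e-12)


class TestGenomicInflation:
    def test_all_half_gives_unity(self):
        assert genomic_inflation(np.full(101, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_pvalues_near_unity(self):
        rng = np.random.default_rng(6)
        lam = genomic_inflation(rng.random(100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_scaled_chisquare_inflation_detected(self):
        rng = np.random.default_rng(7)
        chi = 1.2 * rng.chisquare(1, size=200_000)
        lam = genomic_inflation(stats.chi2.sf(chi, 1))
        assert lam == pytest.approx(1.2, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))
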