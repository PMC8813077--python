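import numpy as np
import pandas as pd
import pytest

from twinewas import (
    BetaMatrix,
    SimConfig,
    longitudinal_delta,
    paired_ttest,
    rank_combine,
    run_paired_ewas,
    simulate_cohort,
    specificity_anova,
    within_pair_differences,
)


def _matrices_from(sheet, values_by_sample, probe_ids):
    keys = {}
    for (tissue, age) in {(r.tissue, r.age) for r in sheet.itertuples()}:
        cols = sheet[(sheet["tissue"] == tissue) & (sheet["age"] == age)]["sample_id"]
        df = pd.DataFrame({c: values_by_sample[c] for c in cols}, index=probe_ids)
        keys[f"{tissue}_{age}"] = BetaMatrix(df)
    return keys


class TestLongitudinalDelta:
    def test_identical_timepoints_give_zero(self, discordant_sheet):
        probe_ids = ["cg1", "cg2"]
        vals = {s: [0.4, 0.6] for s in discordant_sheet["sample_id"]}
        mats = _matrices_from(discordant_sheet, vals, probe_ids)
        d = longitudinal_delta(mats["buccal_10"], mats["buccal_18"], discordant_sheet)
        assert (d.to_numpy() == 0).all()

    def test_simple_difference(self, discordant_sheet):
        vals = {}
        for s in discordant_sheet["sample_id"]:
            vals[s] = [0.7] if "18" in s.split("_")[1] else [0.5]
        mats = _matrices_from(discordant_sheet, vals, ["cg1"])
        d = longitudinal_delta(mats["buccal_10"], mats["buccal_18"], discordant_sheet)
        np.testing.assert_allclose(d.to_numpy(), 0.2)

    def test_group_mean_difference_identity(self):
        """delta equals exposed mean minus co-twin mean, exactly, on complete
        pairs — the arithmetic behind the reported group-mean columns."""
        cfg = SimConfig(n_pairs_by_group=(12, 2, 2), n_probes=40, seed=8)
        r = simulate_cohort(cfg)
        full, _ = run_paired_ewas(r.matrices, r.sheet, mode="longitudinal")
        np.testing.assert_allclose(
            full["delta"].to_numpy(),
            (full["exposed_mean"] - full["unexposed_mean"]).to_numpy(),
            atol=1e-12,
        )


class TestPairedTTest:
    def test_closed_form_three_differences(self):
        # t = mean/(sd/sqrt(n)); for d=[1,2,3]: t = 2/(1/sqrt(3)) = 3.4641, df=2
        t, p, df, flag = paired_ttest([1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        # closed-form t CDF at df=2: P(T<=t) = 1/2 + t/(2*sqrt(2)*sqrt(1+t^2/2))
        t0 = 2 / (1 / np.sqrt(3))
        p_closed = 2 * (1 - (0.5 + t0 / (2 * np.sqrt(2) * np.sqrt(1 + t0**2 / 2))))
        assert p == pytest.approx(p_closed, abs=1e-10)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_all_zero_differences_flagged_p_one(self):
        t, p, df, flag = paired_ttest([0.0, 0.0, 0.0, 0.0])
        assert p == 1.0 and flag == "zero_variance"

    def test_constant_nonzero_differences_degenerate(self):
        t, p, df, flag = paired_ttest([0.2, 0.2, 0.2])
        assert flag == "degenerate" and np.isnan(p)

    def test_two_sided_symmetry(self):
        d = np.array([0.5, -0.1, 0.9, 0.3])
        _, p_pos, _, _ = paired_ttest(d)
        _, p_neg, _, _ = paired_ttest(-d)
        assert p_pos == pytest.approx(p_neg, rel=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([0.1])


class TestRankCombine:
    def test_hand_enumerated_example(self):
        df = rank_combine([0.001, 0.01, 0.005], [0.10, 0.02, 0.05],
                          probe_ids=["p1", "p2", "p3"])
        assert list(df["rank_sum"]) == [2, 6, 4]
        order = df.sort_values("final_rank")["probe_id"].tolist()
        assert order == ["p1", "p3", "p2"]

    def test_single_probe(self):
        df = rank_combine([0.5], [0.01], probe_ids=["only"])
        assert df["final_rank"].tolist() == [1]

    def test_exact_ties_broken_by_probe_id(self):
        df = rank_combine([0.01, 0.01], [0.05, 0.05], probe_ids=["b", "a"])
        winner = df.loc[df["final_rank"] == 1, "probe_id"].item()
        assert winner == "a"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.random(30)
        d = rng.standard_normal(30)
        ids = [f"cg{i:02d}" for i in range(30)]
        base = rank_combine(p, d, ids).set_index("probe_id")["final_rank"]
        perm = rng.permutation(30)
        shuf = rank_combine(p[perm], d[perm], [ids[i] for i in perm]).set_index("probe_id")["final_rank"]
        pd.testing.assert_series_equal(base.sort_index(), shuf.sort_index())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_combine([0.1, 0.2], [0.3])


class TestRunPairedEwas:
    def test_planted_probe_attains_top_rank(self):
        cfg = SimConfig(
            n_pairs_by_group=(20, 2, 2), n_probes=100, seed=10,
            effect_probes=(42,), effect_delta=0.10,
            subject_sd=0.2, noise_sd=0.02, age_drift_sd=0.02,
            sex_effect=0.0, smoking_effect=0.0, cell_effect=0.0,
        )
        r = simulate_cohort(cfg)
        full, top = run_paired_ewas(r.matrices, r.sheet, mode="longitudinal")
        assert top["probe_id"].iloc[0] == r.truth["probe_id"].iloc[42]

    def test_cross_sectional_constant_shift_detected(self):
        # near-perfect twin correlation: within-pair spread is essentially
        # measurement noise, so a +0.02 shift in every exposed twin dominates
        cfg = SimConfig(
            n_pairs_by_group=(41, 2, 2), n_probes=50, seed=11,
            effect_probes=tuple(range(10)), xsec_effect_delta=0.02,
            subject_sd=0.2, pair_icc=0.99, noise_sd=0.005, age_drift_sd=0.01,
            sex_effect=0.0, smoking_effect=0.0, cell_effect=0.0,
        )
        r = simulate_cohort(cfg)
        full, _ = run_paired_ewas(r.matrices, r.sheet, mode="cross_sectional", tissue="blood")
        planted = full.iloc[:10]
        assert planted["delta"].mean() == pytest.approx(0.02, abs=0.01)
        assert (planted["p"] < 0.05).mean() >= 0.9
        assert planted["n_pairs"].eq(41).all()

    def test_top_k_subset_consistent(self):
        cfg = SimConfig(n_pairs_by_group=(6, 2, 2), n_probes=200, seed=12)
        r = simulate_cohort(cfg)
        full, top = run_paired_ewas(r.matrices, r.sheet, mode="longitudinal", top_k=10)
        assert len(top) == 10
        assert (top["final_rank"] <= 10).all()
        assert sorted(full["final_rank"].dropna()) == list(range(1, 201))

    def test_no_discordant_pairs_rejected(self, small_cohort):
        sheet = small_cohort.sheet[small_cohort.sheet["group"] != 1]
        with pytest.raises(ValueError, match="discordant"):
            run_paired_ewas(small_cohort.matrices, sheet, mode="longitudinal")


class TestWithinPairConvention:
    def test_concordant_groups_use_order_invariant_absolute_difference(self, small_cohort):
        sheet = small_cohort.sheet
        m = small_cohort.matrices["blood_18"]
        sub = sheet[(sheet["tissue"] == "blood")]
        mapping = sub.set_index("individual_id")["sample_id"]
        values = m.values.loc[:, mapping]
        values.columns = mapping.index
        d = within_pair_differences(values, sheet, group=2)
        assert (d.to_numpy() >= 0).all()
        # reversing the column order leaves |A-B| unchanged
        d2 = within_pair_differences(values[values.columns[::-1]], sheet, group=2)
        pd.testing.assert_frame_equal(d, d2[d.columns])

    def test_discordant_differences_signed_exposed_minus_unexposed(self, small_cohort):
        sheet = small_cohort.sheet
        m = small_cohort.matrices["blood_18"]
        sub = sheet[(sheet["tissue"] == "blood")]
        mapping = sub.set_index("individual_id")["sample_id"]
        values = m.values.loc[:, mapping]
        values.columns = mapping.index
        d = within_pair_differences(values, sheet, group=1)
        fam = d.columns[0]
        ind = sheet[sheet["family_id"] == fam].drop_duplicates("individual_id")
        exp = ind.loc[ind["exposed"], "individual_id"].item()
        unexp = ind.loc[~ind["exposed"], "individual_id"].item()
        np.testing.assert_allclose(d[fam], values[exp] - values[unexp])


class TestSpecificityAnova:
    def test_identical_groups_give_zero_f(self):
        res = specificity_anova({1: [1, 2, 3], 2: [1, 2, 3], 3: [1, 2, 3]})
        assert res.f_stat == 0.0 and res.p == 1.0

    def test_closed_form_f_and_p(self):
        # groups [1,2,3],[2,3,4],[3,4,5]: MSB=3, MSW=1 -> F=3 on (2,6) df;
        # for F(2,6), P(F>f) = (1 + 2f/6)^-3 = 2^-3 = 0.125
        res = specificity_anova({1: [1, 2, 3], 2: [2, 3, 4], 3: [3, 4, 5]})
        assert res.f_stat == pytest.approx(3.0, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx((1 + 2 * 3.0 / 6) ** -3, abs=1e-10)
        assert res.p == pytest.approx(0.125, abs=1e-4)

    def test_shifted_group_flagged_in_posthoc(self):
        rng = np.random.default_rng(13)
        base = rng.normal(0, 0.5, size=12)
        res = specificity_anova({1: base + 10, 2: base, 3: base + 0.01})
        ph = res.posthoc.set_index(["group_a", "group_b"])["p"]
        assert ph.loc[(1, 2)] < 1e-6 and ph.loc[(1, 3)] < 1e-6
        assert ph.loc[(2, 3)] > 0.05

    def test_small_group_dropped_then_error_if_one_left(self):
        with pytest.raises(ValueError):
            specificity_anova({1: [1.0, 2.0], 2: [1.0]})
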