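"""GLM-ANCOVA, Tukey-Kramer, FDR, correspondence and demographics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from morphnet import (CohortConfig, RegionalMorphometryTable, demographics_tests,
                      fdr_correct, generate_cohort, network_metric_anova,
                      regional_ancova, regional_correspondence, tukey_kramer)

from _oracles import bh_stepup


def make_table(values, measure="GWc", group=None, field=None, prefix="s"):
    frame = pd.DataFrame(np.asarray(values, dtype=float))
    frame.index = [f"{prefix}{i}" for i in range(len(frame))]
    frame.columns = [f"r{j}" for j in range(frame.shape[1])]
    return RegionalMorphometryTable(values=frame, measure=measure,
                                    group=group, field=field)


class TestFDR:
    def test_hand_evaluated_stepup_thresholds(self):
        adjusted, reject = fdr_correct([0.01, 0.02, 0.03, 0.04, 0.05], q_level=0.05)
        assert reject.all()  # p_i <= i * 0.05 / 5 fails, but step-up rescues all
        np.testing.assert_allclose(adjusted, [0.05, 0.05, 0.05, 0.05, 0.05])

    def test_all_ones_reject_nothing(self):
        adjusted, reject = fdr_correct([1.0] * 6)
        assert not reject.any() and (adjusted == 1.0).all()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_reference_stepup_and_is_monotone(self, p):
        adjusted, reject = fdr_correct(p)
        ref_adj, ref_rej = bh_stepup(p)
        np.testing.assert_allclose(adjusted, ref_adj, atol=1e-12)
        assert (reject == ref_rej).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestTukeyKramer:
    def test_two_groups_reduce_to_the_t_test(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=9)
        n1, n2 = len(a), len(b)
        mse = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
        pairs = tukey_kramer(["A", "B"], [a.mean(), b.mean()],
                             np.diag([mse / n1, mse / n2]), n1 + n2 - 2)
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert pairs[0]["p_adj"] == pytest.approx(t_p, rel=1e-6)

    def test_covers_all_pairs(self):
        pairs = tukey_kramer(["A", "B", "C"], [0.0, 1.0, 2.0],
                             np.diag([0.1, 0.1, 0.1]), 30)
        assert [p["pair"] for p in pairs] == [("A", "B"), ("A", "C"), ("B", "C")]


class TestRegionalAncova:
    def subjects_for(self, tables):
        rows = []
        rng = np.random.default_rng(99)
        for t in tables:
            for sid in t.values.index:
                rows.append({"subject_id": sid, "age": rng.uniform(20, 60),
                             "sex": rng.choice(["F", "M"])})
        return pd.DataFrame(rows).drop_duplicates("subject_id")

    def test_identical_groups_give_null_result(self, rng):
        base = rng.normal(size=(10, 4)) + 20.0
        t1 = make_table(base, group="HC", field="3T", prefix="a")
        t2 = make_table(base, group="MS", field="3T", prefix="b")
        res = regional_ancova([t1, t2], self.subjects_for([t1, t2]),
                              covariates=())
        assert (res["F"] < 1e-10).all()
        assert (res["p"] > 0.999).all()
        assert not any(p["significant"] for ph in res["posthoc"] for p in ph)

    def test_f_equals_squared_t_without_covariates(self, rng):
        a = rng.normal(size=(8, 1)) + 20
        b = rng.normal(0.7, 1, size=(8, 1)) + 20
        t1 = make_table(a, group="HC", field="3T", prefix="a")
        t2 = make_table(b, group="MS", field="3T", prefix="b")
        res = regional_ancova([t1, t2], self.subjects_for([t1, t2]), covariates=())
        t_stat, t_p = stats.ttest_ind(b.ravel(), a.ravel(), equal_var=True)
        assert res.loc[0, "F"] == pytest.approx(t_stat ** 2, rel=1e-9)
        assert res.loc[0, "p"] == pytest.approx(t_p, rel=1e-9)

    def test_power_with_a_strong_thickness_deficit(self):
        cfg = CohortConfig(n_subjects_per_cell=50, seed=21,
                           disease_effect_ct=-0.3, subject_sd_ct=0.1)
        cohort = generate_cohort(cfg)
        tables = [cohort.table("CT", g, f) for g in ("HC", "MS")
                  for f in ("3T", "7T")]
        res = regional_ancova(tables, cohort.subjects, posthoc=False)
        assert res["reject"].mean() > 0.9

    def test_aliased_scanner_is_reported(self, rng):
        # scanner perfectly confounded with group
        t1 = make_table(rng.normal(size=(6, 2)), group="HC", field="3T", prefix="a")
        t2 = make_table(rng.normal(size=(6, 2)), group="MS", field="7T", prefix="b")
        with pytest.raises(ValueError, match="aliased"):
            regional_ancova([t1, t2], self.subjects_for([t1, t2]),
                            covariates=("scanner",))


class TestNetworkMetricAnova:
    def metrics_frame(self, cells, rng, shift=None):
        rows = []
        for c in cells:
            for d in np.linspace(0.5, 0.69, 20):
                q = rng.normal(0.3, 0.02) + (shift or {}).get(c, 0.0)
                rows.append({"measure": "CT", "cell": c, "density": d,
                             "Q": q, "gamma": rng.normal(1.2, 0.05),
                             "lambda": rng.normal(1.0, 0.02),
                             "sigma": rng.normal(1.2, 0.05)})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_f(self, rng):
        frame = self.metrics_frame(["HC_3T"], rng)
        clones = [frame.assign(cell=c) for c in
                  ("HC_3T", "HC_7T", "MS_3T", "MS_7T")]
        res = network_metric_anova(pd.concat(clones, ignore_index=True))
        assert (res["F"] < 1e-18).all()

    def test_two_equal_groups_f_equals_squared_t(self, rng):
        frame = self.metrics_frame(["HC_3T", "MS_3T"], rng,
                                   shift={"MS_3T": 0.05})
        res = network_metric_anova(frame, value_columns=("Q",))
        a = frame.loc[frame.cell == "HC_3T", "Q"]
        b = frame.loc[frame.cell == "MS_3T", "Q"]
        t_stat = stats.ttest_ind(a, b, equal_var=True).statistic
        assert res.loc[0, "F"] == pytest.approx(t_stat ** 2, rel=1e-9)

    def test_single_observation_cell_rejected(self, rng):
        frame = self.metrics_frame(["HC_3T", "MS_3T"], rng)
        frame = frame.drop(frame[frame.cell == "MS_3T"].index[1:])
        with pytest.raises(ValueError, match="single observation"):
            network_metric_anova(frame, value_columns=("Q",))


class TestCorrespondence:
    def test_identity_correspondence(self, rng):
        t1 = make_table(rng.normal(size=(6, 8)) + 20, field="3T")
        t2 = RegionalMorphometryTable(values=t1.values.copy(), measure="GWc",
                                      field="7T")
        res = regional_correspondence(t1, t2)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.n_points == 48

    def test_affine_recovery(self, rng):
        x = rng.normal(size=(20, 68)) + 20
        noise = 0.05 * rng.normal(size=x.shape)
        t1 = make_table(x, field="3T")
        t2 = RegionalMorphometryTable(
            values=pd.DataFrame(1.3 * x + 2.0 + noise, index=t1.values.index,
                                columns=t1.values.columns),
            measure="GWc", field="7T")
        res = regional_correspondence(t1, t2)
        assert res.n_points == 20 * 68
        assert abs(res.slope - 1.3) / 1.3 < 0.05

    def test_p_value_matches_permutation_oracle(self, rng):
        x = rng.normal(size=(5, 10)) + 20
        y = rng.normal(size=(5, 10)) + 20
        t1 = make_table(x)
        t2 = RegionalMorphometryTable(
            values=pd.DataFrame(y, index=t1.values.index, columns=t1.values.columns),
            measure="GWc")
        res = regional_correspondence(t1, t2)
        assert abs(res.r) < 0.5
        xs, ys = t1.values.to_numpy().ravel(), t2.values.to_numpy().ravel()
        n_perm, hits = 2000, 0
        for _ in range(n_perm):
            r = np.corrcoef(xs, rng.permutation(ys))[0, 1]
            hits += abs(r) >= abs(res.r)
        p_perm = (hits + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < mc_err + 0.01

    def test_region_means_pooling_gives_one_point_per_region(self, rng):
        t1 = make_table(rng.normal(size=(6, 8)) + 20, prefix="a")
        t2 = make_table(rng.normal(size=(9, 8)) + 20, prefix="b")
        res = regional_correspondence(t1, t2, pooling="region_means")
        assert res.n_points == 8

    def test_mismatched_subject_sets_listed(self, rng):
        t1 = make_table(rng.normal(size=(4, 5)) + 20, prefix="a")
        t2 = make_table(rng.normal(size=(4, 5)) + 20, prefix="b")
        with pytest.raises(ValueError, match="a0"):
            regional_correspondence(t1, t2)

    def test_too_few_points_rejected(self, rng):
        t1 = make_table(rng.normal(size=(3, 2)) + 9, prefix="a")
        t2 = make_table(rng.normal(size=(4, 2)) + 9, prefix="b")
        with pytest.raises(ValueError, match="3 paired"):
            regional_correspondence(t1, t2, pooling="region_means")


class TestDemographics:
    def subjects(self, counts, ages=None):
        rows = []
        for (group, sex), n in counts.items():
            for i in range(n):
                rows.append({"subject_id": f"{group}{sex}{i}", "group": group,
                             "sex": sex,
                             "age": 40.0 if ages is None else ages[group]})
        return pd.DataFrame(rows)

    def test_perfect_independence_gives_zero_chi2(self):
        res = demographics_tests(self.subjects(
            {("HC", "F"): 10, ("HC", "M"): 10, ("MS", "F"): 10, ("MS", "M"): 10}))
        sex = res[res.variable == "sex"].iloc[0]
        assert sex["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert sex["p"] == pytest.approx(1.0)

    def test_contingency_arithmetic(self):
        res = demographics_tests(self.subjects(
            {("HC", "F"): 20, ("HC", "M"): 5, ("MS", "F"): 5, ("MS", "M"): 20}))
        sex = res[res.variable == "sex"].iloc[0]
        # all expected counts 12.5 -> sum (O-E)^2/E = 4 * 7.5^2/12.5 = 18
        assert sex["statistic"] == pytest.approx(18.0, abs=1e-12)
        assert sex["df"] == 1

    def test_identical_ages_give_null_test(self):
        res = demographics_tests(self.subjects(
            {("HC", "F"): 6, ("MS", "F"): 6, ("HC", "M"): 6, ("MS", "M"): 6}))
        age = res[res.variable == "age"].iloc[0]
        assert age["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_small_expected_counts_warn(self):
        res = demographics_tests(self.subjects(
            {("HC", "F"): 2, ("HC", "M"): 9, ("MS", "F"): 1, ("MS", "M"): 8}))
        sex = res[res.variable == "sex"].iloc[0]
        assert sex["warning"] is not None
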