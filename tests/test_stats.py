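"""Association and survival statistics: ANOVA/KW + BH, chi-squared,
Pearson, Kaplan-Meier/log-rank, Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest

from histotype import (
    bh_adjust,
    chisq_test,
    cox_ph,
    feature_subtype_tests,
    km_logrank,
    pearson_corr,
)


class TestBH:
    def test_closed_form_case(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFeatureSubtypeTests:
    def test_identical_groups_p_one(self):
        F = pd.DataFrame({"f1": [1.0] * 9})
        labels = np.repeat([0, 1, 2], 3)
        out = feature_subtype_tests(F, labels)
        assert out.loc["f1", "anova_p"] == 1.0
        assert out.loc["f1", "kw_p"] == 1.0

    def test_strong_separation_power(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(20):
            x = np.concatenate(
                [rng.normal(0, 1, 30), rng.normal(2, 1, 30), rng.normal(4, 1, 30)]
            )
            F = pd.DataFrame({"f": x})
            labels = np.repeat([0, 1, 2], 30)
            out = feature_subtype_tests(F, labels)
            hits += out.loc["f", "anova_p"] < 1e-6
        assert hits >= 19

    def test_matches_scipy_directly(self):
        from scipy.stats import f_oneway, kruskal

        rng = np.random.default_rng(2)
        F = pd.DataFrame({"a": rng.normal(size=30), "b": rng.uniform(size=30)})
        labels = np.repeat([0, 1, 2], 10)
        out = feature_subtype_tests(F, labels)
        for col in ("a", "b"):
            groups = [F[col][labels == g] for g in (0, 1, 2)]
            assert out.loc[col, "anova_F"] == pytest.approx(f_oneway(*groups).statistic)
            assert out.loc[col, "kw_H"] == pytest.approx(kruskal(*groups).statistic)

    def test_q_columns_are_bh_of_p(self):
        rng = np.random.default_rng(3)
        F = pd.DataFrame(rng.normal(size=(30, 8)), columns=list("abcdefgh"))
        labels = np.repeat([0, 1, 2], 10)
        out = feature_subtype_tests(F, labels)
        np.testing.assert_allclose(
            out["anova_q"].to_numpy(), bh_adjust(out["anova_p"].to_numpy())
        )


class TestChiSquared:
    def test_cohort_gender_table(self):
        """Two cohorts with 37/62 vs 66/139 female/male counts are not
        significantly different (continuity-corrected p about 0.44)."""
        res = chisq_test([[37, 62], [66, 139]])
        assert res.extra["yates"] is True
        assert res.p == pytest.approx(0.4445, abs=5e-4)

    def test_uniform_table_statistic_zero(self):
        res = chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_computed_2x2_without_correction(self):
        t = np.array([[20, 10], [10, 20]])
        res = chisq_test(t, yates=False)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        hand = ((t - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand)

    def test_yates_default_off_for_larger_tables(self):
        res = chisq_test([[10, 5, 5], [5, 10, 5], [5, 5, 10]])
        assert res.extra["yates"] is False
        assert res.df == 4

    def test_null_calibration_3x3(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            t = rng.multinomial(180, np.ones(9) / 9).reshape(3, 3)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            ps.append(chisq_test(t).p)
        ps = np.asarray(ps)
        # approximately uniform: mean ~0.5 and 5% tail about right
        assert abs(ps.mean() - 0.5) < 0.06
        assert abs((ps < 0.05).mean() - 0.05) < 0.04

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 0], [5, 5]])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, x)
        assert r == pytest.approx(1.0)

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(5)
        x = np.arange(50.0)
        r, _ = pearson_corr(x, -x + 1e-8 * rng.normal(size=50))
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_weak_negative_correlation_recovery(self):
        """Sampling distribution: r estimated from n=304 bivariate-normal
        draws with rho=-0.17 lands within +-0.11 of the truth in ~95% of
        replicates."""
        rng = np.random.default_rng(6)
        rho = -0.17
        cov = [[1, rho], [rho, 1]]
        inside = 0
        n_rep = 100
        for _ in range(n_rep):
            xy = rng.multivariate_normal([0, 0], cov, size=304)
            r, _ = pearson_corr(xy[:, 0], xy[:, 1])
            inside += abs(r - rho) < 0.11
        assert inside >= 0.9 * n_rep

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def exp_clinical(rng, n, hazard, censor_max=1e9, group=None):
    t_event = rng.exponential(1 / hazard, size=n)
    t_cens = rng.uniform(0, censor_max, size=n)
    df = pd.DataFrame(
        {
            "specimen_id": [f"s{i}" for i in range(n)],
            "os_time": np.minimum(t_event, t_cens),
            "os_event": (t_event <= t_cens).astype(int),
        }
    )
    if group is not None:
        df["group"] = group
    return df


class TestKMLogrank:
    def test_uncensored_km_equals_empirical_survivor(self):
        clin = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [1, 1, 1, 1],
             "group": ["a", "a", "b", "b"]}
        )
        # single group: survival steps 0.75/0.5/0.25/0
        clin1 = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [1, 1, 1, 1]}
        )
        fit = km_logrank(
            pd.concat([clin1, clin1]).assign(
                group=["a"] * 4 + ["b"] * 4
            ),
            ["a"] * 4 + ["b"] * 4,
        )
        tab = fit.km["a"]
        s = tab.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(0.75)
        assert s.loc[2.0] == pytest.approx(0.5)
        assert s.loc[3.0] == pytest.approx(0.25)
        assert s.loc[4.0] == pytest.approx(0.0)

    def test_identical_groups_statistic_zero(self):
        clin = pd.DataFrame(
            {"os_time": [1.0, 2, 3, 4, 1, 2, 3, 4], "os_event": [1] * 8}
        )
        fit = km_logrank(clin, ["a", "a", "a", "a", "b", "b", "b", "b"])
        assert fit.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_df == 1

    def test_survival_curve_monotone(self):
        rng = np.random.default_rng(7)
        clin = exp_clinical(rng, 100, 0.05, censor_max=40)
        fit = km_logrank(clin, rng.choice(["a", "b"], 100))
        for tab in fit.km.values():
            assert (np.diff(tab["survival"]) <= 1e-12).all()
            assert tab["survival"].iloc[0] <= 1.0

    def test_power_against_hazard_ratio_two(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            a = exp_clinical(rng, 200, 0.02, censor_max=200)
            b = exp_clinical(rng, 200, 0.04, censor_max=200)
            clin = pd.concat([a, b], ignore_index=True)
            fit = km_logrank(clin, ["a"] * 200 + ["b"] * 200)
            hits += fit.logrank_p < 0.01
        assert hits >= 0.95 * n_rep

    def test_empty_group_raises(self):
        clin = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [1, 1]})
        with pytest.raises(ValueError):
            km_logrank(clin, ["a", "a"])


class TestCox:
    def test_identical_arms_hr_near_one(self):
        rng = np.random.default_rng(9)
        clin = exp_clinical(rng, 400, 0.05, censor_max=100)
        clin["arm"] = np.tile(["a", "b"], 200)
        fit = cox_ph(clin, ["arm"])
        hr = fit.cox["hr"].iloc[0]
        assert 0.75 < hr < 1.3
        assert fit.cox["wald_p"].iloc[0] > 0.05

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(10)
        inside = 0
        n_rep = 20
        for _ in range(n_rep):
            a = exp_clinical(rng, 250, 0.02, censor_max=300)
            b = exp_clinical(rng, 250, 0.04, censor_max=300)
            clin = pd.concat([a, b], ignore_index=True)
            clin["arm"] = ["a"] * 250 + ["b"] * 250
            fit = cox_ph(clin, ["arm"], baselines={"arm": "a"})
            inside += 1.6 <= fit.cox["hr"].iloc[0] <= 2.5
        assert inside >= 0.9 * n_rep

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(11)
        clin = exp_clinical(rng, 200, 0.05, censor_max=100)
        clin["arm"] = np.tile(["a", "b"], 100)
        b1 = cox_ph(clin, ["arm"]).cox["log_hr"].iloc[0]
        clin2 = clin.copy()
        clin2["os_time"] = clin2["os_time"] * 12.0  # months -> years scaling
        b2 = cox_ph(clin2, ["arm"]).cox["log_hr"].iloc[0]
        assert b1 == pytest.approx(b2, abs=1e-8)

    def test_baseline_coding_and_ci(self):
        rng = np.random.default_rng(12)
        a = exp_clinical(rng, 150, 0.02, censor_max=300)
        b = exp_clinical(rng, 150, 0.04, censor_max=300)
        clin = pd.concat([a, b], ignore_index=True)
        clin["arm"] = ["a"] * 150 + ["b"] * 150
        fit = cox_ph(clin, ["arm"], baselines={"arm": "a"})
        assert list(fit.cox.index) == ["arm[b]"]
        row = fit.cox.iloc[0]
        assert row["hr_ci_low"] < row["hr"] < row["hr_ci_high"]
        assert row["hr"] > 1  # b is the higher-hazard arm

    def test_unknown_levels_excluded(self):
        rng = np.random.default_rng(13)
        clin = exp_clinical(rng, 90, 0.05, censor_max=100)
        clin["stage"] = ["pT1", "pT2", "unknown"] * 30
        fit = cox_ph(clin, ["stage"], baselines={"stage": "pT1"})
        assert list(fit.cox.index) == ["stage[pT2]"]

    def test_too_few_events_raises(self):
        clin = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0], "os_event": [0, 0, 0],
             "arm": ["a", "b", "a"]}
        )
        with pytest.raises(ValueError):
            cox_ph(clin, ["arm"])

    def test_matches_lifelines_on_continuous_covariate(self):
        """Breslow-tie partial likelihood agrees with the independent
        survival library on tie-free data."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(14)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        c = rng.uniform(0, 40, size=n)
        clin = pd.DataFrame(
            {"os_time": np.minimum(t, c), "os_event": (t <= c).astype(int), "x": x}
        )
        fit = cox_ph(clin, ["x"])
        cph = CoxPHFitter().fit(
            clin.rename(columns={"os_time": "T", "os_event": "E"}), "T", "E"
        )
        assert fit.cox["log_hr"].iloc[0] == pytest.approx(
            cph.params_["x"], abs=1e-4
        )


class TestBHProperties:
    """BH equals the brute-force step-up transform on arbitrary inputs."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _bh_oracle(p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * m / rank)
            q[i] = running_min
        return q

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(bh_adjust(p), self._bh_oracle(p), atol=1e-12)
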