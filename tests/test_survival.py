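"""Median split, Kaplan-Meier, log-rank, Cox fits and AIC selection."""

import numpy as np
import pandas as pd
import pytest

import myeloquant as mq

from oracles import empirical_survival, permutation_logrank_p


def cohort(times, events, **cols):
    df = pd.DataFrame({"time_months": times, "event": events})
    df["case_id"] = [f"p{i}" for i in range(len(df))]
    for k, v in cols.items():
        df[k] = v
    return df


class TestExcludeCases:
    def frame(self):
        return cohort([1, 2, 3], [1, 1, 1], idh1_mutant=[0, 1, 0], mgmt_methylated=[1, 0, 0])

    def test_idh1_mutant_exclusion(self):
        kept, log = mq.exclude_cases(self.frame(), ["idh1_mutant == 1"])
        assert len(kept) == 2
        assert list(log["rule"]) == ["idh1_mutant == 1"]

    def test_empty_rules_identity(self):
        df = self.frame()
        kept, log = mq.exclude_cases(df, [])
        assert kept.equals(df) and len(log) == 0

    def test_exclude_all_warns(self):
        with pytest.warns(UserWarning, match="every record"):
            kept, _ = mq.exclude_cases(self.frame(), ["time_months > 0"])
        assert len(kept) == 0

    def test_unknown_covariate_is_config_error(self):
        with pytest.raises(mq.ConfigError):
            mq.exclude_cases(self.frame(), ["no_such_column == 1"])


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values,expect_high",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([1, 2, 2, 3], ["low", "low", "low", "high"]),  # ties at median -> low
            ([1, 2, 3], ["low", "low", "high"]),
        ],
    )
    def test_split_conventions(self, values, expect_high):
        df = cohort([1] * len(values), [1] * len(values), ratio=values)
        out = mq.median_split(df, "ratio")
        assert list(out["ratio_group"]) == expect_high

    def test_tie_convention_switchable(self):
        df = cohort([1, 1, 1, 1], [1, 1, 1, 1], ratio=[1, 2, 2, 3])
        out = mq.median_split(df, "ratio", ties="high")
        assert list(out["ratio_group"]) == ["low", "high", "high", "high"]

    def test_degenerate_split_rejected(self):
        df = cohort([1, 2], [1, 1], ratio=[5.0, 5.0])
        with pytest.raises(mq.DegenerateSplitError):
            mq.median_split(df, "ratio")

    def test_monotone_transform_invariance(self):
        """Group labels depend only on ranks of the metric."""
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 1, 31)
        df = cohort(np.ones(31), np.ones(31, int), ratio=vals)
        a = mq.median_split(df, "ratio")["ratio_group"]
        df["ratio"] = np.log(vals)  # strictly monotone transform
        b = mq.median_split(df, "ratio")["ratio_group"]
        assert (a == b).all()


class TestKaplanMeier:
    def test_uncensored_closed_form(self):
        """Four deaths at 1,2,3,4: S steps 0.75, 0.5, 0.25, 0; median 2."""
        curves = mq.km_estimate(cohort([1, 2, 3, 4], [1, 1, 1, 1]))
        c = curves["all"]
        assert np.allclose(c.survival, [0.75, 0.5, 0.25, 0.0])
        assert c.median == 2
        assert list(c.at_risk) == [4, 3, 2, 1]

    def test_all_censored_flat_curve_undefined_median(self):
        c = mq.km_estimate(cohort([1, 2, 3], [0, 0, 0]))["all"]
        assert np.allclose(c.survival, 1.0)
        assert c.median is None

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        c = mq.km_estimate(cohort(t, np.ones(200, int)))["all"]
        assert np.allclose(c.survival, empirical_survival(t, c.times))

    def test_exponential_median_closed_form(self):
        lam = 0.05
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / lam, 5000)
        c = mq.km_estimate(cohort(t, np.ones(5000, int)))["all"]
        assert c.median == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_survival_nonincreasing_starts_at_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 80)
        e = (rng.random(80) < 0.7).astype(int)
        c = mq.km_estimate(cohort(t, e))["all"]
        assert c.survival[0] <= 1.0
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert c.survival_at(0.0) == 1.0


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5] * 2
        g = ["a"] * 5 + ["b"] * 5
        res = mq.logrank_test(cohort(t, [1] * 10, group=g), "group")
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(mq.ValidationError):
            mq.logrank_test(cohort([1, 2], [1, 1], group=["a", "a"]), "group")

    def test_matches_permutation_null_on_small_fixture(self):
        """Implementation p agrees with a 2000-permutation approximation."""
        rng = np.random.default_rng(4)
        n = 30
        g = np.array(["a"] * 15 + ["b"] * 15)
        t = np.where(g == "a", rng.exponential(5, n), rng.exponential(10, n))
        df = cohort(t, np.ones(n, int), group=g)
        res = mq.logrank_test(df, "group")

        def stat(time, event, group):
            d = pd.DataFrame({"time_months": time, "event": event, "group": group})
            d["case_id"] = range(len(d))
            return mq.logrank_test(d, "group").chi2

        p_perm = permutation_logrank_p(t, np.ones(n, int), g, stat, n_perm=1000, seed=0)
        assert abs(res.p_value - p_perm) < 0.06

    def test_power_under_strong_separation(self):
        """HR 0.2 at n=200: the test should essentially always reject."""
        rejections = 0
        for rep in range(20):
            df = mq.simulate_cohort(
                mq.CohortSimSpec(
                    n_patients=200, log_hr_ratio_high=np.log(0.2), log_hr_mgmt=0.0, seed=500 + rep
                )
            )
            res = mq.logrank_test(df, "ratio_group_true")
            rejections += res.p_value < 0.05
        assert rejections >= 19


class TestCox:
    def sim(self, log_hr, n=2000, seed=7, **kw):
        return mq.simulate_cohort(
            mq.CohortSimSpec(
                n_patients=n, log_hr_ratio_high=log_hr, log_hr_mgmt=0.0, seed=seed, **kw
            )
        )

    def test_constant_covariate_flagged(self):
        df = cohort([1, 2, 3, 4], [1, 1, 1, 1], x=[2.0, 2.0, 2.0, 2.0])
        res = mq.cox_univariate(df, "x")
        assert not res.converged
        assert res.hr("x") == 1.0
        assert any("constant" in n for n in res.notes)

    def test_parameter_recovery(self):
        df = mq.median_split(self.sim(-1.0), "ratio")
        res = mq.cox_univariate(df, "ratio_group")
        assert res.converged
        assert res.hr("ratio_group") == pytest.approx(np.exp(-1.0), abs=0.05)
        lo, hi = res.covariates.loc["ratio_group", ["ci_lower", "ci_upper"]]
        assert lo < res.hr("ratio_group") < hi
        assert res.aic == pytest.approx(2 * 1 - 2 * res.log_likelihood)

    def test_duplication_leaves_hr_nearly_unchanged(self):
        df = mq.median_split(self.sim(-1.0, n=400, seed=9), "ratio")
        r1 = mq.cox_univariate(df, "ratio_group")
        doubled = pd.concat([df, df], ignore_index=True)
        r2 = mq.cox_univariate(doubled, "ratio_group")
        assert r2.hr("ratio_group") == pytest.approx(r1.hr("ratio_group"), rel=1e-2)

    def test_multivariate_joint_recovery(self):
        df = mq.simulate_cohort(
            mq.CohortSimSpec(
                n_patients=2000, log_hr_ratio_high=-1.6, log_hr_mgmt=-1.5, seed=11
            )
        )
        df = mq.median_split(df, "ratio")
        res = mq.cox_multivariate(df, ["ratio_group", "mgmt_methylated"])
        assert res.hr("ratio_group") == pytest.approx(np.exp(-1.6), abs=0.06)
        assert res.hr("mgmt_methylated") == pytest.approx(np.exp(-1.5), abs=0.06)

    def test_nuisance_zero_covariate_leaves_hr_stable(self):
        df = mq.median_split(self.sim(-1.0, n=1000, seed=13), "ratio")
        r1 = mq.cox_univariate(df, "ratio_group")
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(0, 1, len(df))
        r2 = mq.cox_multivariate(df, ["ratio_group", "noise"])
        assert r2.hr("ratio_group") == pytest.approx(r1.hr("ratio_group"), rel=0.02)

    def test_more_covariates_than_records_rejected(self):
        df = cohort([1, 2], [1, 1], a=[1.0, 2.0], b=[2.0, 1.0], c=[0.0, 1.0])
        with pytest.raises(mq.ValidationError):
            mq.cox_multivariate(df, ["a", "b", "c"])

    def test_recovery_grid_with_coverage(self):
        """log-HR bias and 95% CI coverage across an HR grid (scaled replicates)."""
        for hr in (0.5, 2.0):
            true = np.log(hr)
            est, covered = [], 0
            n_rep = 30
            for rep in range(n_rep):
                df = mq.median_split(self.sim(true, n=300, seed=2000 + rep), "ratio")
                r = mq.cox_univariate(df, "ratio_group")
                est.append(np.log(r.hr("ratio_group")))
                lo, hi = r.covariates.loc["ratio_group", ["ci_lower", "ci_upper"]]
                covered += np.log(lo) <= true <= np.log(hi)
            assert abs(np.mean(est) - true) < 0.1
            assert covered / n_rep >= 0.85


class TestAicSelect:
    def test_single_candidate_definition(self):
        """A lone candidate is selected iff its AIC beats the null model's."""
        df = mq.median_split(
            mq.simulate_cohort(
                mq.CohortSimSpec(n_patients=500, log_hr_ratio_high=-1.5, log_hr_mgmt=0.0, seed=3)
            ),
            "ratio",
        )
        sel = mq.aic_select(df, ["ratio_group"])
        uni = mq.cox_univariate(df, "ratio_group")
        assert uni.aic < sel.null_aic
        assert sel.selected == ("ratio_group",)

    def test_noise_candidate_dropped(self):
        df = mq.median_split(
            mq.simulate_cohort(
                mq.CohortSimSpec(n_patients=1000, log_hr_ratio_high=-1.5, log_hr_mgmt=0.0, seed=4)
            ),
            "ratio",
        )
        rng = np.random.default_rng(5)
        df["noise"] = rng.normal(0, 1, len(df))
        sel = mq.aic_select(df, ["ratio_group", "noise"])
        assert "ratio_group" in sel.selected
        assert sel.strategy == "exhaustive"
        assert len(sel.trace) == 4  # null + 3 non-empty subsets

    def test_collinear_duplicate_dropped_with_warning(self):
        df = mq.median_split(
            mq.simulate_cohort(mq.CohortSimSpec(n_patients=300, seed=6)), "ratio"
        )
        df["ratio_copy"] = df["ratio"]
        with pytest.warns(UserWarning, match="collinear"):
            sel = mq.aic_select(df, ["ratio", "ratio_copy"])
        assert sel.dropped_collinear == ["ratio_copy"]

    def test_null_aic_matches_hand_computed_efron_loglik(self):
        """Null partial log-likelihood oracle: -sum log(n-j) over tied events."""
        from myeloquant.survival import _null_partial_loglik

        df = cohort([1, 1, 2, 3], [1, 1, 1, 0])
        # t=1: risk 4, d=2 -> -log4 - log3 ; t=2: risk 2, d=1 -> -log2
        expected = -(np.log(4) + np.log(3)) - np.log(2)
        assert _null_partial_loglik(df) == pytest.approx(expected)


class TestPlot:
    def test_km_plot_writes_file(self, tmp_path):
        curves = mq.km_estimate(cohort([1, 2, 3, 4], [1, 1, 0, 1]))
        out = tmp_path / "km.png"
        mq.plot_km(curves, out)
        assert out.exists() and out.stat().st_size > 0
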