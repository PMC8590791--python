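from datetime import date
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from wristpa.errors import ConfigError, InputError
from wristpa.stats import (
    ModelSpec,
    fit_mixed,
    sleep_weekday_regression,
    weartime_rank_test,
    weekend_week_contrast,
)
from wristpa.synthetic import DailyEffectSpec, gen_daily_dataset

MON = date(2019, 6, 3)


def dataset(n=60, seed=0, **spec_kwargs):
    spec = DailyEffectSpec(n_subjects={"HEART": n, "HEALTH": 0}, **spec_kwargs)
    return gen_daily_dataset(spec, 13, MON, seed=seed)


@pytest.fixture(scope="module")
def fits():
    df = dataset(n=40, seed=21)
    mine = fit_mixed(df, ModelSpec(outcome="lpa", factor="day_of_week"))
    formula = (
        "lpa_minutes ~ C(day_of_week, Treatment('Monday')) + age + C(sex)"
        " + vo2peak + wear_minutes"
    )
    sm_reml = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=True)
    sm_ml = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=False)
    return mine, sm_reml, sm_ml


class TestAgainstStatsmodels:
    """Dual-route check: the in-package (RE)ML engine vs MixedLM."""

    def test_fixed_effects_match(self, fits):
        mine, sm_reml, _ = fits
        sunday = [k for k in sm_reml.params.index if "Sunday" in k][0]
        assert mine.params.loc["day_of_week[Sunday]", "estimate"] == pytest.approx(
            sm_reml.params[sunday], rel=1e-4
        )
        assert mine.params.loc["age", "estimate"] == pytest.approx(
            sm_reml.params["age"], rel=1e-3, abs=1e-6
        )

    def test_standard_errors_match(self, fits):
        mine, sm_reml, _ = fits
        sunday = [k for k in sm_reml.params.index if "Sunday" in k][0]
        assert mine.params.loc["day_of_week[Sunday]", "se"] == pytest.approx(
            sm_reml.bse[sunday], rel=1e-3
        )

    def test_variance_components_match(self, fits):
        mine, sm_reml, _ = fits
        assert mine.sigma2 == pytest.approx(sm_reml.scale, rel=1e-3)
        assert mine.tau2 == pytest.approx(float(sm_reml.cov_re.iloc[0, 0]), rel=1e-2)

    def test_ml_loglik_matches(self, fits):
        mine, _, sm_ml = fits
        assert mine.loglik == pytest.approx(sm_ml.llf, abs=1e-3)


class TestRecovery:
    def test_sunday_deficit_recovered(self):
        df = dataset(
            n=200, seed=31,
            day_of_week_effects={"lpa": [0, 0, 0, 0, 0, 0, -20.0]},
        )
        res = fit_mixed(df, ModelSpec(outcome="lpa", factor="day_of_week"))
        est = res.params.loc["day_of_week[Sunday]", "estimate"]
        se = res.params.loc["day_of_week[Sunday]", "se"]
        assert res.converged
        assert abs(est - (-20.0)) <= 2 * se

    def test_weartime_slope_recovered(self):
        df = dataset(n=200, seed=32, reactivity_slope={"wear": -0.5})
        res = fit_mixed(df, ModelSpec(outcome="wear", factor="measurement_day"))
        est = res.params.loc["measurement_day", "estimate"]
        se = res.params.loc["measurement_day", "se"]
        assert abs(est - (-0.5)) <= 2 * se
        assert "wear_minutes" not in res.params.index  # wear never self-adjusts

    def test_consistency_bias_shrinks_with_n(self):
        errs = {}
        for n in (30, 300):
            errs[n] = np.mean(
                [
                    abs(
                        fit_mixed(
                            dataset(
                                n=n, seed=100 + r,
                                day_of_week_effects={"lpa": [0, 0, 0, 0, 0, 0, -20.0]},
                            ),
                            ModelSpec(outcome="lpa", factor="day_of_week"),
                        ).params.loc["day_of_week[Sunday]", "estimate"]
                        - (-20.0)
                    )
                    for r in range(5)
                ]
            )
        assert errs[300] < errs[30]


class TestWeekendWeekContrast:
    def test_weekend_deficit_recovered(self):
        df = dataset(
            n=200, seed=41,
            day_of_week_effects={"lpa": [0, 0, 0, 0, 0, -15.0, -15.0]},
        )
        res = weekend_week_contrast(df, "lpa")
        est = res.params.loc["is_weekend", "estimate"]
        se = res.params.loc["is_weekend", "se"]
        assert abs(est - (-15.0)) <= 2 * se

    def test_null_week_effect_covered(self):
        # single CIs miss ~5% of the time; require coverage in most replicates
        covered = 0
        for r in range(10):
            df = dataset(n=100, seed=420 + r)
            res = weekend_week_contrast(df, "lpa")
            lo, hi = res.params.loc["week2", ["ci_low", "ci_high"]]
            covered += lo <= 0 <= hi
        assert covered >= 8

    def test_zero_weekend_effect_coverage(self):
        covered = 0
        for r in range(100):
            df = dataset(n=25, seed=500 + r)
            res = weekend_week_contrast(df, "lpa", reml=True)
            lo, hi = res.params.loc["is_weekend", ["ci_low", "ci_high"]]
            covered += lo <= 0 <= hi
        assert covered >= 93


class TestWeights:
    def test_equal_supplied_weights_match_unweighted(self):
        df = dataset(n=40, seed=51)
        base = fit_mixed(df, ModelSpec(outcome="lpa", factor="day_of_week"))
        days = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
                "Saturday", "Sunday")
        weighted = fit_mixed(
            df,
            ModelSpec(outcome="lpa", factor="day_of_week",
                      weights={d: 1.0 for d in days}),
        )
        assert np.allclose(
            base.params["estimate"], weighted.params["estimate"], rtol=1e-6
        )
        assert np.allclose(base.params["se"], weighted.params["se"], rtol=1e-6)

    def test_estimated_weights_homoscedastic_close(self):
        df = dataset(n=120, seed=52)
        base = fit_mixed(df, ModelSpec(outcome="lpa", factor="day_of_week"))
        weighted = fit_mixed(
            df, ModelSpec(outcome="lpa", factor="day_of_week",
                          weights="by_factor_level"),
        )
        dow = [t for t in base.params.index if t.startswith("day_of_week")]
        assert np.allclose(
            base.params.loc[dow, "estimate"],
            weighted.params.loc[dow, "estimate"],
            atol=1.5,
        )

    def test_missing_weight_level_rejected(self):
        df = dataset(n=20, seed=53)
        with pytest.raises(ConfigError):
            fit_mixed(
                df,
                ModelSpec(outcome="lpa", factor="day_of_week",
                          weights={"Monday": 1.0}),
            )


class TestDesignAndValidation:
    def test_row_order_invariance(self, rng):
        df = dataset(n=30, seed=61)
        res1 = fit_mixed(df, ModelSpec(outcome="tpa", factor="weekend_week"))
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        res2 = fit_mixed(shuffled, ModelSpec(outcome="tpa", factor="weekend_week"))
        assert np.allclose(res1.params["estimate"], res2.params["estimate"], atol=1e-8)
        assert res1.factor_test.pvalue == pytest.approx(res2.factor_test.pvalue, abs=1e-10)

    def test_rank_deficient_design_named(self):
        df = dataset(n=20, seed=62)
        df["age"] = 50.0  # constant -> collinear with the intercept
        with pytest.raises(InputError, match="collinear"):
            fit_mixed(df, ModelSpec(outcome="lpa", factor="day_of_week"))

    def test_too_few_subjects(self):
        df = dataset(n=20, seed=63)
        one = df[df["subject_id"] == df["subject_id"].iloc[0]]
        with pytest.raises(InputError):
            fit_mixed(one, ModelSpec(outcome="lpa", factor="day_of_week"))

    def test_unknown_outcome_or_factor(self):
        with pytest.raises(ConfigError):
            ModelSpec(outcome="steps", factor="day_of_week")
        with pytest.raises(ConfigError):
            ModelSpec(outcome="lpa", factor="moon_phase")

    def test_ci_matches_normal_approximation(self):
        df = dataset(n=40, seed=64)
        res = fit_mixed(df, ModelSpec(outcome="lpa", factor="weekend_week"))
        est = res.params["estimate"]
        se = res.params["se"]
        assert np.allclose(res.params["ci_low"], est - 1.959963984540054 * se)
        assert np.allclose(res.params["ci_high"], est + 1.959963984540054 * se)


class TestSleepRegression:
    def test_weekend_shift_recovered(self):
        df = dataset(
            n=150, seed=71,
            day_of_week_effects={"sleep": [0, 0, 0, 0, 0, 28.0, 28.0]},
        )
        res = sleep_weekday_regression(df)
        assert abs(res.estimate - 28.0) <= 2 * res.se

    def test_constant_sleep_zero_estimate(self):
        df = dataset(n=10, seed=72)
        df["sleep_minutes"] = 480.0
        res = sleep_weekday_regression(df)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_all_missing_rejected(self):
        df = dataset(n=10, seed=73)
        df["sleep_minutes"] = np.nan
        with pytest.raises(InputError):
            sleep_weekday_regression(df)


def brute_force_rank_p(a, b):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    n1 = len(a)
    obs = sum(ranks[v] for v in a)
    all_sums = [sum(c) for c in combinations(range(1, len(pooled) + 1), n1)]
    mean = np.mean(all_sums)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in all_sums)
    return extreme / len(all_sums)


class TestWeartimeRankTest:
    def test_identical_samples(self):
        res = weartime_rank_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.pvalue == 1.0

    def test_complete_separation_exact(self):
        res = weartime_rank_test([1, 2, 3], [10, 11, 12])
        assert res.pvalue == pytest.approx(brute_force_rank_p([1, 2, 3], [10, 11, 12]))
        assert res.pvalue == pytest.approx(0.1)

    def test_enumeration_oracle_random(self, rng):
        for _ in range(10):
            a = list(rng.permutation(100)[:4].astype(float))
            b = list(rng.permutation(100)[50:][:5].astype(float))
            if set(a) & set(b):
                continue
            res = weartime_rank_test(a, b)
            assert res.pvalue == pytest.approx(brute_force_rank_p(a, b), abs=1e-10)

    def test_shift_invariance(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        r1 = weartime_rank_test(a, b)
        r2 = weartime_rank_test([x + 100 for x in a], [x + 100 for x in b])
        assert r1.statistic == r2.statistic
        assert r1.pvalue == r2.pvalue

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            weartime_rank_test([], [1.0])
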