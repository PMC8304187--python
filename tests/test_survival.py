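"""Spearman correlation, maximally selected cutpoints, Cox fits,
Harrell's C and Kaplan-Meier estimation."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

from petscore import (
    CohortSpec,
    cox_fit,
    generate_cohort,
    harrell_c,
    km_estimate,
    logrank_chi2,
    maxstat_cutoff,
    spearman_correlation,
)


def _ph_sample(rng, n, beta, censor_frac=0.2):
    """Exponential proportional-hazards data with one binary covariate."""
    x = (rng.random(n) < 0.5).astype(float)
    hazard = 0.05 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / (0.05 * censor_frac / max(1 - censor_frac, 1e-9)), n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return x, time, event


class TestSpearman:
    def test_monotone_pairs_give_unit_correlation(self):
        x = np.arange(10.0)
        rho, _ = spearman_correlation(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(5), np.arange(5.0))

    def test_null_simulation_centres_on_zero(self):
        rng = np.random.default_rng(11)
        rhos = [
            spearman_correlation(rng.normal(size=1000), rng.normal(size=1000))[0]
            for _ in range(200)
        ]
        assert abs(np.mean(rhos)) < 0.05


class TestLogrank:
    def test_matches_lifelines_on_tie_free_data(self):
        """Our vectorized log-rank equals the independent library statistic
        to 1e-6 on tie-free data (it is the Cox score test at beta = 0)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, time, event = _ph_sample(rng, 120, beta=0.7)
            g = x.astype(bool)
            ours = logrank_chi2(g, time, event)
            ref = logrank_test(time[g], time[~g], event[g], event[~g]).test_statistic
            assert ours == pytest.approx(ref, abs=1e-6)


class TestMaxstatCutoff:
    def test_recovers_planted_changepoint(self):
        """A planted HR-3 step at BM SUV 1.53 is recovered within 0.1 at
        n = 400 with ample events."""
        spec = CohortSpec(
            n=400, log_hr_bm_suv=np.log(3.0), log_hr_tlg=0, log_hr_entropy=0,
            log_hr_age=0, log_hr_stage=0, baseline_hazard=0.05,
            censoring_rate=0.012, seed=0,
        )
        df = generate_cohort(spec)
        res = maxstat_cutoff(
            df["bm_suv"], df["time_months"], df["event"], variable="bm_suv"
        )
        assert abs(res.cutoff - 1.53) <= 0.1
        assert res.direction == "high"
        assert res.p_value_corrected >= res.p_value

    def test_selection_inflates_null_statistic(self):
        """Under no association the maximal chi-square is stochastically
        larger than the chi-square at a fixed median cutoff."""
        rng = np.random.default_rng(10)
        max_stats, fixed_stats = [], []
        for _ in range(200):
            x = rng.normal(size=100)
            time = rng.exponential(10.0, 100)
            event = np.ones(100, dtype=int)
            res = maxstat_cutoff(x, time, event)
            max_stats.append(res.chi2)
            fixed_stats.append(logrank_chi2(x > np.median(x), time, event))
        assert np.mean(max_stats) > np.mean(fixed_stats)
        assert np.median(max_stats) > np.median(fixed_stats)

    def test_recovery_error_shrinks_with_sample_size(self):
        """Median |cutoff error| decreases over n in {100, 400, 1600}."""
        maes = []
        for n in (100, 400, 1600):
            errs = []
            for rep in range(15):
                spec = CohortSpec(
                    n=n, log_hr_bm_suv=np.log(3.0), log_hr_tlg=0,
                    log_hr_entropy=0, log_hr_age=0, log_hr_stage=0,
                    baseline_hazard=0.05, censoring_rate=0.012,
                    seed=7000 + 17 * n + rep,
                )
                df = generate_cohort(spec)
                res = maxstat_cutoff(df["bm_suv"], df["time_months"], df["event"])
                errs.append(abs(res.cutoff - 1.53))
            maes.append(np.median(errs))
        assert maes[0] > maes[2]
        assert maes[1] >= maes[2]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutoff(np.ones(50), np.arange(1.0, 51.0), np.ones(50, dtype=int))


class TestCoxFit:
    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(15)
        x, time, event = _ph_sample(rng, 2000, beta=np.log(2.0))
        df = pd.DataFrame({"x": x, "time_months": time, "event": event})
        fit = cox_fit(df, ["x"])
        assert 1.8 <= fit.hazard_ratio("x") <= 2.2

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(30)
        covered = 0
        reps = 200
        for _ in range(reps):
            x, time, event = _ph_sample(rng, 150, beta=0.0)
            df = pd.DataFrame({"x": x, "time_months": time, "event": event})
            fit = cox_fit(df, ["x"])
            row = fit.summary.loc["x"]
            covered += row["ci_lower"] <= 1.0 <= row["ci_upper"]
        assert covered / reps >= 0.90

    def test_complete_separation_fails_explicitly(self):
        n = 40
        x = np.repeat([0.0, 1.0], n // 2)
        time = np.concatenate([np.full(n // 2, 50.0), np.linspace(1, 5, n // 2)])
        event = np.concatenate([np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)])
        df = pd.DataFrame({"x": x, "time_months": time, "event": event})
        with pytest.raises(RuntimeError, match="separation|converge"):
            cox_fit(df, ["x"])

    def test_low_event_count_warns_but_fits(self):
        rng = np.random.default_rng(40)
        x = (rng.random(40) < 0.5).astype(float)
        time = rng.exponential(10, 40)
        event = np.zeros(40, dtype=int)
        event[rng.choice(40, size=8, replace=False)] = 1  # 8 events < 10 per term
        df = pd.DataFrame({"x": x, "time_months": time, "event": event})
        fit = cox_fit(df, ["x"])
        assert any("rule of thumb" in w for w in fit.warnings)


class TestHarrellC:
    def test_perfect_predictor_is_fully_concordant(self):
        time = np.arange(1.0, 51.0)
        event = np.ones(50, dtype=int)
        c, _ = harrell_c(-time, time, event)
        assert c == 1.0

    def test_tied_risks_give_half(self):
        time = np.arange(1.0, 21.0)
        c, _ = harrell_c(np.zeros(20), time, np.ones(20, dtype=int))
        assert c == 0.5

    def test_random_risk_centres_on_half(self):
        rng = np.random.default_rng(6)
        cs = []
        for _ in range(100):
            time = rng.exponential(10, 500)
            event = (rng.random(500) < 0.8).astype(int)
            c, _ = harrell_c(rng.normal(size=500), time, event)
            cs.append(c)
        assert abs(np.mean(cs) - 0.5) < 0.03

    def test_matches_lifelines_with_censoring_and_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            time = np.round(rng.exponential(10, 200), 1)  # induce time ties
            event = (rng.random(200) < 0.7).astype(int)
            risk = np.round(rng.normal(size=200), 1)  # induce risk ties
            c, _ = harrell_c(risk, time, event)
            assert c == pytest.approx(concordance_index(time, -risk, event), abs=1e-12)

    def test_bootstrap_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(19)
        time = rng.exponential(10, 150)
        event = np.ones(150, dtype=int)
        risk = -time + rng.normal(0, 5, 150)
        c, ci = harrell_c(risk, time, event, n_boot=200, seed=5)
        assert ci[0] <= c <= ci[1]

    def test_true_linear_predictor_beats_single_covariates(self):
        """On planted proportional-hazards cohorts the true linear predictor
        is more concordant than any single noised covariate (50 reps)."""
        rng = np.random.default_rng(23)
        for rep in range(50):
            spec = CohortSpec(n=500, baseline_hazard=0.05, seed=3000 + rep)
            df = generate_cohort(spec)
            t = df["time_months"].to_numpy()
            e = df["event"].to_numpy()
            c_true, _ = harrell_c(df["true_log_hazard"].to_numpy(), t, e)
            for col in ("bm_suv", "tlg_g", "firstorder_entropy"):
                noised = df[col].to_numpy() + rng.normal(0, df[col].std(), 500)
                c_cov, _ = harrell_c(noised, t, e)
                assert c_true > c_cov

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestKaplanMeier:
    def test_uncensored_curve_is_empirical_survivor_function(self):
        time = np.arange(1.0, 11.0)
        event = np.ones(10, dtype=int)
        km = km_estimate(time, event)
        assert km.median == pytest.approx(5.0)
        s_at_5 = km.survival[np.searchsorted(km.times, 5.0)]
        assert s_at_5 == pytest.approx(0.5)
        # exact 1 - ECDF at every event time
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(1.0 - (time <= t).mean())

    def test_exponential_median_consistency(self):
        """KM median of exponential survival with true median 14.1 months is
        recovered within [13.4, 14.8] at n = 5000."""
        rng = np.random.default_rng(1)
        time = rng.exponential(14.1 / np.log(2), 5000)
        km = km_estimate(time, np.ones(5000, dtype=int))
        assert 13.4 <= km.median <= 14.8

    def test_all_censored_median_undefined(self):
        km = km_estimate(np.arange(1.0, 6.0), np.zeros(5, dtype=int))
        assert np.isnan(km.median)

    def test_horizon_beyond_follow_up_flagged_as_extrapolation(self):
        km = km_estimate(np.arange(1.0, 6.0), np.ones(5, dtype=int), horizon=100.0)
        assert km.horizon_extrapolated
        km2 = km_estimate(np.arange(1.0, 6.0), np.ones(5, dtype=int), horizon=3.0)
        assert not km2.horizon_extrapolated
        assert km2.horizon_survival == pytest.approx(0.4)
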