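"""Rate/growth estimation: likelihoods, survival, bootstrap, sync fit."""

import math

import numpy as np
import pytest

from mitopoisson.events import CensoredGaps, EventSeries, accumulated_events, apply_frame_censoring
from mitopoisson.fit import (
    ProliferationModel,
    SynchronizationModel,
    empirical_survival,
    fit_growth,
    fit_lambda,
    fit_sync_fraction,
)
from mitopoisson.model import GrowthModel, SyncSchedule, cumulative_intensity, expected_cumulative
from mitopoisson.simulate import apply_synchronization, simulate_event_times


def _gaps(exact, n_censored=0, d=0.25):
    return CensoredGaps(exact=np.asarray(exact, dtype=float), n_censored=n_censored, frame_interval=d)


class TestEmpiricalSurvival:
    def test_counting(self):
        curve = empirical_survival(_gaps([1.0, 2.0, 3.0], d=0.5))
        assert curve(0.5) == 1.0
        assert curve(1.5) == pytest.approx(2 / 3)
        assert curve(2.5) == pytest.approx(1 / 3)

    def test_degenerate_equal_gaps(self):
        curve = empirical_survival(_gaps([2.0, 2.0, 2.0], d=0.5))
        assert curve(1.9) == 1.0
        assert curve(2.0) == 0.0

    def test_censored_gaps_fail_at_the_interval(self):
        curve = empirical_survival(_gaps([1.0], n_censored=3, d=0.25))
        # below the frame interval the censored gaps still count as surviving
        assert curve(0.2) == 1.0
        assert curve(0.25) == pytest.approx(1 / 4)

    def test_matches_exponential_monte_carlo(self, rng):
        lam = 2.0
        sample = rng.exponential(1 / lam, size=100_000)
        d = 0.01
        curve = empirical_survival(_gaps(sample[sample >= d], n_censored=int((sample < d).sum()), d=d))
        taus = curve.tau[curve.tau <= 2.0]
        assert np.max(np.abs(curve(taus) - np.exp(-lam * taus))) < 0.01

    def test_no_exact_gaps_is_an_error(self):
        with pytest.raises(ValueError, match="finer frame interval"):
            empirical_survival(_gaps([], n_censored=5))


class TestFitLambdaInterval:
    def test_no_censoring_is_reciprocal_mean(self):
        ar = fit_lambda(_gaps([1.0, 1.0, 1.0], d=0.5), horizon=10.0)
        assert ar.lam_bar == pytest.approx(1.0, rel=1e-9)
        ar = fit_lambda(_gaps([0.5, 1.0, 1.5, 3.0], d=0.25), horizon=10.0)
        assert ar.lam_bar == pytest.approx(1 / 1.5, rel=1e-9)

    def test_monte_carlo_recovery_with_true_interval_censoring(self, rng):
        # censoring mechanism matches the likelihood: gaps below d censored
        lam, d = 2.0, 0.25
        sample = rng.exponential(1 / lam, size=10_000)
        gaps = _gaps(sample[sample >= d], n_censored=int((sample < d).sum()), d=d)
        assert fit_lambda(gaps, horizon=1.0).lam_bar == pytest.approx(lam, rel=0.02)

    def test_agrees_with_likelihood_grid_search(self, rng):
        d = 0.25
        for trial in range(20):
            n = int(rng.integers(5, 30))
            exact = d + rng.exponential(0.5, size=n)
            n_cens = int(rng.integers(0, 10))
            gaps = _gaps(exact, n_censored=n_cens, d=d)
            mle = fit_lambda(gaps, horizon=1.0).lam_bar
            grid = np.linspace(0.01, 20, 500)
            loglik = (
                gaps.n_exact * np.log(grid)
                - grid * exact.sum()
                + n_cens * np.log1p(-np.exp(-grid * d))
            )
            best = grid[np.argmax(loglik)]
            assert abs(mle - best) <= (grid[1] - grid[0])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_lambda(_gaps([], n_censored=10), horizon=1.0)


class TestFitLambdaFrame:
    def test_recovers_rate_from_snapped_poisson_stream(self, rng):
        # homogeneous stream read at 15-min frames; mean gap < interval
        lam, d, T = 4.5, 0.25, 400.0
        t = np.cumsum(rng.exponential(1 / lam, size=int(lam * T * 1.2)))
        t = t[t < T]
        series = EventSeries(times=t, horizon=T, frame_interval=d)
        gaps = apply_frame_censoring(series)
        est = fit_lambda(gaps, horizon=T, method="frame").lam_bar
        assert est == pytest.approx(lam, rel=0.05)

    def test_interval_method_biased_under_frame_snapping(self, rng):
        # documents why the frame likelihood is the growth-fit default
        lam, d, T = 4.5, 0.25, 2000.0
        t = np.cumsum(rng.exponential(1 / lam, size=int(lam * T * 1.2)))
        t = t[t < T]
        gaps = apply_frame_censoring(EventSeries(times=t, horizon=T, frame_interval=d))
        est_frame = fit_lambda(gaps, horizon=T, method="frame").lam_bar
        est_interval = fit_lambda(gaps, horizon=T, method="interval").lam_bar
        assert abs(est_frame - lam) / lam < 0.03
        assert est_interval < 0.92 * lam  # systematic underestimate

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            fit_lambda(_gaps([1.0] * 10), horizon=1.0, method="bogus")


class TestFitGrowth:
    def test_parameter_recovery_median(self, ref_model):
        imt_true = math.log(2) / ref_model.gamma
        errs = []
        for s in range(60):
            series = simulate_event_times(ref_model, 40.0, seed=s)
            res = fit_growth(series, n0=65, bootstrap_reps=0)
            errs.append(abs(res.imt_hat - imt_true) / imt_true)
        assert np.median(errs) <= 0.05

    def test_noiseless_quantile_round_trip(self, ref_model):
        # gaps placed at expected survival quantiles of the fitted law
        lam = cumulative_intensity(40.0, ref_model) / 40.0
        n = 4000
        u = (np.arange(n) + 0.5) / n
        gaps = -np.log(1 - u) / lam
        d = 1e-5  # fine frames: censoring negligible, snapping exact
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        series = EventSeries(times=times, horizon=times[-1] + d, frame_interval=d)
        res = fit_growth(series, n0=65, bootstrap_reps=0, method="interval")
        # Lambda -> gamma -> t_IMT round trip at the true horizon scale
        lam_hat = res.lam_bar_hat
        assert lam_hat == pytest.approx(lam, rel=0.01)

    def test_bootstrap_reps_zero_collapses_ci(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=9)
        res = fit_growth(series, n0=65, bootstrap_reps=0)
        assert res.ci_low == res.imt_hat == res.ci_high

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=9)
        a = fit_growth(series, n0=65, bootstrap_reps=200, seed=4)
        b = fit_growth(series, n0=65, bootstrap_reps=200, seed=4)
        assert a.ci_low <= a.imt_hat <= a.ci_high
        assert a.ci_low < a.ci_high
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_gof_small_under_correct_model(self, ref_model):
        bad = 0
        for s in range(40):
            series = simulate_event_times(ref_model, 40.0, seed=s)
            res = fit_growth(series, n0=65, bootstrap_reps=0)
            gaps = apply_frame_censoring(series)
            crit = 1.628 / math.sqrt(gaps.n_total)  # KS alpha=0.01
            if res.gof > crit:
                bad += 1
        assert bad <= 2

    def test_too_few_events_rejected(self):
        series = EventSeries(times=np.array([1.0]), horizon=2.0)
        with pytest.raises(ValueError):
            fit_growth(series, n0=10)


class TestFitSyncFraction:
    def test_null_case_returns_one(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=21)
        fit = fit_sync_fraction(series, ref_model, [(20, 40)])
        assert fit.fractions_hat[0] == pytest.approx(1.0, abs=0.1)

    def test_recovers_thinning_fraction(self, ref_model):
        sched = SyncSchedule([(18, 32, 0.30)])
        fr = []
        for s in range(60):
            series = simulate_event_times(ref_model, 40.0, seed=s)
            thinned = apply_synchronization(series, sched, seed=500 + s)
            fr.append(fit_sync_fraction(thinned, ref_model, [(18, 32)]).fractions_hat[0])
        assert np.mean(fr) == pytest.approx(0.30, abs=0.04)

    def test_monotone_in_true_fraction(self, ref_model):
        means = []
        for frac in (0.1, 0.5, 0.9):
            sched = SyncSchedule([(18, 32, frac)])
            fr = []
            for s in range(30):
                series = simulate_event_times(ref_model, 40.0, seed=s)
                thinned = apply_synchronization(series, sched, seed=700 + s)
                fr.append(fit_sync_fraction(thinned, ref_model, [(18, 32)]).fractions_hat[0])
            means.append(np.mean(fr))
        assert means[0] < means[1] < means[2]

    def test_zero_expectation_window_rejected(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=3)
        with pytest.raises(ValueError):
            fit_sync_fraction(series, ref_model, [(20.0, 20.0 + 1e-15)])

    def test_residual_reflects_model_fit(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=3)
        fit = fit_sync_fraction(series, ref_model, [(18, 32)])
        assert fit.residual >= 0
        assert fit.residual < 3 * math.sqrt(cumulative_intensity(40.0, ref_model))


class TestAccumulatedEvents:
    def test_empty_series(self):
        t, c = accumulated_events(EventSeries(times=np.empty(0), horizon=1.0))
        assert t.size == 0 and c.size == 0

    def test_counting_with_ties(self):
        series = EventSeries(times=np.array([1.0, 2.0, 2.0, 5.0]), horizon=6.0)
        t, c = accumulated_events(series)
        np.testing.assert_array_equal(t, [1.0, 2.0, 5.0])
        np.testing.assert_array_equal(c, [1, 3, 4])

    def test_tracks_expected_curve(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=8)
        t, c = accumulated_events(series)
        expected = expected_cumulative(t, ref_model, None)
        # stay within ~4 sigma Poisson noise of the expectation
        assert np.all(np.abs(c - expected) <= 4 * np.sqrt(np.maximum(expected, 1)))


class TestModelResultsApi:
    def test_model_fit_summary_roundtrip(self, ref_model):
        series = simulate_event_times(ref_model, 40.0, seed=13)
        res = ProliferationModel(series, n0=65).fit(bootstrap_reps=100, seed=2)
        text = res.summary()
        assert "t_IMT" in text and f"{res.imt:.2f}" in text
        d = res.to_dict()
        assert d["imt_hat"] == res.imt
        assert d["n_events"] == len(series)

    def test_from_dataframe(self, ref_model):
        import pandas as pd

        series = simulate_event_times(ref_model, 40.0, seed=13)
        df = pd.DataFrame({"time_h": series.times})
        model = ProliferationModel.from_dataframe(df, n0=65, horizon=40.0)
        res = model.fit(bootstrap_reps=0)
        direct = ProliferationModel(series, n0=65).fit(bootstrap_reps=0)
        assert res.imt == pytest.approx(direct.imt, rel=1e-12)

    def test_synchronization_model_pipeline(self, ref_model):
        sched = SyncSchedule([(18, 32, 0.30)])
        series = simulate_event_times(ref_model, 40.0, seed=30)
        thinned = apply_synchronization(series, sched, seed=31)
        res = SynchronizationModel(thinned, n0=65, windows=[(18, 32)], reference=(0, 18)).fit()
        assert 0.0 <= res.fractions[0] <= 1.0
        assert res.synchronized_fractions[0] == pytest.approx(1 - res.fractions[0])
        assert "synchronization" in res.summary().lower()
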