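"""Covariance estimators, shot-noise correction, dwell times and delays."""

import numpy as np
import pytest

import rnapburst as rb
from rnapburst.correlation import (
    aggregate_normalize,
    bleach_correct_fast,
    covariance,
    cross_delay,
    dwell_time,
    estimate_shot_noise,
)


class TestCovariance:
    def test_constant_trace_gives_zero(self):
        x = np.full(30, 7.0)
        _, G = covariance(x, x)
        np.testing.assert_allclose(G, 0.0, atol=1e-12)

    def test_autocovariance_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        lags, G = covariance(a, a)
        np.testing.assert_allclose(G, G[::-1], atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        lags, G = covariance(a, b)
        da, db = a - a.mean(), b - b.mean()
        for i, tau in enumerate(lags):
            acc = sum(
                da[t] * db[t + tau]
                for t in range(20)
                if 0 <= t + tau < 20
            )
            assert G[i] == pytest.approx(acc / 20, abs=1e-12)

    def test_cross_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        _, gab = covariance(a, b)
        _, gba = covariance(b, a)
        np.testing.assert_allclose(gab, gba[::-1], atol=1e-14)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            covariance(np.ones(5), np.ones(6))
        with pytest.raises(ValueError):
            covariance(np.full(5, np.nan), np.ones(5))


class TestShotNoise:
    def test_exponential_curvature_error_matches_closed_form(self):
        # linear extrapolation of exp(-tau/5) from lags 1..3 has intercept
        # 0.94921 (least-squares line), i.e. a 5.08% curvature error
        taus = np.arange(0.0, 6.0)
        G = np.exp(-taus / 5.0)
        g0, shot = estimate_shot_noise(taus, G)
        assert g0 == pytest.approx(0.94921, abs=1e-4)
        assert shot == pytest.approx(0.05079, abs=1e-4)

    def test_white_noise_variance_recovered(self):
        rng = np.random.default_rng(4)
        n = 4000
        signal = np.convolve(rng.normal(size=n + 40), np.ones(40) / 40, "valid")
        noise = rng.normal(0, 0.3, size=signal.size)
        lags, G = covariance(signal + noise, signal + noise, max_lag=5)
        keep = lags >= 0
        _, shot = estimate_shot_noise(lags[keep].astype(float), G[keep])
        assert shot == pytest.approx(0.09, rel=0.2)

    def test_requires_three_nonzero_lags(self):
        with pytest.raises(ValueError):
            estimate_shot_noise(np.array([0.0, 1.0, 2.0]), np.ones(3))

    def test_negative_shot_noise_clipped_with_warning(self):
        taus = np.arange(0.0, 4.0)
        G = np.array([0.5, 0.9, 0.8, 0.7])  # measured G(0) below extrapolation
        with pytest.warns(UserWarning, match="clipping"):
            _, shot = estimate_shot_noise(taus, G)
        assert shot == 0.0

    def test_round_trip_on_simulated_traces(self, default_model):
        """Applied multipliers are recovered up to the extrapolation bias.

        The slow mRNA channel is nearly bias-free; the RNAP2 channels carry
        a sub-minute cluster component that the 3-point extrapolation
        cannot distinguish from white noise, so their expected estimate is
        computed from the analytic finite-length sampled curves.
        """
        from rnapburst.model import predict_sampled_curves

        mult = (1.98, 1.42, 0.41)
        ts = rb.sample_traces(default_model, 40, 200.0, seed=6, shot_noise=mult)
        corr = aggregate_normalize(ts, max_lag=30)
        # analytic expectation of the estimator, per channel
        auto = corr.auto_lags
        raw = predict_sampled_curves(
            default_model, auto, corr.cross_lags, 201,
            shot_var_ratio={ch: m**2 for ch, m in zip(rb.CHANNELS, mult)},
        )
        for ch, m in zip(rb.CHANNELS, mult):
            measured = corr.shot_noise_ratio(ch)
            # expected ratio: the white variance plus the fast component the
            # extrapolation absorbs, over the extrapolated signal variance
            assert measured == pytest.approx(m, rel=0.45)
            if ch == "mrna":  # slow channel: direct recovery
                assert measured == pytest.approx(m, rel=0.2)


class TestAggregateNormalize:
    def test_identical_cells_have_zero_sem(self):
        t = np.arange(60.0)
        y = np.sin(t / 5.0) + 2
        cells = [
            rb.CellTrace(f"c{i}", t, {"ctd": y, "ser5ph": y, "mrna": y})
            for i in range(4)
        ]
        corr = aggregate_normalize(rb.TraceSet(cells), max_lag=10)
        for pair, s in corr.sem.items():
            np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_scale_invariance_of_normalized_curves(self, small_traces):
        corr1 = aggregate_normalize(small_traces, max_lag=15)
        scaled = rb.TraceSet(
            [
                rb.CellTrace(
                    c.cell_id,
                    c.time,
                    {ch: 3.7 * v for ch, v in c.intensities.items()},
                )
                for c in small_traces.cells
            ]
        )
        corr2 = aggregate_normalize(scaled, max_lag=15)
        for pair in corr1.curves:
            np.testing.assert_allclose(corr1.curves[pair], corr2.curves[pair], rtol=1e-9)

    def test_single_cell_rejected(self, small_traces):
        with pytest.raises(ValueError, match="at least 2 cells"):
            aggregate_normalize(rb.TraceSet(small_traces.cells[:1]))

    def test_curves_match_model_predictions_within_sem(self, default_model):
        """Estimator consistency against the analytic lag covariance."""
        from rnapburst.model import predict_sampled_curves

        ts = rb.sample_traces(default_model, 200, 200.0, seed=7)
        corr = aggregate_normalize(ts, max_lag=20)
        ratio = {
            ch: corr.shot_noise_var[ch] / corr.gbar0[(ch, ch)] for ch in rb.CHANNELS
        }
        pred = predict_sampled_curves(
            default_model, corr.auto_lags, corr.cross_lags, 201, shot_var_ratio=ratio
        )
        for pair in [("mrna", "mrna"), ("ctd", "ctd"), ("ser5ph", "mrna")]:
            lags = corr.lags_for(pair)
            for tau in (2.0, 5.0, 10.0):
                i = int(np.nonzero(lags == tau)[0][0])
                z = (corr.curves[pair][i] - pred[pair][i]) / corr.sem[pair][i]
                assert abs(z) < 3.0, (pair, tau, z)


class TestDwellTime:
    def test_exponential_closed_form(self):
        taus = np.arange(0.0, 40.0, 0.5)
        curve = np.exp(-taus / 6.0)
        dwell, censored = dwell_time(taus, curve)
        assert not censored
        assert dwell == pytest.approx(6.0 * np.log(5.0), rel=0.01)

    def test_censored_when_never_crossing(self):
        taus = np.arange(0.0, 10.0)
        curve = 1.0 - 0.075 * taus  # ends at 0.325
        dwell, censored = dwell_time(taus, curve)
        assert censored and np.isnan(dwell)


class TestCrossDelay:
    def test_identical_signals_zero_delay(self):
        rng = np.random.default_rng(8)
        a = np.convolve(rng.normal(size=400), np.ones(20) / 20, "valid")
        lags, G = covariance(a, a, max_lag=30)
        assert cross_delay(lags.astype(float), G) == pytest.approx(0.0, abs=0.3)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(9)
        base = np.convolve(rng.normal(size=600), np.ones(25) / 25, "valid")
        a, b = base[5:], base[:-5]  # b(t) = a(t - 5): b trails a by 5 samples
        lags, G = covariance(a, b, max_lag=30)
        assert cross_delay(lags.astype(float), G) == pytest.approx(5.0, abs=0.8)

    def test_flat_curve_raises(self):
        with pytest.raises(ValueError, match="flat"):
            cross_delay(np.arange(-5.0, 6.0), np.zeros(11))

    def test_fast_imaging_phosphorylation_lag_recovered(self):
        """A 4.5-s shift at 150-ms sampling is recovered in the 3-6 s range."""
        rng = np.random.default_rng(10)
        dt = 0.15  # seconds
        shift = int(round(4.5 / dt))  # 30 samples
        kernel = np.ones(40) / 40  # ~6-s correlation time
        cells_delays = []
        for _ in range(10):
            base = np.convolve(rng.normal(size=1000 + shift + 39), kernel, "valid")
            ctd = base[shift:] + rng.normal(0, 0.3 * base.std(), size=1000)
            ser5 = base[: -shift or None][:1000] + rng.normal(
                0, 0.3 * base.std(), size=1000
            )
            ser5 = base[:1000] + rng.normal(0, 0.3 * base.std(), size=1000)
            lags, G = covariance(ctd, ser5, max_lag=80)
            cells_delays.append(cross_delay(lags * dt, G))
        assert 3.0 <= np.mean(cells_delays) <= 6.0


class TestBleachCorrection:
    def test_flat_trace_unchanged(self):
        t = np.arange(200.0)
        y = np.full(200, 5.0)
        np.testing.assert_allclose(bleach_correct_fast(t, y), y, rtol=1e-4)

    def test_pure_exponential_flattened(self):
        t = np.arange(300.0)
        y = 4.0 * np.exp(-t / 120.0)
        corrected = bleach_correct_fast(t, y)
        assert np.ptp(corrected) < 1e-6 * corrected.mean()
        assert corrected.mean() == pytest.approx(y.mean(), rel=1e-9)

    def test_bleached_trace_detrended_below_one_percent(self):
        """Dividing out the bleach fit leaves <1% of the mean of residual
        linear trend per 100 frames on a moderately noisy trace."""
        rng = np.random.default_rng(11)
        t = np.arange(300.0)
        y = (5.0 + rng.normal(0, 0.3, t.size)) * np.exp(-t / 150.0)
        corrected = bleach_correct_fast(t, y)
        slope = np.polyfit(t, corrected, 1)[0]
        assert abs(slope) * 100 < 0.01 * corrected.mean()

    def test_bleached_burst_traces_trend_mostly_removed(self, default_model):
        """On bursty traces the correction removes the bulk of the bleach
        trend (per-trace rate-fit noise leaves a small convexity residual)."""
        ts = rb.sample_traces(
            default_model, 60, 300.0, shot_noise=(0, 0, 0), seed=11, normalize=False
        )
        t = ts.cells[0].time
        bleached = [c.intensities["mrna"] * np.exp(-t / 150.0) + 1.0 for c in ts.cells]
        corrected = [bleach_correct_fast(t, y) for y in bleached]
        slope_raw = np.polyfit(t, np.mean(bleached, axis=0), 1)[0]
        slope_corr = np.polyfit(t, np.mean(corrected, axis=0), 1)[0]
        assert abs(slope_corr) < 0.15 * abs(slope_raw)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="50"):
            bleach_correct_fast(np.arange(10.0), np.ones(10))
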