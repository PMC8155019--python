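"""Intensity extraction, minima alignment, spatial stats, run-off fits."""

import numpy as np
import pytest

import rnapburst as rb
from rnapburst.trace_analysis import _local_minima, moving_average3


class TestRawIntensity:
    def test_background_equal_site_gives_zeros(self):
        x = np.linspace(1, 5, 20)
        np.testing.assert_allclose(rb.raw_intensity(x, x), 0.0, atol=1e-12)

    def test_hand_computed_smoothing_with_shrunken_edges(self):
        out = rb.raw_intensity(np.array([1.0, 4.0, 7.0, 10.0]))
        np.testing.assert_allclose(out, [2.5, 4.0, 7.0, 8.5])

    def test_matches_independent_rolling_mean_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        oracle = pd.Series(x).rolling(3, center=True, min_periods=1).mean().to_numpy()
        np.testing.assert_allclose(rb.raw_intensity(x), oracle)

    def test_can_dip_below_zero(self):
        out = rb.raw_intensity(np.array([1.0, 1.0, 1.0, 1.0]), 2.0)
        assert np.all(out < 0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            rb.raw_intensity(np.array([1.0, 2.0]))

    def test_smoothing_commutes_with_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        # away from the edges, smoothing then shifting == shifting then smoothing
        np.testing.assert_allclose(
            moving_average3(x)[2:-1], moving_average3(x[1:])[1:-1]
        )


class TestFindMinima:
    def test_monotone_trace_has_no_events(self):
        t = np.arange(40.0)
        cells = [rb.CellTrace("c0", t, {"mrna": t / 40.0})]
        assert rb.find_minima_events(rb.TraceSet(cells)) == []

    def test_constructed_valleys_found_at_known_times(self):
        t = np.arange(100.0)
        y = 0.6 + 0.1 * np.sin(t)  # stays above threshold
        valleys = [20, 40, 60, 80]
        for v in valleys:
            y[v] = 0.05
        cells = [rb.CellTrace("c0", t, {"mrna": y, "ctd": y, "ser5ph": y})]
        events = rb.find_minima_events(rb.TraceSet(cells), threshold=0.2)
        assert [e.index for e in events] == valleys
        assert all(len(e.windows["ctd"]) == 15 for e in events)

    def test_plateau_takes_leftmost_point(self):
        x = np.array([3.0, 1.0, 1.0, 1.0, 3.0, 2.0, 4.0])
        assert list(_local_minima(x)) == [1, 5]

    def test_edge_events_dropped(self):
        t = np.arange(20.0)
        y = np.ones(20)
        y[3] = 0.0  # too close to the start for a 7-sample window
        cells = [rb.CellTrace("c0", t, {"mrna": y})]
        assert rb.find_minima_events(rb.TraceSet(cells)) == []

    def test_paper_scale_synthetic_yields_tens_of_valleys(self, paper_scale_dataset):
        """With one event per valley (noise-split minima merged over the
        7-min window scale), a 20-cell experiment yields tens of events."""
        _, traces, _, _ = paper_scale_dataset
        sm = rb.TraceSet(
            [
                rb.CellTrace(
                    c.cell_id,
                    c.time,
                    {ch: moving_average3(v) for ch, v in c.intensities.items()},
                )
                for c in traces.cells
            ]
        )
        events = rb.find_minima_events(sm, threshold=0.20, merge_within=7.0)
        assert 20 <= len(events) <= 200


class TestAlignAndFit:
    def _valley_traces(self, shift=0, n_cells=8, seed=2):
        """Cells with synchronized valleys; RNAP2 channels lead by ``shift``."""
        rng = np.random.default_rng(seed)
        t = np.arange(120.0)
        cells = []
        for i in range(n_cells):
            base = np.ones(120)
            for center in (20, 60, 100):
                base -= 0.95 * np.exp(-((t - center) ** 2) / 8.0)
            noise = lambda: rng.normal(0, 0.03, size=120)
            mrna = base + noise()
            lead = np.ones(120)
            for center in (20, 60, 100):
                lead -= 0.95 * np.exp(-((t - center + shift) ** 2) / 8.0)
            cells.append(
                rb.CellTrace(
                    f"c{i}",
                    t,
                    {"mrna": mrna, "ctd": lead + noise(), "ser5ph": lead + noise()},
                )
            )
        return rb.TraceSet(cells)

    def test_shared_valleys_fit_at_zero(self):
        ts = self._valley_traces(shift=0)
        events = rb.find_minima_events(ts, threshold=0.2)
        fits = rb.align_and_fit_minima(events)
        for ch, fit in fits.items():
            assert fit.converged
            assert fit.t_min == pytest.approx(0.0, abs=0.5), ch

    def test_rnap2_lead_recovered(self):
        ts = self._valley_traces(shift=1.0)
        events = rb.find_minima_events(ts, threshold=0.2)
        fits = rb.align_and_fit_minima(events)
        for ch in ("ctd", "ser5ph"):
            lead = fits["mrna"].t_min - fits[ch].t_min
            assert lead == pytest.approx(1.0, abs=0.5), ch

    def test_random_timepoint_control_on_stationary_data(self, paper_scale_dataset):
        """Minima are significant vs control; control shows no deep minimum."""
        _, traces, _, _ = paper_scale_dataset
        events = rb.find_minima_events(traces, threshold=0.2)
        fits = rb.align_and_fit_minima(events, traces=traces, seed=4)
        assert fits["mrna"].p_value < 0.01
        # aligned mRNA valley is much deeper than the control dip
        assert fits["mrna"].depth > 2 * fits["mrna"].control_depth

    def test_too_few_events_rejected(self):
        ts = self._valley_traces()
        events = rb.find_minima_events(ts, threshold=0.2)[:3]
        with pytest.raises(ValueError, match="at least 5"):
            rb.align_and_fit_minima(events)


class TestPairwiseDistances:
    def test_identical_tracks_zero_distance(self):
        t = np.arange(100.0)
        rng = np.random.default_rng(5)
        walk = rng.normal(size=(100, 2)).cumsum(axis=0)
        cells = [
            rb.CellTrace(
                "c0",
                t,
                {ch: np.zeros(100) for ch in rb.CHANNELS},
                positions={ch: walk for ch in rb.CHANNELS},
            )
        ]
        res = rb.pairwise_distances(rb.TraceSet(cells))
        assert all(m == 0 for m in res.medians.values())

    def test_default_geometry_recovers_published_separations(self):
        cfg = rb.ExperimentConfig(seed=11)
        tracks = rb.make_positions(cfg, n_cells=13)
        res = rb.pairwise_distances(tracks)
        assert res.medians[("ctd", "mrna")] == pytest.approx(181.0, rel=0.10)
        assert res.medians[("ser5ph", "mrna")] == pytest.approx(148.0, rel=0.10)
        assert res.medians[("ctd", "ser5ph")] == pytest.approx(93.0, rel=0.10)

    def test_noise_only_median_follows_rayleigh_prediction(self):
        # two channels at zero offset with iid per-frame noise of SD s per
        # axis: after w-frame averaging the difference is Gaussian with SD
        # s*sqrt(2/w) per axis, so the distance is Rayleigh with median
        # s*sqrt(2/w)*sqrt(2 ln 2)
        s, w = 40.0, 50
        cfg = rb.ExperimentConfig(
            separations=(1e-9, 1e-9, 1e-9), localization_sd=s, seed=12,
            duration=500.0,
        )
        tracks = rb.make_positions(cfg, n_cells=30)
        res = rb.pairwise_distances(tracks, window=w, sample_every=10.0)
        expected = s * np.sqrt(2.0 / w) * np.sqrt(2 * np.log(2))
        assert res.medians[("ctd", "ser5ph")] == pytest.approx(expected, rel=0.1)

    def test_rigid_translation_invariance(self):
        cfg = rb.ExperimentConfig(seed=13)
        tracks = rb.make_positions(cfg, n_cells=3)
        shifted_cells = []
        for c in tracks.cells:
            shifted_cells.append(
                rb.CellTrace(
                    c.cell_id,
                    c.time,
                    c.intensities,
                    positions={ch: p + np.array([500.0, -300.0]) for ch, p in c.positions.items()},
                )
            )
        r1 = rb.pairwise_distances(tracks)
        r2 = rb.pairwise_distances(rb.TraceSet(shifted_cells))
        for pair in r1.medians:
            assert r1.medians[pair] == pytest.approx(r2.medians[pair], rel=1e-12)

    def test_short_track_rejected(self):
        t = np.arange(10.0)
        cells = [
            rb.CellTrace(
                "c0",
                t,
                {ch: np.zeros(10) for ch in rb.CHANNELS},
                positions={ch: np.zeros((10, 2)) for ch in rb.CHANNELS},
            )
        ]
        with pytest.raises(ValueError, match="shorter than"):
            rb.pairwise_distances(rb.TraceSet(cells))


class TestCovarianceControls:
    def test_bleedthrough_mixture_detected(self):
        rng = np.random.default_rng(6)
        t = np.arange(150.0)
        on_cells, off_cells = [], []
        for i in range(10):
            sig = np.convolve(rng.normal(size=170), np.ones(20) / 20, "valid")[:150]
            on = {
                "ctd": sig + rng.normal(0, 0.1, 150),
                "ser5ph": 0.3 * sig + rng.normal(0, 0.1, 150),
                "mrna": sig + rng.normal(0, 0.1, 150),
            }
            off = {ch: rng.normal(0, 0.1, 150) for ch in rb.CHANNELS}
            on_cells.append(rb.CellTrace(f"c{i}", t, on))
            off_cells.append(rb.CellTrace(f"c{i}", t, off))
        table = rb.covariance_controls(
            rb.TraceSet(on_cells), rb.TraceSet(off_cells)
        )
        row = table[table["pair"] == "ctd-ser5ph"].iloc[0]
        assert row["cov_on_target"] > 5 * abs(row["cov_off_target"])
        assert row["p_value"] < 1e-3

    def test_identical_channels_covariance_equals_variance(self):
        rng = np.random.default_rng(7)
        t = np.arange(100.0)
        y = rng.normal(size=100)
        cells = [rb.CellTrace("c0", t, {"ctd": y, "ser5ph": y, "mrna": y})]
        table = rb.covariance_controls(
            rb.TraceSet(cells), rb.TraceSet(cells)
        )
        assert table["cov_on_target"].iloc[0] == pytest.approx(np.var(y, ddof=1))

    def test_unpaired_inputs_rejected(self):
        t = np.arange(60.0)
        mk = lambda cid: rb.CellTrace(cid, t, {ch: np.zeros(60) for ch in rb.CHANNELS})
        with pytest.raises(ValueError, match="paired"):
            rb.covariance_controls(
                rb.TraceSet([mk("a"), mk("b")]), rb.TraceSet([mk("a")])
            )


class TestRunoffAlignment:
    def _decay_traces(self, offsets=(0.0, 0.0, 0.0), n_cells=8, seed=8):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 40.0)
        cells = []
        for i in range(n_cells):
            jitter = rng.normal(0, 1.0)  # cell-to-cell timing variability
            intens = {}
            for ch, off in zip(rb.CHANNELS, offsets):
                clean = 1.0 - 0.5 * (1 + np.tanh((t - 12.0 - off - jitter) / 2.0))
                intens[ch] = clean + rng.normal(0, 0.03, t.size)
            cells.append(rb.CellTrace(f"c{i}", t, intens))
        return rb.TraceSet(cells)

    def test_identical_decays_zero_delays(self):
        res = rb.runoff_alignment(self._decay_traces(), t_drug=5.0)
        for delay in res.delays.values():
            assert delay == pytest.approx(0.0, abs=0.3)

    def test_constructed_offsets_recovered(self):
        res = rb.runoff_alignment(
            self._decay_traces(offsets=(0.0, 0.5, 1.5)), t_drug=5.0
        )
        assert res.delays[("ctd", "ser5ph")] == pytest.approx(0.5, abs=0.35)
        assert res.delays[("ctd", "mrna")] == pytest.approx(1.5, abs=0.35)

    def test_block_burst_simulation_orders_ctd_ser5ph_mrna(self):
        """Burst inhibition drains the unphosphorylated pool first and the
        mRNA signal last."""
        params = rb.DEFAULT_PARAMS.replace(variant_extras={"k_phos": 2.0})
        model = rb.build_model("phospho_step", params)
        res = rb.perturb(
            model, "block_burst", t_drug=10.0, duration=60.0, n_cells=150, seed=9
        )
        ens = rb.TraceSet(
            [rb.CellTrace("mean", res.time, res.mean)]
            + [rb.CellTrace("mean2", res.time, res.mean)]
        )
        fit = rb.runoff_alignment(ens, t_drug=10.0)
        assert fit.t_half["ctd"] < fit.t_half["ser5ph"] < fit.t_half["mrna"]

    def test_non_decaying_trace_excluded(self):
        ts = self._decay_traces(n_cells=4)
        t = ts.cells[0].time
        flat = rb.CellTrace(
            "flat", t, {ch: np.ones(t.size) for ch in rb.CHANNELS}
        )
        res = rb.runoff_alignment(rb.TraceSet(ts.cells + [flat]), t_drug=5.0)
        assert "flat" in res.excluded
        assert res.n_cells_used == 4
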