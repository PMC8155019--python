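"""Trace-level analysis procedures for transcription-site movies.

Covers intensity extraction (background subtraction + 3-point moving
average), detection and alignment of mRNA minima, spatial statistics of
per-channel centroid tracks, covariance controls against off-target spots,
and alignment of inhibitor run-off decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu

from .containers import CHANNELS, TraceSet

__all__ = [
    "raw_intensity",
    "normalize_traces",
    "MinimaEvent",
    "find_minima_events",
    "align_and_fit_minima",
    "pairwise_distances",
    "covariance_controls",
    "runoff_alignment",
]

PAIR_KEYS = (("ctd", "mrna"), ("ser5ph", "mrna"), ("ctd", "ser5ph"))


def moving_average3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average with shrunken edge windows."""
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(3, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def raw_intensity(i_ts: np.ndarray, i_bg: np.ndarray | float = 0.0) -> np.ndarray:
    """Background-subtracted, 3-point moving-averaged intensity trace.

    May dip below zero when the background ring outshines the site.
    """
    i_ts = np.asarray(i_ts, dtype=float)
    if i_ts.size < 3:
        raise ValueError("need at least 3 frames for the moving average")
    return moving_average3(i_ts - np.asarray(i_bg, dtype=float))


def normalize_traces(traces: TraceSet, q: float = 95.0) -> TraceSet:
    """Divide each channel by the average 95th-percentile intensity over cells."""
    scales = {
        ch: np.mean([np.percentile(c.intensities[ch], q) for c in traces.cells])
        for ch in traces.channels
    }
    cells = []
    for c in traces.cells:
        cells.append(
            type(c)(
                cell_id=c.cell_id,
                time=c.time,
                intensities={
                    ch: v / (scales[ch] if scales[ch] != 0 else 1.0)
                    for ch, v in c.intensities.items()
                },
                positions=c.positions,
                meta=dict(c.meta),
            )
        )
    return TraceSet(cells=cells, meta={**traces.meta, "normalized": True})


@dataclass
class MinimaEvent:
    """One sub-threshold mRNA valley with aligned windows of all channels."""

    cell_id: str
    index: int
    time: float
    windows: dict[str, np.ndarray]  # channel -> (2*half+1,)


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; plateaus contribute their left edge."""
    idx = []
    n = x.size
    for i in range(1, n - 1):
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] > x[i]:
                idx.append(i)
    return np.asarray(idx, dtype=int)


def find_minima_events(
    traces: TraceSet,
    threshold: float = 0.20,
    half_window: int = 7,
    channel: str = "mrna",
    merge_within: float | None = None,
) -> list[MinimaEvent]:
    """Sub-threshold local minima of the normalized mRNA trace per cell.

    Windows of ``half_window`` samples on either side (15 points at 1-min
    sampling) are extracted for every channel; events too close to the
    trace ends are dropped.  Measurement noise can split one valley into
    several neighbouring minima; ``merge_within`` (minutes) keeps only the
    deepest minimum among events closer than that spacing.
    """
    events = []
    for cell in traces.cells:
        if channel not in cell.intensities:
            raise ValueError(f"channel {channel!r} missing from cell {cell.cell_id}")
        x = cell.intensities[channel]
        idx = [
            i
            for i in _local_minima(x)
            if x[i] <= threshold and half_window <= i < x.size - half_window
        ]
        if merge_within is not None and idx:
            min_sep = merge_within / cell.dt
            merged: list[int] = [idx[0]]
            for i in idx[1:]:
                if i - merged[-1] < min_sep:
                    if x[i] < x[merged[-1]]:
                        merged[-1] = i
                else:
                    merged.append(i)
            idx = merged
        for i in idx:
            events.append(
                MinimaEvent(
                    cell_id=cell.cell_id,
                    index=i,
                    time=float(cell.time[i]),
                    windows={
                        ch: cell.intensities[ch][i - half_window : i + half_window + 1]
                        for ch in cell.intensities
                    },
                )
            )
    return events


def _inverted_gaussian(t, base, amp, t0, width):
    return base - amp * np.exp(-((t - t0) ** 2) / (2.0 * width**2))


@dataclass
class MinimaFit:
    channel: str
    t_min: float
    t_min_se: float
    depth: float
    depth_se: float
    baseline: float
    converged: bool
    control_depth: float | None = None
    p_value: float | None = None


def align_and_fit_minima(
    events: list[MinimaEvent],
    traces: TraceSet | None = None,
    dt: float = 1.0,
    n_control: int = 300,
    seed: int = 0,
) -> dict[str, MinimaFit]:
    """Channel-averaged minima windows fitted with an inverted Gaussian.

    Returns the fitted minimum time (relative to the aligned mRNA valley)
    and depth with their fit standard errors per channel.  When ``traces``
    is given, the analysis is repeated at random time points as a negative
    control and a two-sided Mann-Whitney test compares the per-event window
    minima against the control windows.
    """
    if len(events) < 5:
        raise ValueError("need at least 5 events to fit aligned minima")
    half = (len(next(iter(events[0].windows.values()))) - 1) // 2
    rel_t = np.arange(-half, half + 1) * dt
    channels = list(events[0].windows)
    control_windows: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    if traces is not None:
        rng = np.random.default_rng(seed)
        cells = traces.cells
        for _ in range(n_control):
            cell = cells[rng.integers(len(cells))]
            n = cell.time.size
            i = int(rng.integers(half, n - half))
            for ch in channels:
                control_windows[ch].append(
                    cell.intensities[ch][i - half : i + half + 1]
                )
    out: dict[str, MinimaFit] = {}
    for ch in channels:
        stack = np.vstack([e.windows[ch] for e in events])
        mean_win = stack.mean(axis=0)
        p0 = (
            float(np.max(mean_win)),
            float(np.ptp(mean_win)),
            float(rel_t[np.argmin(mean_win)]),
            2.0,
        )
        try:
            popt, pcov = curve_fit(
                _inverted_gaussian,
                rel_t,
                mean_win,
                p0=p0,
                bounds=((-np.inf, 0, rel_t[0], 0.3), (np.inf, np.inf, rel_t[-1], 50)),
                maxfev=20000,
            )
            perr = np.sqrt(np.diag(pcov))
            fit = MinimaFit(
                channel=ch,
                t_min=float(popt[2]),
                t_min_se=float(perr[2]),
                depth=float(popt[1]),
                depth_se=float(perr[1]),
                baseline=float(popt[0]),
                converged=True,
            )
        except RuntimeError:
            fit = MinimaFit(ch, np.nan, np.nan, np.nan, np.nan, np.nan, False)
        if traces is not None and control_windows[ch]:
            ctrl = np.vstack(control_windows[ch])
            fit.control_depth = float(np.mean(ctrl.mean(axis=0)) - ctrl.mean(axis=0).min())
            event_minima = stack.min(axis=1)
            ctrl_minima = ctrl.min(axis=1)
            fit.p_value = float(
                mannwhitneyu(event_minima, ctrl_minima, alternative="two-sided").pvalue
            )
        out[ch] = fit
    return out


@dataclass
class DistanceResult:
    distances: dict[tuple[str, str], np.ndarray]  # pooled, nm
    medians: dict[tuple[str, str], float]
    quartiles: dict[tuple[str, str], tuple[float, float]]
    p_values: dict[tuple[tuple[str, str], tuple[str, str]], float] = field(
        default_factory=dict
    )


def _moving_average_positions(pos: np.ndarray, window: int) -> np.ndarray:
    """Rolling-mean smoothing of an (n, 2) track; valid region only."""
    if pos.shape[0] < window:
        raise ValueError("track shorter than the averaging window")
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(pos[:, k], kernel, mode="valid") for k in range(2)]
    )
    return out


def pairwise_distances(
    traces: TraceSet,
    window: int = 50,
    sample_every: float = 10.0,
    pairs: tuple[tuple[str, str], ...] = PAIR_KEYS,
) -> DistanceResult:
    """Euclidean inter-channel distances of moving-averaged centroid tracks.

    Each channel's XY track is smoothed with a ``window``-frame moving
    average; pairwise distances are sampled every ``sample_every`` minutes
    and pooled over cells.  Medians, quartiles and pairwise Mann-Whitney
    comparisons between distance distributions are returned.
    """
    pooled: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in pairs}
    for cell in traces.cells:
        if cell.positions is None:
            raise ValueError(f"cell {cell.cell_id} has no position tracks")
        smoothed = {
            ch: _moving_average_positions(cell.positions[ch], window)
            for ch in cell.positions
        }
        t_valid = cell.time[window - 1 :]
        step = max(1, int(round(sample_every / cell.dt)))
        sel = slice(0, t_valid.size, step)
        for a, b in pairs:
            d = np.linalg.norm(smoothed[a][sel] - smoothed[b][sel], axis=1)
            pooled[(a, b)].append(d)
    distances = {p: np.concatenate(v) for p, v in pooled.items()}
    medians = {p: float(np.median(d)) for p, d in distances.items()}
    quartiles = {
        p: (float(np.percentile(d, 25)), float(np.percentile(d, 75)))
        for p, d in distances.items()
    }
    p_values = {}
    keys = list(pairs)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            p_values[(keys[i], keys[j])] = float(
                mannwhitneyu(
                    distances[keys[i]], distances[keys[j]], alternative="two-sided"
                ).pvalue
            )
    return DistanceResult(
        distances=distances, medians=medians, quartiles=quartiles, p_values=p_values
    )


def covariance_controls(
    on_target: TraceSet, off_target: TraceSet, pairs=PAIR_KEYS
) -> pd.DataFrame:
    """Channel-pair covariances at the site vs at an off-target spot.

    Cells must be paired (same ids, same order).  Returns per-pair mean
    covariance in both conditions and a two-sided Mann-Whitney p-value over
    the per-cell covariances.
    """
    if len(on_target) != len(off_target):
        raise ValueError("on/off-target trace sets must be paired")
    for c_on, c_off in zip(on_target.cells, off_target.cells):
        if c_on.cell_id != c_off.cell_id:
            raise ValueError("on/off-target cell ids do not match")
    rows = []
    for a, b in pairs:
        on_covs = [
            float(np.cov(c.intensities[a], c.intensities[b])[0, 1])
            for c in on_target.cells
        ]
        off_covs = [
            float(np.cov(c.intensities[a], c.intensities[b])[0, 1])
            for c in off_target.cells
        ]
        p = float(mannwhitneyu(on_covs, off_covs, alternative="two-sided").pvalue)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "cov_on_target": np.mean(on_covs),
                "cov_off_target": np.mean(off_covs),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _tanh_decay(t, a, b, t_half, width):
    return a - b * np.tanh((t - t_half) / width)


@dataclass
class RunoffResult:
    t_half: dict[str, float]  # fitted half-decay time per channel [min]
    t_half_se: dict[str, float]
    delays: dict[tuple[str, str], float]  # (a, b) -> t_half[b] - t_half[a]
    n_cells_used: int
    excluded: list[str]
    aligned_time: np.ndarray | None = None
    aligned_mean: dict[str, np.ndarray] | None = None


def runoff_alignment(
    traces: TraceSet,
    t_drug: float,
    channels: tuple[str, ...] = CHANNELS,
) -> RunoffResult:
    """Align inhibitor run-off decays and estimate inter-channel delays.

    Each cell and channel is fitted with the sigmoidal decay
    ``A - B tanh((t - t_half)/w)``; cells whose mRNA channel does not decay
    are excluded.  Traces are aligned by subtracting the cell's mean fitted
    half-decay time, channel-averaged, and refitted with inverse-variance
    weights; delays are differences of the final fitted half-decay times.
    """
    per_cell_thalf: dict[str, dict[str, float]] = {}
    excluded = []
    for cell in traces.cells:
        fits = {}
        ok = True
        for ch in channels:
            y = cell.intensities[ch]
            t = cell.time
            pre = y[t < t_drug]
            # a decaying trace must actually drop from its pre-drug level
            head = y[: max(3, y.size // 4)].mean()
            tail = y[-max(3, y.size // 4) :].mean()
            if head - tail < 0.2 * max(abs(head), 1e-12):
                ok = False
                break
            a0 = 0.5 * (pre.mean() if pre.size else y[:3].mean())
            try:
                popt, _ = curve_fit(
                    _tanh_decay,
                    t,
                    y,
                    p0=(a0, max(a0, 1e-3), t_drug + 2.0, 2.0),
                    bounds=(
                        (-np.inf, 1e-9, t[0], 0.1),
                        (np.inf, np.inf, t[-1], t[-1] - t[0]),
                    ),
                    maxfev=20000,
                )
            except RuntimeError:
                ok = False
                break
            fits[ch] = float(popt[2])
        if ok:
            per_cell_thalf[cell.cell_id] = fits
        else:
            excluded.append(cell.cell_id)
    if not per_cell_thalf:
        raise ValueError("no cell shows a fittable decay in all channels")

    # align: one shift per cell = mean of its channel half-decay times
    shifts = {cid: np.mean(list(f.values())) for cid, f in per_cell_thalf.items()}
    used = [c for c in traces.cells if c.cell_id in shifts]
    rel_grid = None
    dt = used[0].dt
    t_mins = [c.time[0] - shifts[c.cell_id] for c in used]
    t_maxs = [c.time[-1] - shifts[c.cell_id] for c in used]
    rel_grid = np.arange(max(t_mins), min(t_maxs) + 0.5 * dt, dt)
    mean_curves: dict[str, np.ndarray] = {}
    t_half: dict[str, float] = {}
    t_half_se: dict[str, float] = {}
    for ch in channels:
        interp = np.vstack(
            [
                np.interp(rel_grid, c.time - shifts[c.cell_id], c.intensities[ch])
                for c in used
            ]
        )
        mean = interp.mean(axis=0)
        sd = interp.std(axis=0, ddof=1) if len(used) > 1 else np.ones_like(mean)
        sd = np.where(sd <= 0, np.nanmax([sd.max(), 1e-9]), sd)
        popt, pcov = curve_fit(
            _tanh_decay,
            rel_grid,
            mean,
            p0=(mean.mean(), max(np.ptp(mean) / 2, 1e-6), 0.0, 2.0),
            sigma=sd / np.sqrt(len(used)),
            absolute_sigma=False,
            bounds=(
                (-np.inf, 1e-9, rel_grid[0], 0.1),
                (np.inf, np.inf, rel_grid[-1], rel_grid[-1] - rel_grid[0]),
            ),
            maxfev=20000,
        )
        mean_curves[ch] = mean
        t_half[ch] = float(popt[2])
        t_half_se[ch] = float(np.sqrt(pcov[2, 2]))
    delays = {}
    for i, a in enumerate(channels):
        for b in channels[i + 1 :]:
            delays[(a, b)] = t_half[b] - t_half[a]
    return RunoffResult(
        t_half=t_half,
        t_half_se=t_half_se,
        delays=delays,
        n_cells_used=len(used),
        excluded=excluded,
        aligned_time=rel_grid,
        aligned_mean=mean_curves,
    )
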