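"""Fluctuation auto/cross-covariance analysis of transcription-site traces.

The estimators mirror fluorescence correlation analysis on a sampled grid:
per-trace temporal means are removed, the biased (divide-by-N) covariance
G(tau) = <da(t) db(t+tau)> is computed per cell, curves are normalized by
the zero-lag covariance averaged over replicas, and the zero-lag auto
values are corrected for shot noise by linear extrapolation from the three
shortest nonzero lags.  Shot noise is white, so it contributes to the auto
covariance only at tau = 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .containers import ALL_PAIRS, CorrelationSet, TraceSet

__all__ = [
    "covariance",
    "aggregate_normalize",
    "estimate_shot_noise",
    "dwell_time",
    "cross_delay",
    "bleach_correct_fast",
]


def covariance(
    a: np.ndarray, b: np.ndarray, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample covariance function G(tau) = <da(t) db(t+tau)> on integer lags.

    Uses the biased estimator (every lag divided by the full trace length
    N), which trades a small downward bias for lower variance at long lags.
    Returns ``(lags, G)`` with lags in samples from ``-max_lag`` to
    ``+max_lag`` (defaults to N-1).  For ``a is b`` the result is symmetric.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 time points")
    if np.all(np.isnan(a)) or np.all(np.isnan(b)):
        raise ValueError("all-NaN trace")
    da = a - a.mean()
    db = b - b.mean()
    # full cross-correlation; index k of np.correlate(db, da, "full")
    # equals sum_t da[t] db[t + (k - (n-1))]
    full = np.correlate(db, da, mode="full") / n
    lags = np.arange(-(n - 1), n)
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        lags, full = lags[keep], full[keep]
    return lags, full


def estimate_shot_noise(
    lags: np.ndarray, G: np.ndarray
) -> tuple[float, float]:
    """Split measured G(0) into true signal variance and shot-noise variance.

    The shot-noise-free G(0) is the intercept of a least-squares line
    through the three shortest nonzero positive lags; the difference from
    the measured G(0) is the white (shot) noise variance, clipped at zero.
    """
    lags = np.asarray(lags, dtype=float)
    G = np.asarray(G, dtype=float)
    pos = lags > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 nonzero lags to extrapolate G(0)")
    order = np.argsort(lags[pos])
    x = lags[pos][order][:3]
    y = G[pos][order][:3]
    slope, intercept = np.polyfit(x, y, 1)
    g0_meas = float(G[lags == 0][0])
    shot = g0_meas - intercept
    if shot < 0:
        warnings.warn(
            "extrapolated G(0) exceeds the measured value; clipping "
            "shot-noise variance at 0",
            stacklevel=2,
        )
        shot = 0.0
    return float(intercept), float(shot)


def aggregate_normalize(
    traces: TraceSet,
    max_lag: float = 30.0,
    channels: tuple[str, ...] = ("ctd", "ser5ph", "mrna"),
) -> CorrelationSet:
    """Replica-averaged normalized covariance curves with SEM.

    Per cell and signal pair the covariance curve is computed, auto zero
    lags are shot-noise corrected, each pair's curves are normalized by the
    shared replica-averaged zero-lag value Gbar(0), and the mean and
    SEM (= SD/sqrt(N)) over cells are returned.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 cells for a SEM")
    dt = traces.cells[0].dt
    m = int(round(max_lag / dt))
    per_cell: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in ALL_PAIRS}
    shot_vars: dict[str, list[float]] = {ch: [] for ch in channels}
    lengths = {cell.time.size for cell in traces.cells}
    for cell in traces.cells:
        for a, b in ALL_PAIRS:
            lags, G = covariance(cell.intensities[a], cell.intensities[b], max_lag=m)
            if a == b:
                g0_true, shot = estimate_shot_noise(lags * dt, G)
                G = G[lags >= 0].copy()
                G[0] = g0_true  # corrected zero-lag point
                shot_vars[a].append(shot)
            per_cell[(a, b)].append(G)
    n = len(traces)
    curves, sems, gbar0 = {}, {}, {}
    for pair, glist in per_cell.items():
        stack = np.vstack(glist)
        zero_idx = 0 if pair[0] == pair[1] else stack.shape[1] // 2
        g0 = stack[:, zero_idx].mean()
        norm = stack / g0
        curves[pair] = norm.mean(axis=0)
        sems[pair] = norm.std(axis=0, ddof=1) / np.sqrt(n)
        gbar0[pair] = float(g0)
    return CorrelationSet(
        auto_lags=np.arange(0, m + 1) * dt,
        cross_lags=np.arange(-m, m + 1) * dt,
        curves=curves,
        sem=sems,
        gbar0=gbar0,
        shot_noise_var={ch: float(np.mean(v)) for ch, v in shot_vars.items()},
        n_cells=n,
        dt=dt,
        meta={"max_lag": max_lag, "n_points": lengths.pop() if len(lengths) == 1 else None},
    )


def dwell_time(
    lags: np.ndarray, curve: np.ndarray, threshold: float = 0.2
) -> tuple[float, bool]:
    """Lag at which a normalized autocovariance first falls below 20%.

    The curve is assumed corrected so curve[0] corresponds to 1; the
    crossing is linearly interpolated between the bracketing lags.  Returns
    ``(dwell, censored)``; censored is True when the curve never crosses.
    """
    lags = np.asarray(lags, dtype=float)
    curve = np.asarray(curve, dtype=float)
    below = np.nonzero(curve < threshold)[0]
    if below.size == 0:
        return np.nan, True
    i = below[0]
    if i == 0:
        return float(lags[0]), False
    x0, x1 = lags[i - 1], lags[i]
    y0, y1 = curve[i - 1], curve[i]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)), False


def cross_delay(lags: np.ndarray, curve: np.ndarray) -> float:
    """Peak lag of a cross-covariance curve via quadratic interpolation.

    A positive value means the second signal of the pair trails the first.
    """
    lags = np.asarray(lags, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if np.ptp(curve) < 1e-12 * max(1.0, np.abs(curve).max()):
        raise ValueError("flat cross-covariance curve: delay undefined")
    i = int(np.argmax(curve))
    if i == 0 or i == curve.size - 1:
        return float(lags[i])
    y0, y1, y2 = curve[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(lags[i])
    offset = 0.5 * (y0 - y2) / denom
    return float(lags[i] + offset * (lags[1] - lags[0]))


def bleach_correct_fast(time: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Divide out a single-exponential photobleaching decay (fast imaging).

    Fits A exp(-t/tau_b) and divides it out, rescaling so the temporal mean
    is preserved.  A flat trace is returned unchanged (decay time -> inf).
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if trace.size < 50:
        raise ValueError("need at least 50 points to fit the bleach decay")
    t = time - time[0]
    a0 = trace[: trace.size // 5].mean()
    if a0 <= 0:
        raise ValueError("non-positive initial amplitude; cannot fit bleach decay")
    span = t[-1]

    def model(tt, a, rate):
        return a * np.exp(-rate * tt)

    try:
        popt, _ = curve_fit(
            model, t, trace, p0=(a0, 0.1 / span),
            bounds=((1e-12, 0.0), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError:
        popt = (a0, 0.0)
    a_fit, rate = popt
    if a_fit <= 0:
        raise ValueError("non-positive fitted amplitude")
    corrected = trace / np.exp(-rate * t)
    mean = corrected.mean()
    if mean != 0:
        corrected *= trace.mean() / mean
    return corrected
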