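"""Exact stochastic simulation of the bursting model and derived experiments.

The Gillespie direct method is run on any :class:`~rnapburst.model.ModelSpec`
(affine propensities, integer stoichiometry).  The state is recorded on a
uniform time grid, which is all the downstream trace analysis consumes;
per-polymerase bookkeeping (arrival/escape/completion times) is kept by a
dedicated promoter+cluster core used for simulated ChIP occupancy profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CHANNELS, CellTrace, TraceSet
from .model import ModelSpec, RateParameters, build_model, steady_state_mean

__all__ = [
    "SSATrajectory",
    "ChIPProfile",
    "PerturbationResult",
    "ChIPGeometry",
    "ssa_run",
    "sample_traces",
    "simulate_chip",
    "perturb",
    "dwell_uncertainty",
    "default_chip_geometry",
]

_MAX_COUNT = 1e9  # propensity-overflow guard


def _ssa_grid_py(S_T, W1, w0, x0, t_grid, seed):  # pragma: no cover - numba used
    np.random.seed(seed)
    n_r, n_s = W1.shape
    x = x0.astype(np.float64)
    out = np.empty((t_grid.size, n_s), dtype=np.int64)
    t = t_grid[0]
    gi = 0
    while gi < t_grid.size:
        w = W1 @ x + w0
        for j in range(n_r):
            if w[j] < 0.0:
                w[j] = 0.0
        wtot = w.sum()
        if wtot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / wtot)
        while gi < t_grid.size and t_grid[gi] < t_next:
            for k in range(n_s):
                out[gi, k] = int(x[k])
            gi += 1
        if not np.isfinite(t_next):
            break
        u = np.random.random() * wtot
        acc = 0.0
        r = n_r - 1
        for j in range(n_r):
            acc += w[j]
            if u <= acc:
                r = j
                break
        x += S_T[r]
        if x.max() > _MAX_COUNT:
            return out[: max(gi, 1)] * 0 - 1  # overflow sentinel
        t = t_next
    return out


def _cluster_escapes_py(k_on, k_off, k_rec, k_ab, k_esc, t_end, seed):  # pragma: no cover
    """Promoter + cluster subsystem; returns escape times and x2 time-average."""
    np.random.seed(seed)
    x1 = 0
    x2 = 0.0
    t = 0.0
    x2_int = 0.0
    cap = 1024
    escapes = np.empty(cap)
    n_esc = 0
    while t < t_end:
        w_on = k_on * (1 - x1)
        w_off = k_off * x1
        w_rec = k_rec * x1
        w_ab = k_ab * x2
        w_esc = k_esc * x2
        wtot = w_on + w_off + w_rec + w_ab + w_esc
        if wtot <= 0.0:
            break
        dt = np.random.exponential(1.0 / wtot)
        if t + dt > t_end:
            x2_int += x2 * (t_end - t)
            t = t_end
            break
        x2_int += x2 * dt
        t += dt
        u = np.random.random() * wtot
        if u <= w_on:
            x1 = 1
        elif u <= w_on + w_off:
            x1 = 0
        elif u <= w_on + w_off + w_rec:
            x2 += 1.0
        elif u <= w_on + w_off + w_rec + w_ab:
            x2 -= 1.0
        else:
            x2 -= 1.0
            if n_esc == cap:
                cap *= 2
                bigger = np.empty(cap)
                bigger[:n_esc] = escapes[:n_esc]
                escapes = bigger
            escapes[n_esc] = t
            n_esc += 1
    return escapes[:n_esc].copy(), x2_int / t_end


try:  # numba speeds the inner loops up by ~two orders of magnitude
    from numba import njit

    _ssa_grid = njit(cache=False)(_ssa_grid_py)
    _cluster_escapes = njit(cache=False)(_cluster_escapes_py)
except ImportError:  # pragma: no cover
    _ssa_grid = _ssa_grid_py
    _cluster_escapes = _cluster_escapes_py


@dataclass
class SSATrajectory:
    """State path of one SSA realization sampled on a uniform grid."""

    times: np.ndarray  # minutes
    states: np.ndarray  # (n_t, n_species) integer counts
    state_names: tuple[str, ...]
    seed: int

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


def _default_burn_in(model: ModelSpec) -> float:
    """Ten times the slowest relaxation timescale of the mean dynamics."""
    eig = np.linalg.eigvals(model.relaxation_matrix)
    slowest = np.abs(eig.real).min()
    if slowest <= 0:
        raise ValueError("model has no relaxing mode; cannot choose a burn-in")
    return 10.0 / slowest


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def ssa_run(
    model: ModelSpec,
    t_end: float,
    seed: int,
    dt: float = 1.0,
    burn_in: float | None = None,
    x0: np.ndarray | None = None,
) -> SSATrajectory:
    """Gillespie direct-method realization, sampled every ``dt`` minutes.

    A burn-in of ``10 * max(1/rates)`` (discarded) precedes the recorded
    window so samples are drawn at stationarity; pass ``burn_in=0`` together
    with ``x0`` to continue from a known state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if burn_in is None:
        burn_in = _default_burn_in(model)
    burn_in = np.ceil(burn_in / dt) * dt  # keep the recorded grid on 0, dt, ...
    if x0 is None:
        x0 = np.zeros(model.n_species, dtype=np.int64)
    grid = np.arange(0.0, burn_in + t_end + 0.5 * dt, dt)
    states = _ssa_grid(
        np.ascontiguousarray(model.S.T.astype(np.float64)),
        np.ascontiguousarray(model.W1),
        np.ascontiguousarray(model.w0),
        np.asarray(x0, dtype=np.int64),
        grid,
        seed % (2**31),
    )
    if states.size and states.min() < 0:
        raise RuntimeError("SSA aborted: species count overflow (unstable model?)")
    keep = grid >= burn_in - 1e-9
    return SSATrajectory(
        times=grid[keep] - burn_in,
        states=states[keep],
        state_names=model.state_names,
        seed=seed,
    )


def sample_traces(
    model: ModelSpec,
    n_cells: int,
    duration: float,
    dt: float = 1.0,
    shot_noise: tuple[float, float, float] = (1.98, 1.42, 0.41),
    seed: int = 0,
    normalize: bool = True,
) -> TraceSet:
    """Simulate an ensemble of cells and map states to noisy intensity traces.

    Channels are the linear read-outs of the model (ctd/ser5ph/mrna rows of
    c).  Shot noise is additive iid Gaussian per frame with SD equal to the
    stated multiple of the noiseless channel's ensemble SD; channels are
    then normalized to a 95th percentile of unity (pooled over cells).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if any(m < 0 for m in shot_noise):
        raise ValueError("shot-noise multipliers must be nonnegative")
    clean: list[np.ndarray] = []
    for i in range(n_cells):
        traj = ssa_run(model, duration, seed=_child_seed(seed, i), dt=dt)
        clean.append(model.c @ traj.states.T.astype(float))  # (3, n_t)
    time = traj.times
    stacked = np.stack(clean)  # (n_cells, 3, n_t)
    sds = stacked.std(axis=(0, 2))
    rng = np.random.default_rng(_child_seed(seed, 10**6))
    noisy = np.empty_like(stacked)
    for k, mult in enumerate(shot_noise):
        if mult > 0 and sds[k] == 0:
            raise ValueError(f"channel {CHANNELS[k]} has zero variance; cannot scale noise")
        noisy[:, k, :] = stacked[:, k, :] + rng.normal(
            0.0, mult * sds[k], size=(n_cells, time.size)
        )
    if normalize:
        scale = np.percentile(noisy, 95.0, axis=(0, 2))
        scale[scale == 0] = 1.0
        noisy = noisy / scale[None, :, None]
    cells = [
        CellTrace(
            cell_id=f"cell{i:03d}",
            time=time,
            intensities={ch: noisy[i, k] for k, ch in enumerate(CHANNELS)},
        )
        for i in range(n_cells)
    ]
    return TraceSet(
        cells=cells,
        meta={
            "seed": seed,
            "dt": dt,
            "duration": duration,
            "shot_noise": tuple(shot_noise),
            "variant": model.variant,
            "params": model.params.to_dict(),
        },
    )


@dataclass(frozen=True)
class ChIPGeometry:
    """Gene geometry for positional occupancy mapping."""

    gene_length_kb: float
    elongation_kb_per_min: float
    k_processing: float  # 1/min

    @property
    def elongation_time(self) -> float:
        return self.gene_length_kb / self.elongation_kb_per_min


def default_chip_geometry(
    params: RateParameters,
    elongation_kb_per_min: float = 4.1,
    k_processing: float = 0.27,
) -> ChIPGeometry:
    """Gene length chosen so elongation + processing times sum to 1/k_c."""
    t_el = 1.0 / params.k_c - 1.0 / k_processing
    if t_el <= 0:
        raise ValueError("processing alone exceeds the completion time 1/k_c")
    return ChIPGeometry(
        gene_length_kb=elongation_kb_per_min * t_el,
        elongation_kb_per_min=elongation_kb_per_min,
        k_processing=k_processing,
    )


@dataclass
class ChIPProfile:
    """Mean occupancy per gene position (1 = promoter ... 10 = 3' end)."""

    positions: np.ndarray
    occupancy: dict[str, np.ndarray]  # form -> (n_bins,)
    geometry: ChIPGeometry
    n_cells: int
    weighting: str
    meta: dict = field(default_factory=dict)


def simulate_chip(
    model: ModelSpec,
    geometry: ChIPGeometry | None = None,
    n_cells: int = 20,
    seed: int = 0,
    weighting: str = "none",
    duration: float = 2000.0,
    n_bins: int = 10,
    strict: bool = False,
) -> ChIPProfile:
    """Simulated ChIP occupancy of RNAP2 along the gene.

    The promoter/cluster kinetics are simulated exactly; each escaping
    polymerase then traverses the ``n_bins`` gene positions deterministically
    at the elongation rate and dwells at the 3' bin for an Exp(k_processing)
    processing time.  Cluster polymerases sit at bin 1.  Occupancy is the
    time-averaged molecule count per bin; ``weighting='by_occupancy'``
    weights cells by their mean total RNAP2, emulating the enrichment of
    ChIP toward genes with many polymerases.
    """
    if weighting not in ("none", "by_occupancy"):
        raise ValueError("weighting must be 'none' or 'by_occupancy'")
    p = model.params
    if geometry is None:
        geometry = default_chip_geometry(p)
    total = geometry.elongation_time + 1.0 / geometry.k_processing
    mismatch = abs(total - 1.0 / p.k_c) * p.k_c
    if mismatch > 0.05:
        msg = (
            f"elongation+processing time ({total:.2f} min) differs from 1/k_c "
            f"({1.0 / p.k_c:.2f} min) by {100 * mismatch:.1f}%"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    burn = _default_burn_in(model)
    t_el = geometry.elongation_time
    per_bin = t_el / n_bins
    occ = np.zeros((n_cells, n_bins))
    weights = np.empty(n_cells)
    rng = np.random.default_rng(_child_seed(seed, 7))
    for i in range(n_cells):
        escapes, x2_avg = _cluster_escapes(
            p.omega,
            p.k_off,
            p.beta * p.k_off,
            p.k_ab,
            p.k_esc,
            burn + duration,
            _child_seed(seed, i) % (2**31),
        )
        escapes = escapes[escapes >= burn]
        t0, t1 = burn, burn + duration
        proc = rng.exponential(1.0 / geometry.k_processing, size=escapes.size)
        # time-integrated occupancy per bin, clipped to the recording window
        cell = np.zeros(n_bins)
        for b in range(n_bins):
            start = escapes + b * per_bin
            stop = escapes + (b + 1) * per_bin
            if b == n_bins - 1:
                stop = stop + proc  # 3' bin includes the processing dwell
            cell[b] += np.clip(np.minimum(stop, t1) - np.maximum(start, t0), 0, None).sum()
        cell /= duration
        # cluster RNAP2 occupies the promoter bin; x2_avg includes the short
        # initial transient, a negligible bias for duration >> 1/(k_esc+k_ab)
        cell[0] += x2_avg
        occ[i] = cell
        weights[i] = cell.sum()
    if weighting == "by_occupancy":
        w = weights / weights.sum()
    else:
        w = np.full(n_cells, 1.0 / n_cells)
    mean_occ = (occ * w[:, None]).sum(axis=0)
    forms = {"ctd": mean_occ, "ser5ph": mean_occ.copy()}
    return ChIPProfile(
        positions=np.arange(1, n_bins + 1),
        occupancy=forms,
        geometry=geometry,
        n_cells=n_cells,
        weighting=weighting,
        meta={"seed": seed, "duration": duration, "per_cell": occ},
    )


PERTURB_MODES = (
    "block_burst",
    "block_escape",
    "block_escape_reduce_kc",
    "block_burst_reduce_kc",
)


def _perturbed_params(
    params: RateParameters, mode: str, reduction_fraction: float
) -> RateParameters:
    tiny = 1e-9  # rates must stay positive; 1e-9/min is dynamically zero
    if mode == "block_burst":
        return params.replace(omega=tiny)
    if mode == "block_escape":
        return params.replace(k_esc=tiny)
    if mode == "block_escape_reduce_kc":
        return params.replace(k_esc=tiny, k_c=params.k_c * (1.0 - reduction_fraction))
    if mode == "block_burst_reduce_kc":
        return params.replace(omega=tiny, k_c=params.k_c * (1.0 - reduction_fraction))
    raise ValueError(f"unknown perturbation mode {mode!r}; choose from {PERTURB_MODES}")


@dataclass
class PerturbationResult:
    """Per-cell traces and ensemble mean/SEM around an inhibitor switch."""

    traces: TraceSet
    time: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    mode: str
    t_drug: float

    def to_frame(self):
        import pandas as pd

        rows = []
        for ch in self.mean:
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time,
                        "channel": ch,
                        "mean": self.mean[ch],
                        "sem": self.sem[ch],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def perturb(
    model: ModelSpec,
    mode: str,
    t_drug: float,
    duration: float,
    reduction_fraction: float = 0.0,
    n_cells: int = 20,
    dt: float = 1.0,
    seed: int = 0,
) -> PerturbationResult:
    """Switch rates at ``t_drug`` mid-simulation (inhibitor phenomenology).

    Cells evolve at the unperturbed stationary state until ``t_drug`` and
    under the perturbed rates afterwards; raw (unnormalized, noise-free)
    channel traces are returned along with their ensemble mean and SEM.
    """
    if not 0 <= t_drug <= duration:
        raise ValueError("t_drug must lie within the simulation window")
    post_model = build_model(
        model.variant, _perturbed_params(model.params, mode, reduction_fraction)
    )
    cells = []
    for i in range(n_cells):
        pre = ssa_run(model, max(t_drug, dt), seed=_child_seed(seed, i, 1), dt=dt)
        if t_drug < duration:
            post = ssa_run(
                post_model,
                duration - t_drug,
                seed=_child_seed(seed, i, 2),
                dt=dt,
                burn_in=0.0,
                x0=pre.states[-1],
            )
            times = np.concatenate([pre.times[pre.times < t_drug], post.times + t_drug])
            states = np.concatenate(
                [pre.states[pre.times < t_drug], post.states], axis=0
            )
        else:
            times, states = pre.times, pre.states
        y = model.c @ states.T.astype(float)
        cells.append(
            CellTrace(
                cell_id=f"cell{i:03d}",
                time=times,
                intensities={ch: y[k] for k, ch in enumerate(CHANNELS)},
                meta={"t_drug": t_drug, "mode": mode},
            )
        )
    ts = TraceSet(cells=cells, meta={"mode": mode, "t_drug": t_drug, "seed": seed})
    mat = {ch: ts.channel_matrix(ch) for ch in CHANNELS}
    mean = {ch: m.mean(axis=0) for ch, m in mat.items()}
    sem = {ch: m.std(axis=0, ddof=1) / np.sqrt(n_cells) for ch, m in mat.items()}
    return PerturbationResult(
        traces=ts, time=cells[0].time, mean=mean, sem=sem, mode=mode, t_drug=t_drug
    )


def dwell_uncertainty(
    model: ModelSpec,
    n_datasets: int = 400,
    n_cells: int = 20,
    duration: float = 200.0,
    dt: float = 1.0,
    shot_noise: tuple[float, float, float] = (1.98, 1.42, 0.41),
    max_lag: float = 30.0,
    seed: int = 0,
) -> dict:
    """Spread of the measured dwell time over repeated simulated experiments.

    Each dataset is a full synthetic experiment (``n_cells`` cells over
    ``duration`` minutes); the dwell time is the lag at which the
    shot-noise-corrected normalized autocovariance first falls below 20%.
    Returns per-channel mean, SD and censoring counts across datasets.
    """
    from .correlation import aggregate_normalize, dwell_time

    dwells = {ch: [] for ch in CHANNELS}
    censored = {ch: 0 for ch in CHANNELS}
    for d in range(n_datasets):
        ts = sample_traces(
            model, n_cells, duration, dt=dt, shot_noise=shot_noise,
            seed=_child_seed(seed, 1000 + d),
        )
        cs = aggregate_normalize(ts, max_lag=max_lag)
        for ch in CHANNELS:
            val, cens = dwell_time(cs.auto_lags, cs.curves[(ch, ch)])
            if cens:
                censored[ch] += 1
            else:
                dwells[ch].append(val)
    result = {}
    for ch in CHANNELS:
        arr = np.asarray(dwells[ch])
        flagged = censored[ch] > 0.5 * n_datasets
        result[ch] = {
            "mean": float(arr.mean()) if arr.size else np.nan,
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
            "n_censored": censored[ch],
            "flagged": flagged,
        }
    return result
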