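"""Bursting model of RNAP2 recruitment and nascent transcription.

The gene is described by a linear stochastic reaction network: a telegraph
promoter (x1 in {0,1}) that, while ON, recruits RNAP2 into a promoter-
proximal cluster (x2) at rate beta*k_off.  Because k_off is far larger than
the burst frequency omega (= k_on), each ON period is effectively
instantaneous and delivers a geometric burst of mean size beta.  Cluster
RNAP2 either aborts (k_ab) or escapes the promoter (k_esc) to become
actively transcribing RNAP2 (x3), which completes elongation + 3' processing
at a combined rate k_c.  All propensities are affine in the state, so the
first two moments obey closed ODEs: the steady-state mean solves
S W1 E[x] + S w0 = 0, the stationary covariance solves the algebraic
Lyapunov equation, and lagged covariances follow
Sigma(tau) = expm(S W1 tau) @ Sigma_SS.

Observables are linear read-outs y = c x: the CTD and Ser5ph channels see
RNAP2 at the site and the mRNA (MS2) channel sees transcribing RNAP2.  In
the base model cluster RNAP2 is treated as already Ser5-phosphorylated, so
the CTD and Ser5ph rows of c coincide; the supplementary variants relax
this or add mRNA retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

__all__ = [
    "RateParameters",
    "ModelSpec",
    "MomentSolution",
    "DerivedQuantities",
    "DegenerateModelError",
    "VARIANTS",
    "DEFAULT_PARAMS",
    "build_model",
    "steady_state_mean",
    "steady_state_covariance",
    "lagged_covariance",
    "output_moments",
    "solve_moments",
    "derived_quantities",
    "output_cross_covariance",
    "predict_normalized_curves",
    "predict_sampled_curves",
]

VARIANTS = ("base", "phospho_step", "fractional_phospho", "mrna_retention")

#: extra rate names required per variant
VARIANT_EXTRAS: dict[str, tuple[str, ...]] = {
    "base": (),
    "phospho_step": ("k_phos",),
    "fractional_phospho": ("fraction",),
    "mrna_retention": ("k_c_mRNA", "k_release"),
}


class DegenerateModelError(ValueError):
    """Raised when the relaxation matrix S W1 is singular/unstable."""


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rates of one model variant (units: 1/min; beta: molecules).

    ``omega`` is the burst frequency (k_on in the full telegraph model),
    ``k_off`` the burst termination rate (fixed large so bursts are
    geometric), ``beta`` the mean burst size, ``k_ab``/``k_esc`` the
    abortive-loss and promoter-escape rates from the cluster and ``k_c``
    the combined elongation + processing (completion) rate.
    """

    omega: float
    beta: float
    k_ab: float
    k_esc: float
    k_c: float
    k_off: float = 1000.0
    variant_extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("omega", "beta", "k_ab", "k_esc", "k_c", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name, v in self.variant_extras.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"variant extra {name} must be positive, got {v}")
            if name == "fraction" and not v < 1:
                raise ValueError("fraction must be in (0, 1)")
        if self.k_off < 100.0 * self.omega:
            warnings.warn(
                "k_off < 100*omega: the geometric-burst reduction "
                "(instantaneous bursts) is inaccurate for these rates",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "RateParameters":
        d = self.to_dict()
        extras = d.pop("variant_extras")
        extras.update(kwargs.pop("variant_extras", {}))
        extras.update({k: kwargs.pop(k) for k in list(kwargs) if k in extras})
        d.update(kwargs)
        return RateParameters(**d, variant_extras=extras)

    def to_dict(self) -> dict:
        return {
            "omega": self.omega,
            "beta": self.beta,
            "k_ab": self.k_ab,
            "k_esc": self.k_esc,
            "k_c": self.k_c,
            "k_off": self.k_off,
            "variant_extras": dict(self.variant_extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        d = dict(d)
        extras = dict(d.pop("extras", {}) or {})
        extras.update(d.pop("variant_extras", {}) or {})
        d.pop("variant", None)
        return cls(**d, variant_extras=extras)


#: Default parameter set, back-derived from the published derived-quantity
#: table: omega = 0.43/min, beta = 15.4, k_esc + k_ab = 1/0.692 min^-1 with
#: escape probability f = 0.4615, and k_c = 1/5.032 min^-1.
DEFAULT_PARAMS = RateParameters(
    omega=0.43, beta=15.4, k_ab=0.778, k_esc=0.667, k_c=0.1987, k_off=1000.0
)


@dataclass(frozen=True)
class ModelSpec:
    """Stoichiometry + affine propensities + output map of one variant.

    Propensities are w(x) = W1 x + w0 (n_reactions,), state change for
    reaction j is column j of S, observables are y = c x with rows named by
    ``output_names`` (always ctd, ser5ph, mrna).
    """

    variant: str
    params: RateParameters
    state_names: tuple[str, ...]
    S: np.ndarray  # (n_species, n_reactions), ints
    W1: np.ndarray  # (n_reactions, n_species)
    w0: np.ndarray  # (n_reactions,)
    c: np.ndarray  # (3, n_species)
    output_names: tuple[str, ...] = ("ctd", "ser5ph", "mrna")

    def __post_init__(self) -> None:
        n, m = self.S.shape
        if self.W1.shape != (m, n) or self.w0.shape != (m,):
            raise ValueError("inconsistent S/W1/w0 dimensions")
        if self.c.shape[1] != n:
            raise ValueError("output matrix c has wrong width")

    @property
    def n_species(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def relaxation_matrix(self) -> np.ndarray:
        """A = S W1, the generator of the mean/lag-covariance dynamics."""
        return self.S @ self.W1

    def output_index(self, channel: str) -> int:
        return self.output_names.index(channel)


def build_model(variant: str, params: RateParameters) -> ModelSpec:
    """Assemble S, W1, w0 and the output map c for one model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    missing = [k for k in VARIANT_EXTRAS[variant] if k not in params.variant_extras]
    if missing:
        raise ValueError(f"variant {variant!r} needs variant_extras {missing}")

    w = params
    k_on, k_off = w.omega, w.k_off
    k_r = w.beta * w.k_off  # recruitment propensity coefficient on x1

    if variant == "base":
        # states: x1 promoter, x2 cluster RNAP2 (Ser5ph), x3 transcribing
        state_names = ("promoter", "cluster", "transcribing")
        S = np.array(
            [
                [1, -1, 0, 0, 0, 0],
                [0, 0, 1, -1, -1, 0],
                [0, 0, 0, 0, 1, -1],
            ],
            dtype=np.int64,
        )
        W1 = np.array(
            [
                [-k_on, 0, 0],
                [k_off, 0, 0],
                [k_r, 0, 0],
                [0, w.k_ab, 0],
                [0, w.k_esc, 0],
                [0, 0, w.k_c],
            ]
        )
        w0 = np.array([k_on, 0, 0, 0, 0, 0], dtype=float)
        c = np.array(
            [
                [0, 1, 1],  # ctd: all RNAP2 at the site
                [0, 1, 1],  # ser5ph: cluster assumed phosphorylated
                [0, 0, 1],  # mrna: transcribing RNAP2
            ],
            dtype=float,
        )
    elif variant == "phospho_step":
        # explicit unphosphorylated cluster state; phosphorylation at k_phos
        # precedes escape, unphosphorylated RNAP2 can still abort.
        k_phos = params.variant_extras["k_phos"]
        state_names = ("promoter", "cluster_unphos", "cluster_ser5ph", "transcribing")
        S = np.array(
            [
                # on  off  rec  phos ab_u ab_p esc  comp
                [1, -1, 0, 0, 0, 0, 0, 0],
                [0, 0, 1, -1, -1, 0, 0, 0],
                [0, 0, 0, 1, 0, -1, -1, 0],
                [0, 0, 0, 0, 0, 0, 1, -1],
            ],
            dtype=np.int64,
        )
        W1 = np.array(
            [
                [-k_on, 0, 0, 0],
                [k_off, 0, 0, 0],
                [k_r, 0, 0, 0],
                [0, k_phos, 0, 0],
                [0, w.k_ab, 0, 0],
                [0, 0, w.k_ab, 0],
                [0, 0, w.k_esc, 0],
                [0, 0, 0, w.k_c],
            ]
        )
        w0 = np.zeros(8)
        w0[0] = k_on
        c = np.array(
            [
                [0, 1, 1, 1],
                [0, 0, 1, 1],
                [0, 0, 0, 1],
            ],
            dtype=float,
        )
    elif variant == "fractional_phospho":
        # a fixed fraction of arrivals is already Ser5-phosphorylated; the
        # rest never acquires the mark in the cluster but is phosphorylated
        # upon escape/initiation.
        frac = params.variant_extras["fraction"]
        state_names = ("promoter", "cluster_unphos", "cluster_ser5ph", "transcribing")
        S = np.array(
            [
                # on off rec_u rec_p ab_u esc_u ab_p esc_p comp
                [1, -1, 0, 0, 0, 0, 0, 0, 0],
                [0, 0, 1, 0, -1, -1, 0, 0, 0],
                [0, 0, 0, 1, 0, 0, -1, -1, 0],
                [0, 0, 0, 0, 0, 1, 0, 1, -1],
            ],
            dtype=np.int64,
        )
        W1 = np.array(
            [
                [-k_on, 0, 0, 0],
                [k_off, 0, 0, 0],
                [(1 - frac) * k_r, 0, 0, 0],
                [frac * k_r, 0, 0, 0],
                [0, w.k_ab, 0, 0],
                [0, w.k_esc, 0, 0],
                [0, 0, w.k_ab, 0],
                [0, 0, w.k_esc, 0],
                [0, 0, 0, w.k_c],
            ]
        )
        w0 = np.zeros(9)
        w0[0] = k_on
        c = np.array(
            [
                [0, 1, 1, 1],
                [0, 0, 1, 1],
                [0, 0, 0, 1],
            ],
            dtype=float,
        )
    else:  # mrna_retention
        # completed transcripts are retained at the site and released at
        # k_release; completion uses k_c_mRNA in place of k_c.
        k_cm = params.variant_extras["k_c_mRNA"]
        k_rel = params.variant_extras["k_release"]
        state_names = ("promoter", "cluster", "transcribing", "retained_mrna")
        S = np.array(
            [
                # on off rec  ab  esc comp rel
                [1, -1, 0, 0, 0, 0, 0],
                [0, 0, 1, -1, -1, 0, 0],
                [0, 0, 0, 0, 1, -1, 0],
                [0, 0, 0, 0, 0, 1, -1],
            ],
            dtype=np.int64,
        )
        W1 = np.array(
            [
                [-k_on, 0, 0, 0],
                [k_off, 0, 0, 0],
                [k_r, 0, 0, 0],
                [0, w.k_ab, 0, 0],
                [0, w.k_esc, 0, 0],
                [0, 0, k_cm, 0],
                [0, 0, 0, k_rel],
            ]
        )
        w0 = np.zeros(7)
        w0[0] = k_on
        c = np.array(
            [
                [0, 1, 1, 0],  # RNAP2 leaves at completion
                [0, 1, 1, 0],
                [0, 0, 1, 1],  # MS2 signal persists while mRNA is retained
            ],
            dtype=float,
        )

    return ModelSpec(
        variant=variant,
        params=params,
        state_names=state_names,
        S=S,
        W1=W1,
        w0=w0,
        c=c,
    )


def _check_stable(A: np.ndarray) -> None:
    eig = np.linalg.eigvals(A)
    if np.any(eig.real > -1e-12):
        raise DegenerateModelError(
            f"unstable/degenerate model: relaxation eigenvalues {eig}"
        )


def steady_state_mean(model: ModelSpec) -> np.ndarray:
    """Solve S W1 E[x] + S w0 = 0 for the stationary mean."""
    A = model.relaxation_matrix
    _check_stable(A)
    return np.linalg.solve(A, -model.S @ model.w0)


def steady_state_covariance(model: ModelSpec) -> np.ndarray:
    """Stationary covariance from the algebraic Lyapunov equation.

    Solves A Sigma + Sigma A^T + S diag(W1 E[x] + w0) S^T = 0 with A = S W1.
    """
    A = model.relaxation_matrix
    mean = steady_state_mean(model)
    D = model.S @ np.diag(model.W1 @ mean + model.w0) @ model.S.T
    sigma = solve_continuous_lyapunov(A, -D)
    sigma = 0.5 * (sigma + sigma.T)
    evals = np.linalg.eigvalsh(sigma)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise DegenerateModelError(f"indefinite covariance solution (eigs {evals})")
    return sigma


def lagged_covariance(
    model: ModelSpec, lags: np.ndarray, sigma_ss: np.ndarray | None = None
) -> np.ndarray:
    """Sigma(tau) = expm(A tau) @ Sigma_SS on a sorted nonnegative lag grid.

    Element (i, j) of Sigma(tau) is Cov(x_i(t + tau), x_j(t)).  Negative
    lags follow from Sigma_ij(-tau) = Sigma_ji(tau).
    """
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or np.any(lags < 0) or np.any(np.diff(lags) < 0):
        raise ValueError("lags must be a sorted, nonnegative 1-d grid")
    A = model.relaxation_matrix
    if sigma_ss is None:
        sigma_ss = steady_state_covariance(model)
    out = np.empty((lags.size, *sigma_ss.shape))
    # diagonalize once; fall back to expm per lag if A is defective
    evals, V = np.linalg.eig(A)
    try:
        Vinv_sigma = np.linalg.solve(V, sigma_ss.astype(complex))
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError
        for i, tau in enumerate(lags):
            out[i] = np.real(V @ (np.exp(evals * tau)[:, None] * Vinv_sigma))
    except np.linalg.LinAlgError:
        for i, tau in enumerate(lags):
            out[i] = expm(A * tau) @ sigma_ss
    return out


@dataclass(frozen=True)
class MomentSolution:
    """Stationary first/second moments of states and observables."""

    mean_x: np.ndarray
    cov_x: np.ndarray
    mean_y: np.ndarray
    cov_y: np.ndarray
    lags: np.ndarray | None = None
    lag_cov_x: np.ndarray | None = None
    lag_cov_y: np.ndarray | None = None


def output_moments(
    model: ModelSpec, mean_x: np.ndarray, cov_like: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map state moments to observables: E[y] = c E[x], Sigma_y = c Sigma c^T."""
    c = model.c
    if cov_like.ndim == 2:
        return c @ mean_x, c @ cov_like @ c.T
    return c @ mean_x, np.einsum("ij,tjk,lk->til", c, cov_like, c)


def solve_moments(model: ModelSpec, lags: np.ndarray | None = None) -> MomentSolution:
    mean_x = steady_state_mean(model)
    cov_x = steady_state_covariance(model)
    mean_y, cov_y = output_moments(model, mean_x, cov_x)
    lag_cov_x = lag_cov_y = None
    if lags is not None:
        lags = np.asarray(lags, dtype=float)
        lag_cov_x = lagged_covariance(model, lags, sigma_ss=cov_x)
        _, lag_cov_y = output_moments(model, mean_x, lag_cov_x)
    return MomentSolution(
        mean_x=mean_x,
        cov_x=cov_x,
        mean_y=mean_y,
        cov_y=cov_y,
        lags=lags,
        lag_cov_x=lag_cov_x,
        lag_cov_y=lag_cov_y,
    )


def output_cross_covariance(
    model: ModelSpec,
    channel_a: str,
    channel_b: str,
    lags: np.ndarray,
    sigma_ss: np.ndarray | None = None,
) -> np.ndarray:
    """G_ab(tau) = Cov(y_a(t), y_b(t + tau)) on an arbitrary sorted lag grid.

    Positive values of the peak lag mean channel b trails channel a.
    """
    lags = np.asarray(lags, dtype=float)
    ia, ib = model.output_index(channel_a), model.output_index(channel_b)
    pos = np.unique(np.abs(lags))
    lag_y = output_moments(
        model, steady_state_mean(model), lagged_covariance(model, pos, sigma_ss)
    )[1]
    lookup = {tau: lag_y[i] for i, tau in enumerate(pos)}
    out = np.empty(lags.size)
    for i, tau in enumerate(lags):
        m = lookup[abs(tau)]
        # Sigma(tau)[i, j] = Cov(y_i(t+tau), y_j(t))
        out[i] = m[ib, ia] if tau >= 0 else m[ia, ib]
    return out


def predict_normalized_curves(
    model: ModelSpec,
    auto_lags: np.ndarray,
    cross_lags: np.ndarray,
) -> dict[tuple[str, str], np.ndarray]:
    """Model counterparts of the measured normalized covariance curves.

    Each pair's curve is divided by its own zero-lag covariance, matching
    the normalization G(tau)/Gbar(0) applied to the data.  The model has no
    shot noise, so its tau=0 auto values are the shot-noise-free variances.
    """
    from .containers import ALL_PAIRS

    sigma_ss = steady_state_covariance(model)
    curves = {}
    for a, b in ALL_PAIRS:
        lags = np.asarray(auto_lags if a == b else cross_lags, dtype=float)
        g = output_cross_covariance(model, a, b, lags, sigma_ss=sigma_ss)
        g0 = output_cross_covariance(model, a, b, np.array([0.0]), sigma_ss=sigma_ss)[0]
        curves[(a, b)] = g / g0
    return curves


_weight_cache: dict[tuple[int, int], np.ndarray] = {}


def _finite_sample_weights(n: int, max_idx: int) -> np.ndarray:
    """Linear map from true lag-covariances to the expected sample estimate.

    For a length-n trace with per-trace mean subtraction and the biased
    (divide-by-n) estimator, E[Ghat(tau)] is linear in the true covariance
    sequence g(d), d = -(n-1)..(n-1):

        E[Ghat(tau)] = (1/n) [ (n-tau) g(tau)
                               - (1/n) (c1 + c2) . g
                               + (n-tau)/n^2 * sum_d (n-|d|) g(d) ]

    where c1/c2 count the (t, s) index pairs coupling g(d) through the
    subtracted means.  Rows are tau = 0..max_idx, columns d.
    """
    key = (n, max_idx)
    if key in _weight_cache:
        return _weight_cache[key]
    d = np.arange(-(n - 1), n)
    W = np.zeros((max_idx + 1, d.size))
    tri = (n - np.abs(d)) / n**2
    for tau in range(max_idx + 1):
        c1 = np.clip(np.minimum(n - 1 - tau, n - 1 - d) - np.maximum(0, -d) + 1, 0, None)
        c2 = np.clip(
            np.minimum(n - 1 - tau, n - 1 + d - tau) - np.maximum(0, d - tau) + 1,
            0,
            None,
        )
        row = -(c1 + c2) / n + (n - tau) * tri
        row[d == tau] += n - tau
        W[tau] = row / n
    _weight_cache[key] = W
    return W


def predict_sampled_curves(
    model: ModelSpec,
    auto_lags: np.ndarray,
    cross_lags: np.ndarray,
    n_points: int,
    shot_var_ratio: dict[str, float] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Finite-length-aware model counterparts of the measured curves.

    Unlike :func:`predict_normalized_curves` (asymptotic covariances), this
    propagates the estimator itself: per-trace mean subtraction and the
    divide-by-N normalization shrink and shift the sampled covariance at
    finite N, and white shot noise leaks a small O(var/N) negative offset
    into nonzero lags through the subtracted mean.  Expectations of the
    sampled statistic are computed exactly from the analytic Sigma_y(tau)
    (the operator is linear in the lag domain), the auto zero-lag is
    replaced by the same 3-point linear extrapolation used for shot-noise
    correction of the data, and each pair is normalized by its zero-lag
    expectation.

    ``shot_var_ratio`` maps channel -> (shot-noise variance)/(signal
    variance), as measured by the correlation module.
    """
    from .containers import ALL_PAIRS

    auto_lags = np.asarray(auto_lags, dtype=float)
    cross_lags = np.asarray(cross_lags, dtype=float)
    dt = auto_lags[1] - auto_lags[0]
    n = int(n_points)
    max_idx = int(round(max(auto_lags.max(), np.abs(cross_lags).max()) / dt))
    mean_x = steady_state_mean(model)
    sigma_ss = steady_state_covariance(model)
    taus = np.arange(n) * dt
    _, lag_y = output_moments(model, mean_x, lagged_covariance(model, taus, sigma_ss))
    W = _finite_sample_weights(n, max_idx)
    d_axis = np.arange(-(n - 1), n)
    idx = model.output_index
    curves: dict[tuple[str, str], np.ndarray] = {}
    for a, b in ALL_PAIRS:
        ia, ib = idx(a), idx(b)
        # g_ab(d) = Cov(a_t, b_{t+d}); Sigma(tau)[i, j] = Cov(y_i(t+tau), y_j(t))
        g = np.where(
            d_axis >= 0,
            lag_y[np.abs(d_axis), ib, ia],
            lag_y[np.abs(d_axis), ia, ib],
        )
        if a == b and shot_var_ratio is not None and a in shot_var_ratio:
            g = g.copy()
            g[d_axis == 0] += shot_var_ratio[a] * lag_y[0, ia, ia]
        e_pos = W @ g  # E[Ghat_ab(tau)], tau = 0..max_idx
        if a == b:
            e = e_pos
            # replace tau=0 by the 3-shortest-lag linear extrapolation, the
            # same functional applied to the data
            slope, intercept = np.polyfit([1.0, 2.0, 3.0], e[1:4], 1)
            e0 = intercept
            curve = e / e0
            curve[0] = 1.0
            curves[(a, b)] = curve[np.round(auto_lags / dt).astype(int)]
        else:
            g_rev = np.where(
                d_axis >= 0,
                lag_y[np.abs(d_axis), ia, ib],
                lag_y[np.abs(d_axis), ib, ia],
            )
            e_neg = W @ g_rev  # E[Ghat_ab(-tau)] = E[Ghat_ba(tau)]
            full = np.concatenate([e_neg[1 : max_idx + 1][::-1], e_pos])
            full_lags = np.arange(-max_idx, max_idx + 1) * dt
            e0 = e_pos[0]
            sel = np.searchsorted(full_lags, cross_lags)
            curves[(a, b)] = full[sel] / e0
    return curves


@dataclass(frozen=True)
class DerivedQuantities:
    """Summary quantities of the bursting model (published table layout)."""

    r: float  # average RNAP2 arrival rate, omega*beta [1/min]
    tau_cluster: float  # mean time in the cluster [min]
    mu_cluster: float  # mean cluster RNAP2
    f: float  # escape probability
    beta_mrna: float  # mean mRNA burst size
    r_mrna: float  # mRNA production rate [1/min]
    mu_mrna: float  # mean transcribing RNAP2 (nascent mRNA)
    mu_total: float  # mean total RNAP2 at the site
    tau_mrna: float  # mean completion time [min]

    def as_dict(self) -> dict[str, float]:
        return {
            "r": self.r,
            "tau_cluster": self.tau_cluster,
            "mu_cluster": self.mu_cluster,
            "f": self.f,
            "beta_mrna": self.beta_mrna,
            "r_mrna": self.r_mrna,
            "mu_mrna": self.mu_mrna,
            "mu_total": self.mu_total,
            "tau_mrna": self.tau_mrna,
        }


def derived_quantities(params: RateParameters) -> DerivedQuantities:
    """Evaluate each summary quantity from its defining formula."""
    r = params.omega * params.beta
    tau_cluster = 1.0 / (params.k_esc + params.k_ab)
    mu_cluster = r * tau_cluster
    f = params.k_esc / (params.k_esc + params.k_ab)
    return DerivedQuantities(
        r=r,
        tau_cluster=tau_cluster,
        mu_cluster=mu_cluster,
        f=f,
        beta_mrna=f * params.beta,
        r_mrna=mu_cluster * params.k_esc,
        mu_mrna=mu_cluster * params.k_esc / params.k_c,
        mu_total=mu_cluster + mu_cluster * params.k_esc / params.k_c,
        tau_mrna=1.0 / params.k_c,
    )
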