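"""Composite maximum-likelihood inference and model selection.

The model is fit simultaneously to (i) the six replica-averaged normalized
auto/cross-covariance curves, with Gaussian errors given by the measured
SEM at each lag, and (ii) the mean and variance of the nascent-mRNA count
sample.  The total log-likelihood is the sum of the three parts (additive
constants dropped); the fit is iterated Nelder-Mead in log-parameter space
with k_off fixed at 1000/min, and model variants are ranked by
BIC = k ln(n) - 2 ln L with n = 8 effective independent data sets.
Parameter uncertainty is sampled with random-walk Metropolis over the same
log-parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import ALL_PAIRS, CorrelationSet, MRNACountSample
from .model import (
    predict_sampled_curves,
    VARIANT_EXTRAS,
    VARIANTS,
    ModelSpec,
    RateParameters,
    build_model,
    predict_normalized_curves,
    solve_moments,
)

__all__ = [
    "LikelihoodData",
    "FitResult",
    "loglik_correlations",
    "loglik_mrna",
    "loglik_total",
    "fit_mle",
    "sample_uncertainty",
    "compare_models",
    "N_INDEPENDENT",
]

#: effective number of independent experiments entering the BIC: six
#: correlation curves plus the mRNA mean and variance.
N_INDEPENDENT = 8

N_AUTO_LAGS = 15  # first 15 lag times per auto-covariance curve
CROSS_LAG_MAX = 10.0  # cross curves fitted on lags -10..10 min

#: flat-in-log optimization bounds (1/min, molecules); positivity plus
#: plausibility for a gene transcribed on the minutes timescale.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "omega": (1e-3, 10.0),
    "beta": (1.0, 200.0),
    "k_ab": (1e-3, 10.0),
    "k_esc": (1e-3, 10.0),
    "k_c": (1e-2, 2.0),
    "k_phos": (1e-2, 100.0),
    "fraction": (1e-3, 1.0 - 1e-3),
    "k_c_mRNA": (1e-2, 2.0),
    "k_release": (1e-2, 100.0),
}

_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    v: ("omega", "beta", "k_ab", "k_esc") + (("k_c",) if v != "mrna_retention" else ())
    + VARIANT_EXTRAS[v]
    for v in VARIANTS
}

_DEFAULT_INIT = {
    "omega": 1.0,
    "beta": 10.0,
    "k_ab": 1.0,
    "k_esc": 1.0,
    "k_c": 0.3,
    "k_phos": 2.0,
    "fraction": 0.5,
    "k_c_mRNA": 0.3,
    "k_release": 2.0,
}


@dataclass
class LikelihoodData:
    """Everything the composite likelihood consumes."""

    corr: CorrelationSet
    mrna_mean: float
    mrna_sem: float
    mrna_var: float
    mrna_var_sem: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.mrna_sem <= 0 or self.mrna_var_sem <= 0:
            raise ValueError("SEMs must be positive")
        max_auto = self.corr.auto_lags.max()
        if self.corr.auto_lags.size < N_AUTO_LAGS:
            raise ValueError(f"need at least {N_AUTO_LAGS} auto lags, have fewer")
        if self.corr.cross_lags.min() > -CROSS_LAG_MAX or max_auto < CROSS_LAG_MAX:
            raise ValueError("cross lags must cover -10..10 min")

    @classmethod
    def from_sources(
        cls, corr: CorrelationSet, counts: MRNACountSample
    ) -> "LikelihoodData":
        return cls(
            corr=corr,
            mrna_mean=counts.mean,
            mrna_sem=counts.sem,
            mrna_var=counts.var,
            mrna_var_sem=counts.var_sem,
            n_cells=corr.n_cells,
        )

    def fingerprint(self) -> float:
        """Cheap content hash used to refuse cross-data BIC comparisons."""
        acc = self.mrna_mean + self.mrna_var
        for pair in ALL_PAIRS:
            acc += float(np.sum(self.corr.curves[pair]))
        return round(float(acc), 9)


def _fit_windows(data: LikelihoodData) -> dict[tuple[str, str], np.ndarray]:
    """Boolean masks selecting the fitted lag windows per pair."""
    masks = {}
    for a, b in ALL_PAIRS:
        lags = data.corr.lags_for((a, b))
        if a == b:
            masks[(a, b)] = np.arange(lags.size) < N_AUTO_LAGS
        else:
            masks[(a, b)] = np.abs(lags) <= CROSS_LAG_MAX + 1e-9
    return masks


def loglik_correlations(
    predicted: dict[tuple[str, str], np.ndarray], data: LikelihoodData
) -> float:
    """-1/2 sum (Gbar_D - Gbar_M)^2 / SEM^2 over the fitted lag windows.

    The model carries no shot noise, so the data's tau=0 auto points are the
    shot-noise-corrected values (handled upstream in aggregate_normalize).
    """
    masks = _fit_windows(data)
    total = 0.0
    for pair, mask in masks.items():
        d = data.corr.curves[pair]
        m = predicted[pair]
        if m.shape != d.shape:
            raise ValueError(f"model/data lag-grid mismatch for pair {pair}")
        s = data.corr.sem[pair]
        resid = (d[mask] - m[mask]) / s[mask]
        total += -0.5 * float(np.sum(resid**2))
    return total


def loglik_mrna(model_mean: float, model_var: float, data: LikelihoodData) -> float:
    """Gaussian penalties on the nascent-mRNA sample mean and variance."""
    if data.mrna_sem <= 0 or data.mrna_var_sem <= 0:
        raise ValueError("nonpositive SEM")
    z_mu = (data.mrna_mean - model_mean) / data.mrna_sem
    z_var = (data.mrna_var - model_var) / data.mrna_var_sem
    return -0.5 * float(z_mu**2) - 0.5 * float(z_var**2)


def _model_predictions(model: ModelSpec, data: LikelihoodData):
    n_points = data.corr.meta.get("n_points")
    if n_points:
        # estimator-aware likelihood: compare the data statistic with the
        # model's expectation of that statistic at the actual trace length
        shot_ratio = {
            ch: data.corr.shot_noise_var[ch] / data.corr.gbar0[(ch, ch)]
            for ch in data.corr.shot_noise_var
        }
        curves = predict_sampled_curves(
            model,
            data.corr.auto_lags,
            data.corr.cross_lags,
            n_points,
            shot_var_ratio=shot_ratio,
        )
    else:
        curves = predict_normalized_curves(
            model, data.corr.auto_lags, data.corr.cross_lags
        )
    mom = solve_moments(model)
    i = model.output_index("mrna")
    return curves, float(mom.mean_y[i]), float(mom.cov_y[i, i])


def loglik_total(model: ModelSpec, data: LikelihoodData) -> tuple[float, float, float]:
    """(logL_G, logL_mu, logL_var); the total is their exact sum."""
    curves, mu, var = _model_predictions(model, data)
    lg = loglik_correlations(curves, data)
    z_mu = (data.mrna_mean - mu) / data.mrna_sem
    z_var = (data.mrna_var - var) / data.mrna_var_sem
    return lg, -0.5 * float(z_mu**2), -0.5 * float(z_var**2)


@dataclass
class FitResult:
    """MLE parameters with likelihood decomposition and BIC."""

    variant: str
    params: RateParameters
    loglik_corr: float
    loglik_mean: float
    loglik_var: float
    k: int
    n: int
    converged: bool
    n_rounds: int
    data_fingerprint: float
    samples: pd.DataFrame | None = None
    ci: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_corr + self.loglik_mean + self.loglik_var

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik


def _theta_to_params(variant: str, theta: np.ndarray, k_off: float) -> RateParameters:
    names = _FREE_PARAMS[variant]
    vals = dict(zip(names, np.exp(theta)))
    extras = {k: vals.pop(k) for k in VARIANT_EXTRAS[variant]}
    if variant == "mrna_retention":
        # k_c is replaced by k_c_mRNA; keep a placeholder k_c for validity
        vals["k_c"] = extras["k_c_mRNA"]
    return RateParameters(**vals, k_off=k_off, variant_extras=extras)


def _objective(variant: str, data: LikelihoodData, k_off: float, bounds):
    names = _FREE_PARAMS[variant]
    lo = np.log([bounds[n][0] for n in names])
    hi = np.log([bounds[n][1] for n in names])

    def negloglik(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return 1e12
        try:
            params = _theta_to_params(variant, theta, k_off)
            model = build_model(variant, params)
            return -sum(loglik_total(model, data))
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    return negloglik, names


def fit_mle(
    variant: str,
    data: LikelihoodData,
    init: RateParameters | dict | None = None,
    seed: int = 0,
    k_off: float = 1000.0,
    bounds: dict | None = None,
    tol: float = 1e-4,
    max_rounds: int = 25,
) -> FitResult:
    """Iterated Nelder-Mead maximum-likelihood fit of one model variant.

    The simplex search restarts from the incumbent optimum until the
    log-likelihood improves by less than ``tol`` between rounds
    (fminsearch-style iteration).  k_off is fixed, so the base model has
    k = 5 free parameters.  Deterministic for a given ``init``.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    negloglik, names = _objective(variant, data, k_off, bounds)
    if init is None:
        init_vals = dict(_DEFAULT_INIT)
    elif isinstance(init, RateParameters):
        init_vals = {**init.to_dict(), **init.variant_extras}
    else:
        init_vals = {**_DEFAULT_INIT, **init}
    theta = np.log([init_vals[n] for n in names])
    theta = np.clip(
        theta,
        np.log([bounds[n][0] for n in names]) + 1e-9,
        np.log([bounds[n][1] for n in names]) - 1e-9,
    )
    best = negloglik(theta)
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        res = minimize(
            negloglik,
            theta,
            method="Nelder-Mead",
            options={"maxiter": 400 * len(names), "xatol": 1e-6, "fatol": 1e-8},
        )
        improvement = best - res.fun
        if res.fun < best:
            best, theta = res.fun, res.x
        if improvement < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit of variant {variant!r} did not converge in {max_rounds} rounds",
            stacklevel=2,
        )
    params = _theta_to_params(variant, theta, k_off)
    model = build_model(variant, params)
    lg, lmu, lvar = loglik_total(model, data)
    return FitResult(
        variant=variant,
        params=params,
        loglik_corr=lg,
        loglik_mean=lmu,
        loglik_var=lvar,
        k=len(names),
        n=N_INDEPENDENT,
        converged=converged,
        n_rounds=rounds,
        data_fingerprint=data.fingerprint(),
        meta={"seed": seed, "init": init_vals, "neg_loglik": best},
    )


def sample_uncertainty(
    fit: FitResult,
    data: LikelihoodData,
    n_samples: int = 10_000,
    burn: int = 2_000,
    seed: int = 0,
    step: float = 0.08,
) -> FitResult:
    """Random-walk Metropolis over log-parameters targeting exp(logL_Total).

    The proposal SD is adapted toward ~25% acceptance during burn-in and
    then frozen.  Attaches the samples and the 2.5/97.5-percentile CI table
    to the fit and returns it.
    """
    rng = np.random.default_rng(seed)
    negloglik, names = _objective(fit.variant, data, fit.params.k_off, DEFAULT_BOUNDS)
    free = {**fit.params.to_dict(), **fit.params.variant_extras}
    theta = np.log([free[n] for n in names])
    logp = -negloglik(theta)
    samples = np.empty((n_samples, len(names)))
    accepted = 0
    s = step
    for i in range(burn + n_samples):
        prop = theta + rng.normal(0.0, s, size=theta.size)
        logp_prop = -negloglik(prop)
        if np.log(rng.random()) < logp_prop - logp:
            theta, logp = prop, logp_prop
            accepted += 1
        if i < burn and (i + 1) % 200 == 0:
            rate = accepted / (i + 1)
            s *= np.exp(0.5 * (rate - 0.25))  # nudge toward 25% acceptance
        if i >= burn:
            samples[i - burn] = theta
    acc_rate = accepted / (burn + n_samples)
    if not 0.05 <= acc_rate <= 0.8:
        warnings.warn(
            f"MCMC acceptance rate {acc_rate:.2f} outside [0.05, 0.8]",
            stacklevel=2,
        )
    df = pd.DataFrame(np.exp(samples), columns=list(names))
    ci = pd.DataFrame(
        {
            "mle": [free[n] for n in names],
            "lo95": df.quantile(0.025),
            "hi95": df.quantile(0.975),
        },
        index=list(names),
    )
    fit.samples = df
    fit.ci = ci
    fit.meta["mcmc_acceptance"] = acc_rate
    return fit


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted variants by BIC (lowest first).

    All fits must refer to the same data; k counts only free parameters
    (fixed k_off and the directly measured shot-noise magnitudes excluded).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted variants to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) != 1:
        raise ValueError("variants were fitted to different data")
    rows = [
        {
            "variant": f.variant,
            "k": f.k,
            "loglik": f.loglik,
            "bic": f.bic,
            "converged": f.converged,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    return table
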