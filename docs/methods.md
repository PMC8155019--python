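# Methods

## Model

Transcription at the reporter gene is described by a linear stochastic
reaction network with species `x1` (promoter state, 0/1), `x2` (RNAP2 in
the promoter-proximal cluster) and `x3` (actively transcribing RNAP2).
Six reactions — promoter activation (ω), deactivation (`k_off`),
recruitment (`β·k_off`, conditional on the active promoter), abortive loss
(`k_ab`), promoter escape (`k_esc`) and completion (`k_c`) — have affine
propensities `w(x) = W1 x + w0` with stoichiometry matrix `S`. Because all
propensities are affine, the first two moments obey closed equations: the
stationary mean solves `S W1 E[x] + S w0 = 0`, the stationary covariance
solves the algebraic Lyapunov equation with diffusion
`S diag(W1 E[x] + w0) Sᵀ` (solved with `scipy.linalg.solve_continuous_lyapunov`),
and the lagged covariance is `Σ(τ) = expm(S W1 τ) Σ_SS`, evaluated by
eigendecomposition of `S W1` (vectorized over lags; dense `expm` fallback
for defective matrices; agreement with the dense oracle is ~1e-14).

`k_off` is fixed at 1000/min: with `k_off ≫ ω` each ON period is
instantaneous on the sampling timescale and delivers a geometric burst of
mean β, and predictions are insensitive to the exact value (Σ_y(τ) entries
change by ~0.1% between `k_off` = 10³ and 10⁴/min).

Observables are linear read-outs `y = c x`. In the base model the CTD and
Ser5ph channels share the row `x2 + x3` — cluster RNAP2 is treated as
already Ser5-phosphorylated, consistent with phosphorylation within seconds
of arrival — and the mRNA (MS2) channel reads `x3`.

### Variants

Three nested variants, each with one extra parameter, are provided for
model selection. Their exact wiring is this package's choice:

- **phospho_step**: an explicit unphosphorylated cluster state; arrivals
  are unphosphorylated, phosphorylate at `k_phos`, and only phosphorylated
  RNAP2 escapes; both pools abort at `k_ab`. (One extra state, two extra
  reactions.)
- **fractional_phospho**: a fixed fraction of arrivals is pre-phosphorylated;
  the unphosphorylated pool has identical kinetics but is counted in the
  Ser5ph channel only after escape (phosphorylation at initiation).
- **mrna_retention**: completed transcripts remain at the site (still
  MS2-bright, no longer RNAP2-bound) and release at `k_release`; completion
  uses `k_c_mRNA` in place of `k_c`.

### Default parameters

The defaults (ω = 0.43/min, β = 15.4, k_ab = 0.778/min, k_esc = 0.667/min,
k_c = 0.1987/min) are back-derived from the published derived-quantity
table, whose formulas invert uniquely: `k_esc + k_ab = 1/τ_cluster`,
`k_esc = f/τ_cluster`, `k_c = 1/τ_mrna`. Printed-rounding inconsistencies
of that table are at the ~1% level (e.g. `r·τ_cluster` = 4.58 vs the
printed cluster mean 4.624), which propagates to the defaults: the model's
stationary transcribing mean is 15.38 vs the printed 15.512.

## Correlation analysis

For each cell and signal pair the sample covariance
`G(τ) = ⟨δa(t) δb(t+τ)⟩` is computed with the per-trace temporal mean
removed and the **biased** normalization (divide by the full trace length
N at every lag), chosen for its lower variance at long lags. Shot noise is
white, so it contributes to the auto-covariance only at τ = 0; the
shot-free `G(0)` is estimated per cell as the intercept of a least-squares
line through the three shortest nonzero lags, and the difference from the
measured `G(0)` is the shot-noise variance (clipped at zero with a
warning). Curves are normalized by the zero-lag covariance of that pair
averaged over cells (shot-corrected for autos), and the SEM is the
across-cell SD divided by √N_cells. The 3-point-extrapolation estimator
cannot distinguish white noise from signal components faster than the
1-min sampling: for the RNAP2 channels, whose cluster component
decorrelates in τ_cluster ≈ 0.7 min, part of the cluster variance is
attributed to shot noise, so the recovered multiplier exceeds the injected
one (~2.4 vs 1.98 for CTD). This is a property of the method, reproduced
exactly by the finite-length expectation below; the slow mRNA channel
recovers its multiplier directly.

**Dwell time** is the first lag at which the normalized autocovariance
falls below 20% of its zero-lag value, linearly interpolated between
bracketing lags, with a censored flag when the curve never crosses within
the computed window. **Cross delays** are peak lags located by quadratic
interpolation around the discrete maximum. For fast single-plane imaging,
photobleaching is corrected by dividing out a single-exponential fit
(mean-preserving); per-trace rate-fit noise leaves a small convexity
residual on strongly fluctuating traces.

## Likelihood and fitting

The composite log-likelihood sums three Gaussian parts: (i) the six
normalized correlation curves over the first 15 auto lags and the 21 cross
lags from −10 to +10 min, each residual weighted by its measured SEM;
(ii) the nascent-mRNA sample mean (SE = SD/√N); (iii) the sample variance,
with SE = σ²·√(2/(N−1)) (Gaussian approximation). Additive constants are
dropped.

A deliberate design choice: the model side of part (i) is **the exact
expectation of the sampled statistic**, not the asymptotic covariance.
For a length-N trace with per-trace mean subtraction and divide-by-N
normalization, `E[Ĝ(τ)]` is a fixed linear functional of the true lag
covariance sequence (including an O(var/N) leak of white shot noise into
nonzero lags); the same 3-point extrapolation and zero-lag normalization
applied to the data are applied to this expectation. At N = 201 the
finite-length distortion reaches several SEM; fitting the asymptotic
curves instead biases `k_c` by ~+17% and β by ~−30%. The expectation was
validated against a 400-cell simulated ensemble (|z| < 2 at all checked
lags).

Optimization is iterated Nelder–Mead in log-parameter space (logit for the
bounded fraction), restarting from the incumbent until the log-likelihood
improves by < 1e-4, with flat bounds ω ∈ [1e-3, 10], β ∈ [1, 200],
k_ab/k_esc ∈ [1e-3, 10], k_c ∈ [1e-2, 2] (1/min). Fits are deterministic
given the data and initial point. Parameter uncertainty is sampled by
random-walk Metropolis over the same log-parameters (default 10,000
samples after 2,000 burn-in; proposal adapted toward ~25% acceptance
during burn-in only), with 95% CIs from the 2.5/97.5 percentiles. Model
variants are compared by `BIC = k ln(n) − 2 ln L` with `n = 8` effective
independent data sets (six curves, mRNA mean, mRNA variance); `k` counts
only free parameters (fixed `k_off` and the directly measured shot-noise
magnitudes excluded), so the base model has `k = 5`.

A caveat on model selection at the 20-cell scale: the likelihood treats
lags as independent, but the normalization of each curve by its measured
zero-lag value introduces a common-mode scale error (for the CTD–Ser5ph
cross curve its SD is ~4–5% per 20-cell dataset, driven by the product of
the two largest shot-noise amplitudes). A one-parameter variant can absorb
such a coherent deviation, making the likelihood-ratio null heavier-tailed
than χ²₁; in repeated synthetic experiments the base model wins the BIC
comparison in roughly 6-7 of 10 replicates rather than nearly always.

## Stochastic simulation

The Gillespie direct method runs on any model spec (numba-jitted inner
loop with a pure-Python fallback; identical seeding via the generator's
own `np.random.seed`). The state is recorded on a uniform grid — all
downstream analyses consume sampled traces — after a discarded burn-in of
ten times the slowest relaxation timescale of `S W1`. Intensity traces add
iid Gaussian shot noise per frame with SD equal to the configured multiple
of the noiseless channel's ensemble SD (1.98/1.42/0.41 for CTD/Ser5ph/mRNA
by default), then normalize each channel to a pooled 95th percentile of
one.

**Simulated ChIP** uses a dedicated promoter+cluster core with
per-polymerase bookkeeping: each escaping polymerase traverses ten gene
bins deterministically at the elongation rate (default 4.1 kb/min) and
dwells at the 3′ bin for an Exp(`k_processing`) time (default 0.27/min);
cluster polymerases occupy bin 1. The default gene length is computed from
rate consistency, `L = v·(1/k_c − 1/k_processing)` ≈ 5.45 kb, so
elongation plus processing average to the fitted completion time; a
consistency check warns (or errors in strict mode) beyond 5%. Occupancy is
time-integrated per bin; `weighting="by_occupancy"` weights cells by their
mean total RNAP2 to emulate the enrichment bias of ChIP toward
high-occupancy genes.

**Perturbations** switch rates at a drug time: `block_burst` (ω → 0),
`block_escape` (k_esc → 0), and variants that also reduce `k_c` by a
given fraction. Rates are floored at 1e-9/min rather than zero to keep the
parameter container valid; this is dynamically indistinguishable from a
full block on the simulated timescales.

## Synthetic data generator

`ExperimentConfig` freezes the study conditions: 20 cells × 200 min at
1-min sampling, the default rates, shot-noise multipliers 1.98/1.42/0.41,
an mRNA count sample of 129 (the size implied by the published SEM of
0.93 at SD 10.55; the same choice makes the variance SE ≈ 14), and a
spatial geometry targeting median separations of 181/148/93 nm
(CTD–mRNA / Ser5ph–mRNA / CTD–Ser5ph). mRNA counts are drawn from long
stochastic simulations of the model (samples 25 min apart), not from a
parametric distribution, so distribution-shape checks test the kinetics.
Position tracks superpose a shared anchor walk (AR(1) with 60-nm
stationary SD and 0.95 frame-to-frame memory), fixed inter-channel offsets
realizing the separation triangle, and 30 nm/axis iid localization noise;
after the 50-frame moving average the offsets dominate and the medians
reproduce the targets within a few percent. All artifacts embed their
seeds and true parameters; regeneration is bit-identical.

What the generator does **not** emulate: cell-to-cell kinetic
heterogeneity (all cells share one rate set), tracking loss or missing
frames, photobleaching in the slow-imaging mode, intensity calibration
drift, and any image-domain effects (detection, masks, registration).
Passing tests therefore demonstrate correctness of the estimators and
inference under the model's own assumptions — not robustness to these
real-data complications.

## Numerical choices and scales

- Moment algebra: eigendecomposition-based lag propagation, tolerance
  ~1e-9 against the dense `expm` oracle; Lyapunov solutions symmetrized
  and checked positive semidefinite.
- Moving-average edges (3-point smoothing): shrunken windows.
- Local minima: strictly lower than both neighbours, plateaus take the
  leftmost point; an optional merge radius collapses noise-split minima
  within one valley.
- Run-off decays are fitted with `A − B·tanh((t − t½)/w)`; cells are
  aligned by the mean of their per-channel half-decay times, and the
  channel-averaged curves are refitted with inverse-variance weights.
  Non-decaying traces (head-to-tail drop < 20%) are excluded.
- Mann–Whitney comparisons use `scipy.stats.mannwhitneyu` (two-sided,
  normal approximation with tie correction).
- Test and acceptance problem sizes: long SSA checks use 2×10⁵ simulated
  minutes (Monte-Carlo SEM ≈ 0.1 molecules on the transcribing mean);
  recovery and model-selection studies use 10 replicate synthetic
  experiments at the full 20-cell scale; dwell-time uncertainty uses the
  400-dataset protocol in the API with smaller batches exercised in the
  test suite.

## Known limitations

- The composite likelihood ignores correlations between lags and between
  curves; parameter SEs from the Metropolis sampler inherit this
  approximation (as does the published fit procedure it follows).
- The geometric-burst reduction requires `k_off ≫ ω`; the rate container
  warns when `k_off < 100·ω`.
- Variant wiring is one defensible reading of the one-extra-parameter
  descriptions; alternative wirings with the same parameter counts exist.
- Missing time points are not supported (uniform grids are enforced).
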