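# Methods

## Structural model

Seven compartments track the four measured analytes. A sublingual dose
enters a dissolution depot and reaches a buccal compartment at rate `ka`
(1/h). From the buccal site the drug splits: `k12` into the BUP central
compartment and `k14` directly into BUP-g (buccal first-pass
glucuronidation). BUP distributes to a peripheral compartment (`k26`/`k62`)
and is metabolized to Nor-BUP (`k23`) and BUP-g (`k24`). Nor-BUP is
glucuronidated to Nor-BUP-g (`k35`) or eliminated (`k30`); BUP-g converts to
Nor-BUP-g (`k45`), which is eliminated (`k50`). Only `k30` and `k50` remove
mass from the system. Amounts are in µg; dividing by the apparent volumes
`v2` (BUP, Nor-BUP) and `v3` (both glucuronides, shared to keep the model
identifiable) gives concentrations in µg/L ≡ ng/mL. The volumes are
apparent (V/F): sublingual bioavailability is not a separate parameter.

All transfers are first order, so the system is linear:
`x'(t) = A x(t)` with bolus additions to the depot. It is solved exactly,
piecewise between dose events, as `x(t+Δ) = e^{AΔ} x(t)`. The propagator
uses the eigendecomposition of `A` when it is well conditioned (one
decomposition serves every step size) and falls back to `scipy.linalg.expm`
otherwise; an eighth bookkeeping row accumulates eliminated mass so that
mass balance can be audited at any output time (dose in = on board +
eliminated, relative error ≤ 1e-6 enforced by tests). Three-compartment BUP
disposition is deliberately out of scope.

Default parameter values are the final population estimates shipped with
the package (`ThetaSet()`), e.g. `ka` 2.54 1/h, `k12` 2.34 1/h, `k24`
1.28e-1 1/h, `v2` 861 L. Two printed variants exist for `k30`: 3.81e-3 1/h
(used as the default, being the value the running text states twice) and
3.81e-4 1/h (`model_core.K30_TABLE_VARIANT`); the choice is immaterial for
every BUP-side result because `k30` only touches Nor-BUP elimination.

### An exact non-identifiability, and the gauge we report

The two sequential absorption steps are exchangeable: replacing
`(ka, k12, k14)` by `(k12+k14, ka·r, ka·(1−r))` with `r = k12/(k12+k14)`
rescales the unobserved buccal amount and leaves every plasma concentration
of all four analytes identical (verified numerically to machine precision).
Plasma data therefore cannot decide which of the two rates is `ka`. The
estimators fit both modes and report the canonical gauge `ka ≤ k12 + k14`
— the orientation of the published estimates (2.54 < 3.63), i.e. buccal
dissolution as the rate-limiting absorption step.

## Population model

Five parameters carry inter-individual variability — `k24`, `k23`, `k35`,
`k45`, `k50` — as `p_i = p_pop · exp(η_i)`, `η_i ~ N(0, ω_p²)`, which keeps
individual parameters positive. The IIV is diagonal (off-diagonal terms
were not supported by the data behind the model). Residual error is
additive on the log scale with an analyte-specific SD: `log DV = log pred +
ε`, `ε ~ N(0, σ_analyte²)`. The reported percentage blocks are read as
`100·√ω²` and `100·√σ²` on the log scale (defaults ω: 0.41, 0.63, 0.70,
0.56, 0.54; σ: 0.38, 0.29, 0.80, 0.26); `OmegaSpec.from_percent(...,
convention="cv")` supports the `ln(1+CV²)` reading instead.

## Steady state and the Css metric

Steady state is produced transparently by repeated-dose propagation of the
pre-dose state (`s ← e^{Aτ}(s + dose)`), declared converged when all four
trough concentrations change by < 1e-4 (relative) between doses; the
closed-form cyclic fixed point is used only as an independent oracle in the
tests. A finite course is propagated exactly, without early stopping.

The dose-selection question compares each virtual patient's steady-state
concentration (Css) with 3 ng/mL. Css is read as the **interval average**
`C̄ss = AUC_τ/τ`, computed by the exact identity `∫x = −A⁻¹·dose` for a
periodic linear system — the standard meaning of a steady-state
concentration under repeated dosing. A pre-dose-trough reading was
considered and rejected: with the packaged estimates it yields attainment
fractions (≈3% at 16 mg QD) that are irreconcilable with the framework's
own published simulation results, whereas the interval average reproduces
them to within a few percentage points. Trough and whole-interval-minimum
modes remain available (`metric="trough"`/`"cmin"`). Threshold simulations
use IIV only, no residual error: the target quantity is pharmacological
exposure, not an assay replicate.

## Estimation

**OFV.** The objective function is −2 log marginal likelihood of the
log-transformed concentrations. With zero IIV it is the closed-form
Gaussian expression. Otherwise the five random effects are integrated per
subject by importance sampling: a Nelder–Mead search finds the
empirical-Bayes mode, a finite-difference Hessian (symmetrized,
eigenvalue-floored, inflated ×1.4) provides the Gaussian proposal, and the
log-mean of the importance weights is accumulated with a delta-method
Monte-Carlo SE. Everything is deterministic given the seed, so nested
models can be compared with common random numbers (base vs itself gives
ΔOFV = 0 exactly).

**SAEM.** Individual log-parameters are updated by Metropolis-within-Gibbs
in three blocks mirroring the model's sub-systems (absorption `ka,k12,k14`;
parent disposition `k23,k24,k26,k62,v2`; metabolite disposition
`k35,k45,k30,k50,v3`), with per-block scales adapted toward 30% acceptance
and a proposal-spread floor (0.10) so a transiently collapsed variance
cannot freeze the chains. Latent parameters start from a prior draw, not
from the mean — otherwise the first full-weight variance update collapses
ω. Sufficient statistics are smoothed with step 1 during burn-in and 1/k
afterwards; population means, IIV variances and residual variances then
have closed-form updates. Parameters without IIV receive an artificial
random-effect SD that decays from 0.30 to a 0.03 floor (keeping their
updates closed-form), and are additionally refined every 20 iterations by a
short Levenberg–Marquardt pass on the complete-data likelihood — the
random-walk updates alone descend the strongly correlated directions
(absorption chain, central–peripheral exchange) far too slowly. The final
refinement also restarts from the mirrored absorption mode and reports the
canonical gauge. All least-squares refinements are bounded to ±15 on the
log scale so an unidentified parameter cannot run off along a flat
direction. Defaults: 300 burn-in + 200 smoothing iterations, 2 chains, 2
Metropolis sweeps per iteration; all configurable. With no random effects
at all the fit collapses to exact ML via iteratively reweighted nonlinear
least squares (with the same two-mode search).
Convergence is flagged (never raised) from the drift of late-trace medians,
with an allowance proportional to each parameter's own late-trace spread so
that a structurally weak parameter does not veto the flag.

**Bootstrap.** Subjects are resampled with replacement and refitted;
medians and 2.5th/97.5th percentiles are reported per parameter
(default 500 replicates, matching the tabulated analysis; the methods-text
figure of 1000 is available via `n_reps`). Relative standard errors come
from the bootstrap spread (percentile half-width / 1.96 / estimate), since
a curvature-based covariance matrix is not always obtainable for this
model.

**Covariate screening.** For each covariate×IIV-parameter pair the extended
model adds `φ_i = μ + β·c_i + η_i` with `c_i = log(cov_i/median)` for
continuous covariates (power relation) or a 0/1 indicator (proportional
shift). β has a closed-form regression update inside the SAEM M-step. The
pair is significant when the OFV (common random numbers against the base
model) drops by ≥ 3.84 points (df = 1). Constant covariates are skipped.

## Diagnostics

The pc-VPC simulates replicate studies on the dataset's own design, rescales
observed and simulated values within each (analyte × nominal time) bin by
`median(PRED in bin)/PRED_ij`, and contrasts the observed 2.5/50/97.5th
percentiles with the 95% prediction intervals of those percentiles across
replicates (default 1000). The computational contract is the result table;
the figure is an optional layer. GOF tables report PRED, empirical-Bayes
IPRED and (weighted) log-scale residuals per observation.

## Synthetic studies

The generator emulates the design that produced the model: 11 analyzable
subjects (doses 3×4 mg, 7×8 mg, 1×16 mg — mean 7.6 mg, matching the partial
published allocation), chronic once-daily dosing represented by 14 prior
doses before the observed one (patients dosed for ≥3 months; 14 daily doses
put every analyte within ~0.2% of its cyclic steady state), sampling at
0, 0.5, 1, 2, 3, 4, 6, 8 h, LLOQ 0.05 ng/mL with BLQ flagging, covariates
near the cohort means (46.7 y, 68 kg, 15% CV, balanced sex). A flag emulates
the patients' real-world twice-daily self-dividing of the dose; an optional
pattern drops samples to mimic incomplete draws. What it does **not**
emulate: assay drift, hemolysis, non-adherence, nonlinear kinetics,
covariate-dependent parameters — so green tests say the pipeline recovers
what this model generates, not that the model is true of real patients.

Fitting discards BLQ records (M1); the LLOQ travels with the dataset.
NCA excludes BLQ records listwise, uses the linear trapezoid, reports the
pre-dose sample as the trough C0, and never extrapolates observed data to
infinity (the 8 h window is far shorter than the ~37 h terminal half-life);
model-based profiles may use analytic AUC₀₋∞. Molar masses for the pathway
ratios default to BUP 467.6, Nor-BUP 413.5, BUP-g 643.8, Nor-BUP-g 589.7
g/mol (configurable; they are conventions of this package, not published
with the model).

## Problem sizes and known limitations

* Test-suite experiments are scaled to run unattended: recovery designs use
  24 subjects × 12 post-dose times (no-IIV, σ = 0.05) and 100 subjects × 15
  times (full variability) on single-dose washout sampling, chosen by
  Fisher-information analysis as the most informative layouts of that size;
  SAEM test runs use 1 chain and 200 + 150 iterations; the packaged VPC
  check uses 200 replicates. Production defaults are larger (see above).
* `k30` is ~3% of Nor-BUP's total elimination. Its observable footprint is
  a fraction of a percent of the Nor-BUP-g level, so no concentration-only
  design of the sizes above identifies it (Cramér–Rao lower bounds of
  several hundred percent); fits return essentially arbitrary values for
  it. It is retained for structural fidelity, but its printed value should
  be treated as an assumption.
* The absorption-order gauge (above) means `ka` and `k12+k14` are only
  identified as an unordered pair.
* The external-validation simulation uses one common design (single dose,
  0–72 h AUC window on a 0.25 h grid) across source studies whose actual
  designs differed; the packaged printed table is the reference for ratio
  arithmetic, and the fresh simulation is a consistency check, not a
  reproduction of the printed predicted columns (which are not
  dose-proportional and therefore cannot come from one linear-model design).
* Estimation assumes the shared-`v3` structure; fitting other structures is
  out of scope.
* Reproducibility: every stochastic routine is driven by an explicit seed
  and reproduces its results run to run. The one caveat is bit-level: BLAS
  kernel dispatch can perturb small matrix products at machine precision
  depending on process memory state, and a Metropolis chain amplifies an
  ulp into a different accepted path. Smooth outputs (simulations, NLS
  fits, OFV values) reproduce to solver precision regardless; SAEM chains
  reproduce exactly in practice but are compared at a 1e-6 relative
  tolerance in the tests for this reason.
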