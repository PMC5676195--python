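# Methods

## Model class and assumptions

All measures are functionals of a stable Gaussian VAR(p),
`x(t) = Σ_{k=1..p} A_k x(t−k) + e(t)` with innovation covariance `Σ` and
sampling rate `fs`. Assumptions: linearity, stationarity (companion
spectral radius < 1), no missing data, and — for the interpretation of the
measures — that the observed channels are the complete system (latent
confounders are out of scope, as are nonlinear and time-varying
extensions). Stability is enforced on ground-truth models before
simulation; fitted models only carry a stability flag, since near-unit-root
estimates are legitimate outputs of OLS.

Spectra use per-sample normalization, `S(f) = H(f) Σ H(f)ᴴ` with no
division by `fs`. Every causality measure in the package is a
scale-invariant ratio of such quantities, so the convention affects only
raw PSD values written by the decomposition/spectra writers (where it is
noted in the column docs).

## Geweke spectral GC and the clamping convention

The bivariate measure removes instantaneous innovation correlation by
partializing the source innovation against the target
(`σ̃²_ss = Σ_ss − Σ_ts²/Σ_tt`, a lower-Cholesky-equivalent normalization).
The benchmarks use diagonal `Σ`, where this is a no-op and results are
channel-ordering independent; with correlated innovations the conditional
construction is ordering-dependent, and the ordering actually used
([target, cond..., source]) is recorded in each spectrum's provenance.

The conditional measure follows Geweke's construction: the full system's
spectral factor is filtered through the inverse transfer of the reduced
model (fitted or derived on `{target} ∪ cond`), the source innovation is
partialized against the reduced-set innovations, and the log ratio is taken
with the reduced innovation variance of the target — flat across frequency,
because reduced-model innovations are white — in the numerator.

Numerical guard: log-ratio arguments below 1 are clamped to 1 (GC = 0), and
nonpositive denominators are likewise mapped to GC = 0, never NaN. Clamp
events are counted per call (provenance `n_clamped`), accumulated
package-wide, and reported in every CLI manifest. For theoretical curves
clamps occur only at roundoff level near true zeros; for the misspecified
classical estimator they occur in earnest (the population denominator of a
reduced-order-3 fit actually crosses zero at some frequencies on the
three-node system), and the clamp count is the honest record of that.

## State-space route

A VAR(p) is embedded in innovations form with companion state
(`n = M·p`; no model-order reduction): `A` the companion matrix,
`C = [A_1 … A_p]`, `K` loading the innovation into the first block,
`V = Σ`. Observing a channel subset yields a state-space model with
correlated state/observation noise whose stationary Kalman filter — hence
the subprocess's exact innovations representation — solves the filter DARE
with `Q = KVKᵀ`, `R = V[keep,keep]`, `S = KV[:,keep]`. The solve uses
`scipy.linalg.solve_discrete_are` on the transposed (dual) system, verified
to a Riccati residual below 1e-8 (benchmarks achieve ~1e-12), with a
fixed-point iteration fallback (tolerance 1e-12, at most 10⁴ iterations)
for cases the QZ-based solver declines. Channel reorderings used by the
partitioned formulas are recorded in provenance and original labels are
restored on output.

Two independent routes compute every theoretical conditional GC curve:

1. **state-space closed form** (default) — exact reduced innovations from
   the DARE;
2. **high-order projection** — exact autocovariances from the companion
   discrete Lyapunov equation, then block Yule–Walker projection of the
   subprocess onto a VAR(128).

The truncation error of route 2 decays with the subprocess spectral radius
to the 128th power (≈1e-6 at radius 0.9); the two routes agree to ~1e-13 on
the benchmarks and cross-validate each other in the tests. Route 2's order
is configurable (`reduced_order`).

## DC, PDC, decomposition

Squared-magnitude DC uses the diagonal-`Σ` formula; innovation
cross-correlations above 1% trigger a counted warning, and
`orthogonalize="cholesky"` switches to the ordering-dependent generalized
form. PDC is the original coefficient-based variant. The decomposition
writes `S_t|j(f) = S_tt(f)·|γ_{t←j}(f)|²` with the squared DC — the only
form under which the portions sum exactly to `S_tt(f)`; additivity is
re-verified before any CLI write and a violation above 1e-8 aborts (it
would indicate an internal bug, since additivity holds by construction).

Scale behaviour, verified in tests: DC is invariant to positive rescaling
of any channel (factors 0.1 and 10 tested). Original PDC is *not* invariant
to rescaling a single channel — under `y = Dx` the coefficient transform
becomes `D A(f) D⁻¹` and the column normalization mixes differently scaled
rows; this scale sensitivity motivated the later generalized PDC, which is
out of scope here. What original PDC does guarantee, and what the tests
assert, is complete independence from the innovation variances and
invariance to uniform rescaling of all channels. Known limitation: PDC
values are therefore unit-dependent and channels should be measured on
comparable scales.

## Estimation choices

- **OLS VAR fit**: no intercept (benchmark processes are zero-mean; a
  `demean()` preprocessing method subtracts column means instead). Residual
  covariance divisor `(T_eff − M·p)` with `T_eff = T − p`, an
  unbiased-flavour choice fixed so tests are reproducible. Cross-checked
  against statsmodels' VAR (trend "n") to 1e-8.
- **Classical conditional estimator**: full and reduced models are fitted at
  the *same* user-given order by default (the usual practice); independent
  orders are available via `order_reduced`.
- **Order selection**: AIC/BIC over 1..max_order on the ML residual
  covariance, ties broken toward the smaller order.
- **Simulation**: Gaussian innovations from `numpy.random.default_rng`
  (PCG64), recursion started from zeros, burn-in default 10³ samples.
  Identical (model, n, seed, burn_in) gives bit-identical series; this
  generator choice is part of the package contract so percentile bands are
  reproducible.
- **Frequency grid**: 513 equally spaced points on [0, fs/2] inclusive by
  default. The trapezoidal grid average of a spectrum equals the
  time-domain measure to ~1e-14 on the benchmarks (Geweke's integral
  identity).

## Benchmark systems

Defaults live in `specgc/benchmark_defaults.yaml` and are version-pinned.
`fs = 120` Hz accommodates the 50 Hz resonance below Nyquist. Each node is
an AR(2) oscillator with conjugate poles at radius 0.9 and angle
`2πf₀/fs` (`a1 = 2ρcos(2πf₀/fs)`, `a2 = −ρ²`), giving a clear spectral
peak near `f₀` with realistic bandwidth.

- **three_node**: resonances 40/10/50 Hz; couplings 1→2 (lag 2) and 2→3
  (lag 3), both 0.35, making the system a genuine VAR(3) — the lag-3
  coupling is what lets order selection recover p = 3 — with unidirectional
  chain structure. Because coupling is triangular in channel order, the
  companion eigenvalues are exactly the uncoupled oscillator poles, so
  stability holds for any coupling strength; 0.35 was chosen to give
  clearly visible causal peaks (theoretical GC maxima ≈ 1.7 and 2.7)
  without dominating the intrinsic dynamics.
- **two_node**: transmitter at 50 Hz, receiver at 10/30/50 Hz across
  configurations, coupling 1→2 at lag 1 (0.35) identical in all three; unit
  innovation variances on both nodes.

The study defaults are 100 realizations of 500 samples each (the
per-realization length is a package choice, stated here because it is a
knob of the bias/variance picture: shorter records amplify the classical
estimator's pathologies, longer ones shrink all bands). Realization `i`
uses seed `master_seed + i`. Fit failures are excluded with a logged count
and more than 10% failures aborts. The automated checks and the acceptance
script run a scaled-down study (50 realizations) to keep the default suite
fast; the qualitative orderings they assert (state-space beats the
classical estimator on null-direction bias and on band width, the classical
fit at the true order is strongly biased on coupled directions) are stable
well below that size.

## What the synthetic benchmarks do and do not show

The generators produce exactly the model class the measures assume:
stationary, Gaussian, finite-order VAR with known ground truth. Passing
tests therefore demonstrate correctness of the estimators and the
closed-form algebra *within* that class. They do not probe measurement
noise, volume conduction / instantaneous mixing, nonstationarity,
nonlinearity, unobserved confounders, or sampling-rate mismatch — all
first-order concerns with real neural or physiological recordings that this
package does not address.

## Degenerate inputs and tie-breaks

Non-PD innovation covariances, shape mismatches and non-increasing
frequency grids are rejected at construction; unstable coefficient sets
warn and flag rather than error (but refuse to simulate or embed). A
singular coefficient transform reports the offending frequency. Order
selection breaks IC ties toward the smaller order via first-minimum argmin.
Channel roles may be given by label or 0-based index anywhere; duplicates
and overlapping source/target/conditioning roles are rejected.
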