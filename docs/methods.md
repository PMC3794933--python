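# Methods

## The minimization core

`parafit.lm` implements the damped Gauss–Newton (Levenberg–Marquardt)
method for dense problems with few parameters (n ≤ ~10) and up to a few
thousand data points, in the classic Minpack formulation.  Given a residual
function `f(x)` of length m, each iteration:

1. builds the Jacobian `J` (forward differences with step
   `h_j = sqrt(eps) · max(|x_j|, 1)`, or an analytic callback);
2. factorizes `J P = Q R` by Householder reflections with column pivoting
   on the largest remaining column norm (first index wins ties); pivot
   norms are downdated and recomputed when cancellation degrades them;
3. solves `(JᵀJ + λ DᵀD) δ = −Jᵀf` through the factored augmented system
   `[R; sqrt(λ) D_π]` using Givens rotations (`J ᵀJ` is never formed);
4. chooses λ by a safeguarded Newton iteration (at most 10 steps) so that
   `‖Dδ‖` lands within 10% of the trust radius Δ, with the Gauss–Newton
   step accepted outright when it already fits;
5. updates Δ by the gain ratio (actual/predicted cost reduction): shrink
   ×0.5 below ¼, grow ×2 above ¾; accepts the step only if the cost
   strictly decreases.

Termination: relative cost change (`ftol`), scaled step size (`xtol`),
scaled gradient (`gtol`), or the iteration cap.  Defaults
`ftol = xtol = gtol = 1e-10`, `max_iter = 200`, initial
`Δ₀ = 100 · ‖D x₀‖` (or 100 if that is zero) — the conventional
Minpack/MPFit control values; the applications here converge in 5–30
iterations and are insensitive to these within wide margins.

**Scaling.** `D` is initialized from the Jacobian column norms (the square
root of the diagonal of `JᵀJ`) and updated each iteration to the running
maximum of column norms.  The running maximum prevents the scaling from
collapsing along directions that become momentarily flat.

**Numerical choices.**

* The Euclidean norm scales by the largest magnitude before squaring, so
  it cannot overflow for entries near the floating-point maximum.
* Rank deficiency: back substitution treats a diagonal entry of the
  triangular factor as zero when `|S_jj| ≤ max(m,n) · eps · |S_00|`, and
  zeroes the corresponding solution components in the pivoted basis.  An
  exact-zero test would miss numerically duplicate columns, whose trailing
  diagonal is ~1e-16 of the leading one and would otherwise produce
  ~1e16-sized steps.
* Bounds are enforced by clamping proposed steps (the effective step after
  clamping is what enters the gain ratio); fixed parameters are excluded
  from the solve entirely.  Clamping is transparent and adequate for the
  mild physical bounds used here; it is not an active-set method.
* `batch_fit` maps the single-problem solver over the batch (optionally on
  a thread pool).  Because every fit is independent and deterministic,
  results are bitwise identical for any worker count; a failing fit is
  recorded in its own result and never aborts the batch.
* Reported standard errors are `sqrt(diag((JᵀJ)⁻¹))`, exact when the
  residuals are variance-standardized (the MLE transform); unweighted
  residuals require the usual `sqrt(cost/(m−n))` factor.

## Estimators

For Poisson photon counts the least-squares estimator is statistically
inefficient at low counts.  The MLE residual
`r_i = sqrt(2 |f_i − y_i − y_i ln(f_i/y_i)|)` converts the Poisson deviance
into a sum of squares so the LM engine minimizes it directly.  The inner
expression is nonnegative for all positive `f, y` (equality iff `f = y`),
so the absolute value only guards floating-point underflow.  The unsigned
square root has a derivative-sign kink at `f_i = y_i`; in practice this is
harmless because the Gauss–Newton direction `Jᵀr` is unchanged by row
signs, and forward differences only blur the Jacobian in an O(h)
neighborhood of exact equality.  A signed variant
(`sign(f−y) · r`) is available behind a flag for robustness studies.
Model values are clamped to `model_floor = 1e-10` before the logarithm.

## Single-molecule localization

Model: point-sampled 2-D Gaussian
`B + A·exp(−((x−x_c)² + (y−y_c)²)/(2w²))` at integer pixel centers, with
`(row, col) = (y, x)` and 0-based coordinates.  `w` is the Gaussian
standard deviation ("waist" in the 1/e² sense would be `2w`); an
integrated-per-pixel PSF variant is out of scope.  Initialization uses the
maximum pixel (A and center), the minimum pixel (B), and a caller-supplied
width; images whose minimum is zero get +0.1 added to every pixel before
fitting (keeping the MLE logarithm finite) and the fitted background is
corrected by −0.1 afterwards.  The initial A and B refer to the offset
image — simpler and self-consistent.  Mild bounds (`B ≥ 0`, `A > 0`,
centers within one pixel of the grid, `w ∈ [0.1, 2s]`) keep very dim fits
on the grid.

The Cramér–Rao bound uses the Poisson Fisher information
`I_jk = Σ_p (∂μ_p/∂θ_j)(∂μ_p/∂θ_k)/μ_p` with analytic model derivatives;
its inverse diagonal (restricted to the free parameters) is the variance
floor for any unbiased estimator.  Monte-Carlo studies report the fitted
standard deviation of the center estimates next to `sqrt(CRLB)`; failed
fits are dropped and counted, never imputed.

## Lifetime fitting

Model: `A · (irf ⊛ e)` with `e_k = exp(−t_k/τ)` normalized to unit sum
over the N bins and `⊛` the circular convolution over the laser period.
Circular wrap plus renormalization is equivalent to the geometric-series
closed form `1/(1 − e^{−T/τ})` of the wrapped tail whenever the IRF is
contained in the window, and guarantees photon conservation
`Σ model = A` exactly — the defining constraint, since A is the photon
count of the curve.  The convolution is a Cauchy product (direct double
summation, evaluated as a gather-and-dot); an FFT path exists purely as an
independent cross-check.  The Gaussian IRF is point-sampled at bin times
and normalized, consistent with the point-sampled decay.

Per-histogram fits initialize A from the total count and τ from a constant
(`T/5` by default — any constant in the physical range works for the LM
solver); histograms with fewer than 10 photons are flagged unfittable.
Lifetime images fit only pixels whose total intensity reaches the
threshold; masked pixels are NaN in the τ/A maps.

## Synthetic data

Generators emulate shot-noise-limited acquisition: each image/histogram is
an independent Poisson draw of the noise-free model.  Randomness uses
NumPy's PCG64 with per-item substreams derived from
`SeedSequence([seed, index])`, so output is bitwise reproducible and
item i is independent of the batch size.  Spot centers are jittered
uniformly within ±0.5 px of the grid center by default to avoid
grid-locking the estimator statistics (switchable).  Not emulated: camera
read noise, EMCCD gain, detector afterpulsing, dark counts, IRF drift, or
multi-emitter overlap — passing tests demonstrate estimator correctness
and efficiency under pure shot noise, not robustness to those effects.

### Default study conditions

The default conditions are chosen once as field-realistic values:
localization sweeps use 7×7-pixel images, `w = 1` px, background 2
counts/pixel and total signal photons 100–1000 (the regime where
MLE-versus-LSE differences and CRLB attainment are most informative);
lifetime studies use τ = 2.5 ns in a T = 12.5 ns window (an 80 MHz
repetition laser), 64 bins, and a 100 ps-FWHM Gaussian IRF centered at
1 ns — typical multiphoton-FLIM settings.  Peak amplitude for a requested
photon budget is `A = photons/(2πw²)`.  All are exposed as parameters.

## Known limitations

* Single-exponential decays only; no multi-exponential, stretched
  exponential, phasor or time-gated analysis.
* Single-emitter images only; no spot detection/cropping and no
  high-density multi-emitter models; isotropic PSF (no astigmatic 3-D).
* Lifetime precision at N photons is information-bounded: with A and τ
  both free, `std(τ̂)/τ ≥ 1/sqrt(N · c)` where `c = Var(t)/τ² ≤ 1` is the
  window-truncation factor (`c ≈ 0.83` for `T/τ = 5`).  At 1000 photons
  this floor is ~3.5% relative, i.e. a median absolute relative error of
  ~2.3% for an efficient estimator — which the Monte-Carlo studies show
  this fitter attains.  No fitting method can do better under these
  conditions; claims below the floor indicate a biased comparison.
* The trust-region constants and tolerances are conventional defaults,
  not tuned per application.
* The problem sizes in the test suite and acceptance script (1000–2000
  replicates per condition, 32×32 lifetime images) are the package's
  desk-scale study sizes; the statistics scale as expected to larger runs.
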