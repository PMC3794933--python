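# parafit

Batched Levenberg–Marquardt model fitting for pixel-wise parametric imaging
microscopy, with two complete applications:

* **single-molecule localization** (superresolution localization
  microscopy): Poisson maximum-likelihood fitting of small single-emitter
  images to a 2-D Gaussian point spread function, benchmarked against the
  Cramér–Rao lower bound;
* **fluorescence-lifetime imaging** (TCSPC FLIM): per-pixel reconvolution
  fitting of photon arrival-time histograms to a single-exponential decay
  convolved with the instrument response function, with intensity-threshold
  masking for lifetime-image assembly.

It is written for microscopists and method developers who need to fit the
same small model tens of thousands of times — one fit per emitter or per
pixel — with results that are deterministic, independent of batch order and
directly comparable to the theoretical precision limits.

## The fitting engine

The core (`parafit.lm`) is a dense, Minpack-style trust-region
Levenberg–Marquardt solver written from scratch.  Each iteration solves the
damped normal equations

    (JᵀJ + λ DᵀD) δ = −Jᵀf

through the pivoted Householder QR factorization `J P = Q R` of the
Jacobian and a Givens-rotation update of the augmented system — never by
forming or inverting `JᵀJ`.  The damping factor λ is found by a safeguarded
Newton iteration that matches the scaled step length `‖Dδ‖` to a trust
radius updated by the usual gain-ratio rule; the diagonal scaling `D`
(square root of the diagonal of `JᵀJ`, i.e. Jacobian column norms) makes
convergence invariant to parameter units.  Jacobians default to forward
differences; analytic callbacks are accepted.

Two residual transforms feed the engine (`parafit.estimators`):

* least squares: `r_i = f_i − y_i`;
* Poisson MLE: `r_i = sqrt(2 |f_i − y_i − y_i ln(f_i / y_i)|)` (with
  `r_i = sqrt(2 f_i)` where `y_i = 0`), whose squared sum is the Poisson
  deviance, so minimizing it maximizes the Poisson likelihood of
  photon-count data.

## Worked example

```bash
python examples/localize_spots.py
```

```
fitted 200/200 spots at 500 photons
std(x_c error)  = 0.0533 px
sqrt(CRLB_x)    = 0.0503 px
bias(x_c)       = -0.0067 px
```

200 simulated 7×7-pixel spots (500 signal photons each, 2 background
counts/pixel, PSF width 1 px) were localized by the Poisson-MLE pipeline.
The localization scatter (0.053 px) sits at the Cramér–Rao bound
(0.050 px) with no detectable bias — the fits are information-efficient.
The other scripts in `examples/` walk through the lifetime image
(`flim_lifetime_image.py`), the MLE-vs-LSE precision comparison
(`mle_vs_lse.py`), the precision-versus-photons studies
(`precision_vs_photons.py`) and direct use of the LM core on a custom
model (`custom_model_fit.py`).

A thin CLI wraps the same functions for shell use:

```bash
parafit simulate-spots --n 500 --photons 500 --seed 1 --out run/sim
parafit fit-spots run/sim/spots.tif --fix-w --out run/fit
parafit simulate-flim --rows 32 --cols 32 --tau 2.0 --tau2 4.0 --out run/fsim
parafit fit-flim run/fsim/flim.tif --threshold 400 --out run/ffit
```

Every run directory receives a `config.yaml` echo (parameters, seed,
package version) so outputs are reproducible bitwise.

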