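"""TCSPC fluorescence-lifetime fitting with periodic IRF reconvolution.

In time-correlated single-photon counting (TCSPC) FLIM, each image pixel
holds a histogram of photon arrival times over the laser period T, divided
into N bins of width dt = T/N.  The measured decay is the fluorescence
decay convolved with the instrument response function (IRF).  The model
used here is a single exponential,

    model = A * (irf (*) e),   e_k = exp(-t_k / tau) / sum_j exp(-t_j / tau)

where ``(*)`` is the *circular* convolution over the N bins — the laser is
periodic, so photons emitted later than one period wrap into the next
window — and the exponential is normalized over the window so that the
total model photon count equals the amplitude A exactly (A is "the number
of photons of the curve").  Normalizing over the window is equivalent to
the geometric-series closed form ``1/(1 - exp(-T/tau))`` of the wrapped
tail whenever the IRF is fully contained in the window.

The convolution is computed as a Cauchy product (direct double summation),
with an FFT-based path available as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import ResidualSpec
from .lm import FitProblem, FitResult, LMConfig, lm_fit

__all__ = [
    "TimingContext",
    "IrfSpec",
    "DecayParams",
    "TcspcHistogram",
    "gaussian_irf",
    "cauchy_conv",
    "fft_circular_conv",
    "decay_model",
    "fit_histogram",
    "lifetime_image",
    "flim_precision_study",
]

# cached (k - j) mod N gather indices, keyed by N
_CONV_IDX: dict[int, np.ndarray] = {}


@dataclass(frozen=True)
class TimingContext:
    """Laser period T (ns) divided into N time bins; t_k = k * dt, k=1..N."""

    T: float
    N: int

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("laser period T must be > 0")
        if self.N < 8:
            raise ValueError("need at least 8 time bins")

    @property
    def dt(self) -> float:
        return self.T / self.N

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(1, self.N + 1)


@dataclass
class IrfSpec:
    """Instrument response function as a normalized length-N histogram."""

    histogram: np.ndarray
    t0: Optional[float] = None
    fwhm: Optional[float] = None

    def __post_init__(self) -> None:
        h = np.asarray(self.histogram, dtype=np.float64)
        if h.ndim != 1 or np.any(h < 0):
            raise ValueError("IRF histogram must be a 1-D nonnegative vector")
        total = h.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("IRF histogram must sum to 1")
        self.histogram = h

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "IrfSpec":
        """Build from a measured (unnormalized) IRF histogram."""
        counts = np.asarray(counts, dtype=np.float64)
        total = counts.sum()
        if total <= 0:
            raise ValueError("IRF histogram has no counts")
        return cls(histogram=counts / total)


@dataclass
class DecayParams:
    """Single-exponential decay: amplitude A (photons) and lifetime tau (ns)."""

    A: float
    tau: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("amplitude A must be > 0")
        if self.tau <= 0:
            raise ValueError("lifetime tau must be > 0")


@dataclass
class TcspcHistogram:
    """Per-pixel photon arrival histogram with its timing context."""

    counts: np.ndarray
    context: TimingContext

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size != self.context.N:
            raise ValueError("counts length must match context N")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        self.counts = c

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def gaussian_irf(ctx: TimingContext, t0: float, fwhm: float) -> IrfSpec:
    """Gaussian IRF sampled at the bin times and normalized to sum 1.

    ``sigma = fwhm / (2 sqrt(2 ln 2))``; requires ``0 < t0 < T``.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if not (0.0 < t0 < ctx.T):
        raise ValueError("t0 must lie inside the laser period (0, T)")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    h = np.exp(-((ctx.times - t0) ** 2) / (2.0 * sigma**2))
    total = h.sum()
    if total <= 0:
        raise ValueError("IRF underflowed to zero; widen fwhm")
    return IrfSpec(histogram=h / total, t0=t0, fwhm=fwhm)


def _conv_indices(n: int) -> np.ndarray:
    idx = _CONV_IDX.get(n)
    if idx is None:
        k = np.arange(n)
        idx = (k[:, None] - k[None, :]) % n  # idx[k, j] = (k - j) mod n
        _CONV_IDX[n] = idx
    return idx


def cauchy_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution by direct double summation (Cauchy product).

    ``c_k = sum_j a_j * b_{(k - j) mod N}``.  The double sum is evaluated
    as a gather-and-dot over the (N, N) index table, which is the same
    arithmetic as the explicit nested loops.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch ({a.size} vs {b.size})")
    return b[_conv_indices(a.size)] @ a


def fft_circular_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Transform-domain circular convolution (cross-check path)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch ({a.size} vs {b.size})")
    return np.real(np.fft.ifft(np.fft.fft(a) * np.fft.fft(b)))


def decay_model(
    p: DecayParams, irf: IrfSpec, ctx: TimingContext
) -> np.ndarray:
    """Reconvolved single-exponential model; total photons equal A exactly.

    The exponential is normalized to unit sum over the window (absorbing the
    periodic wrap) and circularly convolved with the unit-sum IRF, so
    ``sum(model) = A`` to rounding.
    """
    if irf.histogram.size != ctx.N:
        raise ValueError("IRF length does not match timing context")
    e = np.exp(-ctx.times / p.tau)
    e /= e.sum()
    return p.A * cauchy_conv(irf.histogram, e)


def fit_histogram(
    h: TcspcHistogram,
    irf: IrfSpec,
    cfg: Optional[LMConfig] = None,
    tau_init: Optional[float] = None,
    estimator: str = "mle",
    min_photons: float = 10.0,
) -> tuple[DecayParams, FitResult]:
    """Fit (A, tau) to one TCSPC histogram by reconvolution.

    A is initialized from the total count; tau from ``tau_init`` (default
    T/5 — a constant in the physical lifetime range works well for the LM
    solver).  Histograms with fewer than ``min_photons`` total counts are
    flagged unfittable (status ``too_few_photons``) rather than raising.
    """
    ctx = h.context
    if irf.histogram.size != ctx.N:
        raise ValueError("IRF length does not match histogram bin count")
    total = h.total
    if tau_init is None:
        tau_init = ctx.T / 5.0
    if total < min_photons:
        return (
            DecayParams(A=max(total, 1e-6) or 1e-6, tau=tau_init),
            FitResult(
                x=np.array([total, tau_init]), cost=np.inf, n_iter=0,
                n_feval=0, status="too_few_photons",
                message=f"only {total:g} photons (< {min_photons:g})",
            ),
        )
    spec = ResidualSpec(estimator=estimator)
    data = np.asarray(h.counts, dtype=np.float64)
    irf_h = irf.histogram
    times = ctx.times

    def residual(x: np.ndarray) -> np.ndarray:
        A, tau = x
        e = np.exp(-times / tau)
        e /= e.sum()
        model = A * cauchy_conv(irf_h, e)
        return spec.residuals(model, data)

    problem = FitProblem(
        residual_fn=residual,
        x0=np.array([total, float(tau_init)]),
        lower=np.array([1e-6, ctx.dt / 50.0]),
        upper=np.array([np.inf, 50.0 * ctx.T]),
    )
    result = lm_fit(problem, cfg)
    A_hat, tau_hat = (float(v) for v in result.x)
    params = DecayParams(A=max(A_hat, 1e-12), tau=max(tau_hat, 1e-12))
    return params, result


def lifetime_image(
    stack: np.ndarray,
    irf: IrfSpec,
    threshold: float,
    ctx: TimingContext,
    cfg: Optional[LMConfig] = None,
    tau_init: Optional[float] = None,
    estimator: str = "mle",
):
    """Threshold-masked per-pixel lifetime fitting of a FLIM stack.

    ``stack`` is (rows, cols, N).  Pixels whose total intensity is below
    ``threshold`` counts are masked and not fitted (NaN in the output
    maps).  Returns ``(tau_map, A_map, intensity_map, mask, n_fitted)``
    where ``mask`` is True for fitted pixels and ``n_fitted`` counts pixels
    that were above threshold (per-pixel fit failures stay NaN in the maps
    but are included in ``n_fitted``'s above-threshold count — the report
    distinguishes them via NaN).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (rows, cols, N)")
    rows, cols, nbins = stack.shape
    if nbins != ctx.N or irf.histogram.size != ctx.N:
        raise ValueError(
            f"bin-count mismatch: stack has {nbins}, context/IRF expect {ctx.N}"
        )
    intensity = stack.sum(axis=2).astype(np.float64)
    mask = intensity >= threshold
    tau_map = np.full((rows, cols), np.nan)
    A_map = np.full((rows, cols), np.nan)
    for r, c in zip(*np.nonzero(mask)):
        h = TcspcHistogram(counts=stack[r, c], context=ctx)
        params, result = fit_histogram(
            h, irf, cfg=cfg, tau_init=tau_init, estimator=estimator
        )
        if result.success:
            tau_map[r, c] = params.tau
            A_map[r, c] = params.A
    return tau_map, A_map, intensity, mask, int(mask.sum())


def flim_precision_study(
    photon_levels: Sequence[float] = (100.0, 200.0, 500.0, 1000.0),
    n_histograms: int = 300,
    tau: float = 2.5,
    ctx: Optional[TimingContext] = None,
    irf: Optional[IrfSpec] = None,
    seed: int = 0,
    estimator: str = "mle",
    cfg: Optional[LMConfig] = None,
    return_estimates: bool = False,
):
    """Monte-Carlo lifetime/amplitude precision versus photon count.

    For each photon level A: simulate ``n_histograms`` Poisson TCSPC
    histograms from the reconvolution model, fit each, and report std and
    bias of the fitted tau and A.  Deterministic under a fixed seed.
    Defaults: tau = 2.5 ns, T = 12.5 ns (80 MHz repetition), 64 bins,
    Gaussian IRF with 100 ps FWHM centered at 1 ns.
    """
    from .simulate import TcspcSimConfig, simulate_tcspc

    if n_histograms < 100:
        raise ValueError("n_histograms must be >= 100 for stable statistics")
    if ctx is None:
        ctx = TimingContext(T=12.5, N=64)
    if irf is None:
        irf = gaussian_irf(ctx, t0=1.0, fwhm=0.1)
    rows = []
    estimates: dict[float, pd.DataFrame] = {}
    for level_idx, photons in enumerate(photon_levels):
        truth = DecayParams(A=float(photons), tau=tau)
        sim = TcspcSimConfig(
            n_histograms=n_histograms, ctx=ctx, truth=truth, irf=irf,
            seed=seed + 7919 * level_idx,
        )
        stack, _ = simulate_tcspc(sim)
        tau_hat = []
        A_hat = []
        n_failed = 0
        for counts in stack:
            h = TcspcHistogram(counts=counts, context=ctx)
            params, result = fit_histogram(h, irf, cfg=cfg,
                                           estimator=estimator)
            if result.success:
                tau_hat.append(params.tau)
                A_hat.append(params.A)
            else:
                n_failed += 1
        tau_hat = np.array(tau_hat)
        A_hat = np.array(A_hat)
        rows.append(
            {
                "photons": float(photons),
                "n_fit": tau_hat.size,
                "n_failed": n_failed,
                "std_tau": float(np.std(tau_hat, ddof=1)),
                "bias_tau": float(np.mean(tau_hat) - tau),
                "std_A": float(np.std(A_hat, ddof=1)),
                "bias_A": float(np.mean(A_hat) - photons),
                "median_abs_rel_err_tau": float(
                    np.median(np.abs(tau_hat - tau) / tau)
                ),
            }
        )
        if return_estimates:
            estimates[float(photons)] = pd.DataFrame(
                {"tau_hat": tau_hat, "A_hat": A_hat}
            )
    table = pd.DataFrame(rows)
    if return_estimates:
        return table, estimates
    return table
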