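"""Seeded synthetic-data generators for the two simulation studies.

Every generator is a pure function of its configuration (seed included):
calling it twice yields bitwise-identical output.  Randomness uses NumPy's
PCG64 generator; each image/histogram gets its own substream derived from
``SeedSequence([seed, index])``, so generated items are independent of the
batch size and order.

Emulated noise is Poisson shot noise only — the counting noise inherent to
photon detection.  Camera read noise, EM gain and detector afterpulsing are
deliberately absent; the generators reproduce shot-noise-limited
conditions, which is what the precision-versus-CRLB comparisons assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flim import DecayParams, IrfSpec, TimingContext, decay_model
from .gauss2d import SpotParams, gauss2d_model

__all__ = [
    "SpotSimConfig",
    "TcspcSimConfig",
    "simulate_spots",
    "simulate_tcspc",
    "simulate_flim_image",
]


def _rng(seed: int, *index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *index]))


@dataclass
class SpotSimConfig:
    """Conditions for a batch of synthetic single-emitter images.

    ``n_images`` square images of side ``s`` with background ``B``
    (counts/pixel), peak amplitude ``A`` and width ``w`` (pixels, Gaussian
    sigma).  Centers sit at the grid center, jittered uniformly within
    +-0.5 px per axis unless ``jitter`` is off (jitter avoids grid-locking
    the estimator statistics).
    """

    n_images: int
    s: int = 7
    B: float = 2.0
    A: float = 15.9
    w: float = 1.0
    jitter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.s < 3:
            raise ValueError("image side must be >= 3")
        if self.B < 0 or self.A <= 0 or self.w <= 0:
            raise ValueError("need B >= 0, A > 0, w > 0")


@dataclass
class TcspcSimConfig:
    """Conditions for a batch of synthetic TCSPC histograms."""

    n_histograms: int
    ctx: TimingContext
    truth: DecayParams
    irf: IrfSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_histograms < 1:
            raise ValueError("n_histograms must be >= 1")


def simulate_spots(cfg: SpotSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Poisson-noised 2-D Gaussian spot images plus a per-image truth table.

    Returns ``(stack, truth)``: an (n_images, s, s) integer count stack and
    a DataFrame with columns (index, B, A, x_c, y_c, w, photons) recording
    the generating parameters of each image.
    """
    center = (cfg.s - 1) / 2.0
    stack = np.empty((cfg.n_images, cfg.s, cfg.s), dtype=np.int64)
    rows = []
    for i in range(cfg.n_images):
        rng = _rng(cfg.seed, i)
        if cfg.jitter:
            xc = center + rng.uniform(-0.5, 0.5)
            yc = center + rng.uniform(-0.5, 0.5)
        else:
            xc = yc = center
        p = SpotParams(B=cfg.B, A=cfg.A, x_c=xc, y_c=yc, w=cfg.w)
        model = gauss2d_model(p, cfg.s)
        stack[i] = rng.poisson(model)
        rows.append(
            {
                "index": i, "B": cfg.B, "A": cfg.A, "x_c": xc, "y_c": yc,
                "w": cfg.w, "photons": float(model.sum() - cfg.B * cfg.s**2),
            }
        )
    return stack, pd.DataFrame(rows)


def simulate_tcspc(cfg: TcspcSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Poisson-noised reconvolved decay histograms plus a truth table.

    Returns ``(stack, truth)``: an (n_histograms, N) integer count stack
    and a DataFrame with the generating (A, tau) per histogram.
    """
    model = decay_model(cfg.truth, cfg.irf, cfg.ctx)
    stack = np.empty((cfg.n_histograms, cfg.ctx.N), dtype=np.int64)
    for i in range(cfg.n_histograms):
        rng = _rng(cfg.seed, i)
        stack[i] = rng.poisson(model)
    truth = pd.DataFrame(
        {
            "index": np.arange(cfg.n_histograms),
            "A": cfg.truth.A,
            "tau": cfg.truth.tau,
        }
    )
    return stack, truth


def simulate_flim_image(
    rows: int,
    cols: int,
    region_map: np.ndarray,
    region_params: dict[int, DecayParams],
    ctx: TimingContext,
    irf: IrfSpec,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic FLIM stack (rows, cols, N) from a per-pixel region label map.

    ``region_map`` is an integer (rows, cols) label image; every label must
    have an entry in ``region_params`` giving that region's generating
    (A, tau).  Each pixel's histogram is an independent Poisson draw from
    its region's reconvolution model, with a per-pixel substream derived
    from (seed, row, col).
    """
    region_map = np.asarray(region_map)
    if region_map.shape != (rows, cols):
        raise ValueError("region_map shape must be (rows, cols)")
    labels = np.unique(region_map)
    missing = [int(l) for l in labels if int(l) not in region_params]
    if missing:
        raise ValueError(f"region_map labels without parameters: {missing}")
    models = {
        int(l): decay_model(region_params[int(l)], irf, ctx) for l in labels
    }
    stack = np.empty((rows, cols, ctx.N), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            rng = _rng(seed, r, c)
            stack[r, c] = rng.poisson(models[int(region_map[r, c])])
    return stack
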