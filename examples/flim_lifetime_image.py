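"""Build a lifetime image from a synthetic two-region FLIM stack.

Simulates a 16x16-pixel TCSPC stack whose left half decays with tau = 2 ns
and right half with tau = 4 ns (600 photons/pixel, 64 bins over a 12.5 ns
laser period, 100 ps Gaussian IRF), then runs the threshold-masked
per-pixel reconvolution fit and prints the recovered regional lifetimes.
"""

import numpy as np

from parafit import (
    DecayParams,
    TimingContext,
    gaussian_irf,
    lifetime_image,
    simulate_flim_image,
)

ctx = TimingContext(T=12.5, N=64)
irf = gaussian_irf(ctx, t0=1.0, fwhm=0.1)
region = np.zeros((16, 16), dtype=int)
region[:, 8:] = 1
params = {0: DecayParams(A=600.0, tau=2.0), 1: DecayParams(A=600.0, tau=4.0)}
stack = simulate_flim_image(16, 16, region, params, ctx, irf, seed=3)

tau_map, A_map, intensity, mask, n_fitted = lifetime_image(
    stack, irf, threshold=400.0, ctx=ctx
)

print(f"fitted {n_fitted}/{mask.size} pixels above the 400-count threshold")
print(f"left half : median tau = {np.nanmedian(tau_map[region == 0]):.3f} ns"
      "  (truth 2.0)")
print(f"right half: median tau = {np.nanmedian(tau_map[region == 1]):.3f} ns"
      "  (truth 4.0)")
print("Median fitted lifetimes should sit within a few percent of the")
print("generating values; masked (dim) pixels would appear as NaN.")
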