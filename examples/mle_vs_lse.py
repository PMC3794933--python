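"""Why fit photon counts with the Poisson MLE instead of least squares.

Simulates 500 dim spots (~100 signal photons) and localizes them twice:
once with the Poisson-MLE residual transform and once with plain least
squares.  At low counts the MLE weighting of the shot noise buys a
measurably tighter localization scatter.
"""

import numpy as np

from parafit import SpotSimConfig, amplitude_for_photons, simulate_spots
from parafit.gauss2d import fit_spot_stack

cfg = SpotSimConfig(
    n_images=500, s=7, B=2.0, A=amplitude_for_photons(100.0, 1.0), w=1.0,
    seed=2,
)
stack, truth = simulate_spots(cfg)

stds = {}
for estimator in ("mle", "lse"):
    outs = fit_spot_stack(stack, w_init=1.0, fix_w=True, estimator=estimator)
    err = np.array(
        [o.params_hat.x_c - t for o, t in zip(outs, truth["x_c"])
         if o.result.success]
    )
    stds[estimator] = err.std(ddof=1)
    print(f"{estimator.upper()}: std(x_c error) = {stds[estimator]:.4f} px "
          f"({err.size} fits)")

print(f"MLE/LSE precision ratio = {stds['mle'] / stds['lse']:.3f}")
print("Values below 1 mean the Poisson-MLE localization is more precise")
print("than least squares on the same low-count images.")
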