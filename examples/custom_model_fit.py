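"""Fit a user-defined model with the Levenberg-Marquardt core.

Builds a noisy two-parameter exponential-decay data set, fits it with
`lm_fit`, and compares against the generating parameters.  The residual
function is all you need to supply: the solver handles Jacobians (forward
differences), scaling and the trust region.
"""

import numpy as np

from parafit import FitProblem, lm_fit

rng = np.random.default_rng(0)
t = np.linspace(0.0, 5.0, 50)
truth = (3.0, 1.3)  # amplitude, rate
y = truth[0] * np.exp(-truth[1] * t) + 0.02 * rng.standard_normal(t.size)


def residual(x):
    return x[0] * np.exp(-x[1] * t) - y


result = lm_fit(FitProblem(residual_fn=residual, x0=np.array([1.0, 1.0])))

# unweighted residuals: scale the curvature-based errors by the residual sigma
stderr = result.stderr * np.sqrt(result.cost / (t.size - 2))

print(f"true parameters      : amplitude={truth[0]}, rate={truth[1]}")
print(f"fitted parameters    : amplitude={result.x[0]:.4f}, "
      f"rate={result.x[1]:.4f}")
print(f"standard errors      : {stderr.round(4)}")
print(f"cost={result.cost:.5f}  iterations={result.n_iter}  "
      f"status={result.status}")
print("The fitted values should sit within a couple of standard errors of")
print("the generating ones; 'status' names the convergence test that fired.")
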