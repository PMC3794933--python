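"""Unit tests for the dense Levenberg-Marquardt core."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from parafit import (
    FitProblem,
    LMConfig,
    LMError,
    batch_fit,
    determine_damping,
    euclidean_norm,
    forward_difference_jacobian,
    lm_fit,
    qr_householder_pivot,
    solve_damped,
)


# ---------------------------------------------------------------- norms

@pytest.mark.parametrize(
    "v, expected",
    [
        ([0.0, 0.0, 0.0], 0.0),
        ([3.0, 4.0], 5.0),
        (np.ones(200), math.sqrt(sum(1.0 for _ in range(200)))),
    ],
)
def test_euclidean_norm_examples(v, expected):
    assert euclidean_norm(np.asarray(v)) == pytest.approx(expected, rel=1e-12)


def test_euclidean_norm_overflow_safe():
    big = 0.5 * np.finfo(np.float64).max
    out = euclidean_norm(np.array([big, big]))
    assert np.isfinite(out)
    assert out == pytest.approx(math.sqrt(2.0) * big, rel=1e-12)


def test_euclidean_norm_rejects_non_finite():
    with pytest.raises(LMError):
        euclidean_norm(np.array([1.0, np.nan]))


@given(st.lists(st.floats(-1e100, 1e100), min_size=1, max_size=30))
def test_euclidean_norm_matches_reference(values):
    v = np.asarray(values)
    # chained math.hypot is an independent overflow/underflow-safe oracle
    ref = 0.0
    for x in values:
        ref = math.hypot(ref, x)
    assert euclidean_norm(v) == pytest.approx(ref, rel=1e-12, abs=0.0)


# ------------------------------------------------------------- jacobian

def test_fd_jacobian_identity():
    cfg = LMConfig()
    x = np.array([0.3, -2.0, 5.0])
    J = forward_difference_jacobian(lambda z: z.copy(), x, x.copy(), cfg)
    assert np.allclose(J, np.eye(3), atol=1e-7)


def test_fd_jacobian_quadratic_one_sided_bias():
    h = 1e-6
    cfg = LMConfig(fd_step_scale=h)
    J = forward_difference_jacobian(
        lambda z: z**2, np.array([1.0]), np.array([1.0]), cfg
    )
    # Taylor: (f(x+h)-f(x))/h = 2x + h
    assert J[0, 0] == pytest.approx(2.0 + h, abs=1e-9)


def test_fd_jacobian_linear_is_exact(rng):
    M = rng.standard_normal((8, 2))
    y = rng.standard_normal(8)
    x = rng.standard_normal(2)
    cfg = LMConfig()
    J = forward_difference_jacobian(lambda z: M @ z - y, x, M @ x - y, cfg)
    assert np.allclose(J, M, atol=1e-6)


def test_fd_jacobian_skips_fixed_columns():
    cfg = LMConfig()
    x = np.array([1.0, 2.0, 3.0])
    J = forward_difference_jacobian(
        lambda z: z.copy(), x, x.copy(), cfg,
        fixed_mask=np.array([False, True, False]),
    )
    assert J.shape == (3, 2)


def test_fd_jacobian_names_offending_parameter():
    def bad(z):
        if z[1] > 2.0:
            return np.array([np.nan, 0.0])
        return z.copy()

    with pytest.raises(LMError, match="index 1"):
        forward_difference_jacobian(
            bad, np.array([1.0, 2.0]), np.array([1.0, 2.0]), LMConfig()
        )


# ------------------------------------------------------------------ QR

def test_qr_identity():
    q = qr_householder_pivot(np.eye(3))
    assert np.allclose(np.abs(q.R), np.eye(3), atol=1e-14)
    assert sorted(q.perm.tolist()) == [0, 1, 2]


def test_qr_single_column_norm_preserved():
    q = qr_householder_pivot(np.array([[3.0], [4.0]]))
    assert abs(q.rdiag[0]) == pytest.approx(5.0, rel=1e-14)


def test_qr_duplicate_columns_rank_revealing(rng):
    col = rng.standard_normal(10)
    J = np.column_stack([col, col])
    q = qr_householder_pivot(J)
    assert abs(q.rdiag[1]) <= 1e-10 * abs(q.rdiag[0])


def test_qr_reconstruction_and_orthogonality(rng):
    for _ in range(30):
        J = rng.standard_normal((64, 5))
        q = qr_householder_pivot(J)
        Q = q.q_thin()
        assert (
            np.linalg.norm(J[:, q.perm] - Q @ q.R)
            <= 1e-10 * np.linalg.norm(J)
        )
        assert np.linalg.norm(Q.T @ Q - np.eye(5)) <= 1e-10
        # pivoting: |R| diagonal non-increasing
        d = np.abs(q.rdiag)
        assert np.all(d[:-1] >= d[1:] - 1e-12)


# ---------------------------------------------------------- damped solve

def test_solve_damped_identity_closed_form():
    q = qr_householder_pivot(np.eye(2))
    qtf = q.apply_qt(np.array([1.0, 1.0]))
    d0 = solve_damped(q, qtf, np.ones(2), 0.0)
    assert np.allclose(d0, [-1.0, -1.0], atol=1e-14)
    d1 = solve_damped(q, qtf, np.ones(2), 1.0)
    assert np.allclose(d1, [-0.5, -0.5], atol=1e-14)


def test_solve_damped_matches_dense_oracle(rng):
    for _ in range(30):
        m = int(rng.integers(6, 65))
        n = int(rng.integers(1, 7))
        J = rng.standard_normal((m, n))
        f = rng.standard_normal(m)
        D = rng.uniform(0.5, 2.0, n)
        q = qr_householder_pivot(J)
        qtf = q.apply_qt(f)
        for lam in (0.0, 0.1, 1.0, 10.0):
            delta = solve_damped(q, qtf, D, lam)
            ref = np.linalg.solve(
                J.T @ J + lam * np.diag(D**2), -J.T @ f
            )
            assert np.linalg.norm(delta - ref) <= 1e-7 * max(
                np.linalg.norm(ref), 1e-30
            )


def test_solve_damped_step_norm_monotone_in_lambda(rng):
    J = rng.standard_normal((20, 4))
    f = rng.standard_normal(20)
    D = rng.uniform(0.5, 2.0, 4)
    q = qr_householder_pivot(J)
    qtf = q.apply_qt(f)
    norms = [
        euclidean_norm(D * solve_damped(q, qtf, D, lam))
        for lam in (0.0, 1.0, 10.0, 100.0)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_solve_damped_rank_deficient_zero_lambda(rng):
    col = rng.standard_normal(12)
    J = np.column_stack([col, col])
    f = rng.standard_normal(12)
    q = qr_householder_pivot(J)
    delta = solve_damped(q, q.apply_qt(f), np.ones(2), 0.0)
    # dependent component zeroed in the pivoted basis; step stays finite
    # and solves the least-squares problem restricted to the leading column
    assert np.all(np.isfinite(delta))
    resid_grad = J.T @ (J @ delta + f)
    assert np.linalg.norm(resid_grad) <= 1e-8 * np.linalg.norm(J.T @ f)


def test_solve_damped_linearity_in_f(rng):
    J = rng.standard_normal((15, 3))
    f = rng.standard_normal(15)
    D = np.ones(3)
    q = qr_householder_pivot(J)
    d1 = solve_damped(q, q.apply_qt(f), D, 2.0)
    d3 = solve_damped(q, q.apply_qt(3.0 * f), D, 2.0)
    assert np.allclose(d3, 3.0 * d1, rtol=1e-10)


# -------------------------------------------------------------- damping

def test_determine_damping_accepts_gauss_newton_inside_radius(rng):
    J = rng.standard_normal((20, 3))
    f = 1e-6 * rng.standard_normal(20)
    q = qr_householder_pivot(J)
    qtf = q.apply_qt(f)
    lam, step, status = determine_damping(q, qtf, np.ones(3), 1e6)
    assert lam == 0.0
    assert status == "ok"


def _bisect_lambda(J, f, D, target, lo=0.0, hi=1e12):
    """Independent oracle: bisection on lam for ||D delta(lam)|| = target."""
    def norm_at(lam):
        delta = np.linalg.solve(J.T @ J + lam * np.diag(D**2), -J.T @ f)
        return np.linalg.norm(D * delta)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if norm_at(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_determine_damping_matches_trust_radius(rng):
    for _ in range(5):
        J = rng.standard_normal((30, 4))
        f = rng.standard_normal(30)
        D = rng.uniform(0.5, 2.0, 4)
        q = qr_householder_pivot(J)
        qtf = q.apply_qt(f)
        gn = solve_damped(q, qtf, D, 0.0)
        target = 1e-3 * euclidean_norm(D * gn)
        lam, step, status = determine_damping(q, qtf, D, target)
        assert lam > 0
        got = euclidean_norm(D * step)
        assert 0.9 * target <= got <= 1.1 * target
        # cross-check against the bisection oracle
        lam_ref = _bisect_lambda(J, f, D, target)
        ref = np.linalg.solve(J.T @ J + lam_ref * np.diag(D**2), -J.T @ f)
        assert np.linalg.norm(D * ref) == pytest.approx(target, rel=1e-3)
        assert np.linalg.norm(D * step) == pytest.approx(
            np.linalg.norm(D * ref), rel=0.25
        )


# ---------------------------------------------------------------- lm_fit

def test_lm_fit_linear_matches_closed_form(rng):
    M = rng.standard_normal((20, 3))
    y = rng.standard_normal(20)
    res = lm_fit(FitProblem(residual_fn=lambda x: M @ x - y, x0=np.zeros(3)))
    ref = np.linalg.lstsq(M, y, rcond=None)[0]
    assert np.linalg.norm(res.x - ref) <= 1e-8
    assert res.n_iter <= 3
    assert res.success


def test_lm_fit_exact_data_recovery(rng):
    t = np.linspace(0.0, 4.0, 30)
    truth = np.array([2.5, 0.8])
    y = truth[0] * np.exp(-truth[1] * t)

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - y

    res = lm_fit(FitProblem(residual_fn=resid, x0=truth * 1.1))
    assert res.success
    assert np.allclose(res.x, truth, rtol=1e-6)
    assert res.status == "ftol" or res.cost <= 1e-20


def test_lm_fit_curved_valley():
    def resid(x):
        return np.array([10.0 * (x[1] - x[0] ** 2), 1.0 - x[0]])

    res = lm_fit(FitProblem(residual_fn=resid, x0=np.array([-1.2, 1.0])))
    assert np.allclose(res.x, [1.0, 1.0], atol=1e-8)
    assert res.cost <= 1e-16


def test_lm_fit_accepted_costs_strictly_decrease():
    t = np.linspace(0.0, 4.0, 25)
    y = 3.0 * np.exp(-1.1 * t) + 0.3

    def resid(x):
        return x[0] * np.exp(-x[1] * t) + x[2] - y

    problem = FitProblem(residual_fn=resid, x0=np.array([1.0, 0.3, 0.0]))
    costs = []
    for k in range(1, 8):
        res = lm_fit(problem, LMConfig(max_iter=k))
        costs.append(res.cost)
    converged = [c for c in costs if c > 1e-20]
    assert all(a > b or a == b == costs[-1]
               for a, b in zip(converged, converged[1:]))
    assert costs[-1] < costs[0]


def test_lm_fit_scaling_invariance(rng):
    """Rescaling a parameter's units must not change the converged cost."""
    t = np.linspace(0.0, 4.0, 40)
    y = 2.0 * np.exp(-0.7 * t) + 0.05 * rng.standard_normal(40)

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - y

    def resid_scaled(x):  # x[1] now expressed in "milli-units"
        return x[0] * np.exp(-1e-3 * x[1] * t) - y

    r1 = lm_fit(FitProblem(residual_fn=resid, x0=np.array([1.0, 1.0])))
    r2 = lm_fit(
        FitProblem(residual_fn=resid_scaled, x0=np.array([1.0, 1000.0]))
    )
    assert r1.success and r2.success
    assert abs(r1.cost - r2.cost) <= 1e-6 * max(r1.cost, 1e-30)


def test_lm_fit_fixed_parameter_stays_fixed():
    t = np.linspace(0.0, 4.0, 20)
    y = 2.0 * np.exp(-0.9 * t)

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - y

    res = lm_fit(
        FitProblem(
            residual_fn=resid,
            x0=np.array([1.5, 0.9]),
            fixed_mask=np.array([False, True]),
        )
    )
    assert res.x[1] == 0.9
    assert res.x[0] == pytest.approx(2.0, rel=1e-6)


def test_lm_fit_bounds_respected():
    y = np.full(10, -1.0)
    res = lm_fit(
        FitProblem(
            residual_fn=lambda x: np.full(10, x[0]) - y,
            x0=np.array([2.0]),
            lower=np.array([0.5]),
        )
    )
    assert res.x[0] == pytest.approx(0.5)


def test_lm_fit_non_finite_x0_is_failure_not_exception():
    res = lm_fit(
        FitProblem(residual_fn=lambda x: x.copy(), x0=np.array([np.nan]))
    )
    assert res.status == "failure"


def test_lm_fit_underdetermined_raises():
    with pytest.raises(LMError):
        lm_fit(
            FitProblem(
                residual_fn=lambda x: np.array([x[0] + x[1]]),
                x0=np.zeros(2),
            )
        )


def test_lm_fit_matches_scipy_reference(rng):
    """Independent cross-check against scipy's LM on a nonlinear problem."""
    from scipy.optimize import least_squares

    t = np.linspace(0.0, 5.0, 40)
    y = 3.0 * np.exp(-1.3 * t) + 0.01 * rng.standard_normal(40)

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - y

    mine = lm_fit(FitProblem(residual_fn=resid, x0=np.array([1.0, 1.0])))
    ref = least_squares(resid, [1.0, 1.0], method="lm")
    assert np.allclose(mine.x, ref.x, rtol=1e-6)


# -------------------------------------------------------------- batching

def _make_problems(rng, n):
    problems = []
    for _ in range(n):
        M = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        problems.append(
            FitProblem(residual_fn=lambda x, M=M, y=y: M @ x - y,
                       x0=np.zeros(2))
        )
    return problems


def test_batch_identical_problems_identical_results(rng):
    M = rng.standard_normal((12, 2))
    y = rng.standard_normal(12)
    problems = [
        FitProblem(residual_fn=lambda x: M @ x - y, x0=np.zeros(2))
        for _ in range(20)
    ]
    results = batch_fit(problems)
    for r in results[1:]:
        assert np.array_equal(r.x, results[0].x)
        assert r.cost == results[0].cost


def test_batch_bitwise_identical_across_workers(rng):
    problems = _make_problems(rng, 30)
    seq = batch_fit(problems, workers=1)
    par = batch_fit(problems, workers=4)
    loop = [lm_fit(p) for p in problems]
    for a, b, c in zip(seq, par, loop):
        assert np.array_equal(a.x, b.x) and np.array_equal(a.x, c.x)
        assert a.cost == b.cost == c.cost
        assert a.n_iter == b.n_iter == c.n_iter


def test_batch_isolates_failures(rng):
    problems = _make_problems(rng, 10)
    problems[3] = FitProblem(
        residual_fn=lambda x: x.copy(), x0=np.array([np.nan, np.nan])
    )
    results = batch_fit(problems)
    assert results[3].status == "failure"
    good = [r for i, r in enumerate(results) if i != 3]
    assert all(r.success for r in good)


def test_batch_empty_input():
    assert batch_fit([]) == []
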