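"""Dense Levenberg-Marquardt minimization for small batched problems.

This module is a self-contained, Minpack-style trust-region
Levenberg-Marquardt solver for dense problems with a handful of parameters
and up to a few thousand data points.  It is the sequential re-expression of
a one-fit-per-compute-block design: every fit is fully independent, so a
batch of fits is exactly ``map(lm_fit, problems)`` and the batch driver
guarantees bitwise-identical results regardless of how many workers run it.

The algorithmic skeleton follows the classic Minpack ``lmdif`` family:

* Householder QR factorization of the Jacobian with column pivoting
  (:func:`qr_householder_pivot`),
* the damped linear subproblem ``(J^T J + lam * D^T D) delta = -J^T f``
  solved through the factored augmented system with Givens rotations
  (:func:`solve_damped`), never by forming or inverting ``J^T J``,
* a safeguarded Newton iteration on the damping factor that matches the
  scaled step length to the trust radius (:func:`determine_damping`),
* a gain-ratio trust-region update (shrink x0.5 below 1/4, grow x2 above
  3/4) in :func:`lm_fit`.

Jacobians default to one-sided forward differences; an analytic Jacobian
callback is accepted.  Per-parameter diagonal scaling ``D`` is initialized
from the square root of the diagonal of ``J^T J`` (the column norms) and
updated to the running maximum of column norms, which makes convergence
invariant to the units the parameters are expressed in.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "LMError",
    "FitProblem",
    "LMConfig",
    "QRFactors",
    "FitResult",
    "euclidean_norm",
    "forward_difference_jacobian",
    "qr_householder_pivot",
    "solve_damped",
    "determine_damping",
    "lm_fit",
    "batch_fit",
]

_EPS = float(np.finfo(np.float64).eps)
_DWARF = float(np.finfo(np.float64).tiny)


class LMError(ValueError):
    """Structural error in a fit problem (bad shapes, invalid inputs)."""


@dataclass
class LMConfig:
    """Solver controls.

    Parameters
    ----------
    ftol, xtol, gtol:
        Relative convergence tolerances on the cost, the step and the scaled
        gradient (dimensionless, all > 0).
    max_iter:
        Cap on accepted iterations (Jacobian evaluations).
    fd_step_scale:
        Relative forward-difference step; the probe step for parameter ``j``
        is ``fd_step_scale * max(|x_j|, 1)``.
    trust_factor:
        Initial trust radius is ``trust_factor * ||D x0||`` (or
        ``trust_factor`` when that norm is zero).
    scaling_mode:
        ``"auto"`` derives D from Jacobian column norms (recommended);
        ``"fixed"`` uses ``fixed_scale`` (or all ones).
    """

    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_iter: int = 200
    fd_step_scale: float = math.sqrt(_EPS)
    trust_factor: float = 100.0
    scaling_mode: str = "auto"
    fixed_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if min(self.ftol, self.xtol, self.gtol) <= 0:
            raise LMError("tolerances must be > 0")
        if self.max_iter < 1:
            raise LMError("max_iter must be >= 1")
        if self.scaling_mode not in ("auto", "fixed"):
            raise LMError(f"unknown scaling_mode {self.scaling_mode!r}")


@dataclass
class FitProblem:
    """One least-squares problem: residual function, data size and start point.

    ``residual_fn`` maps the full parameter vector (length n, including fixed
    entries) to the residual vector (length m).  It must be deterministic.
    ``fixed_mask`` marks parameters excluded from the solve; ``lower`` and
    ``upper`` are optional per-parameter bounds enforced by clamping proposed
    steps.  ``jac_fn``, if given, returns the m x n Jacobian of the residual
    at x (columns for fixed parameters are ignored).
    """

    residual_fn: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray
    m: Optional[int] = None
    fixed_mask: Optional[np.ndarray] = None
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    jac_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.float64)
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(self.x0.size, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.size != self.x0.size:
                raise LMError("fixed_mask length must match x0")
        for name in ("lower", "upper"):
            b = getattr(self, name)
            if b is not None:
                b = np.asarray(b, dtype=np.float64)
                if b.size != self.x0.size:
                    raise LMError(f"{name} length must match x0")
                setattr(self, name, b)

    @property
    def n_free(self) -> int:
        return int((~self.fixed_mask).sum())


@dataclass
class FitResult:
    """Outcome of one LM fit.

    ``cost`` is the final sum of squared residuals ``||f||^2``; ``status`` is
    the termination reason (``ftol``/``xtol``/``gtol``/``max_iter``/
    ``failure``); ``stderr`` holds per-free-parameter standard errors from
    ``sqrt(diag((J^T J)^{-1}))`` at the solution when available (NaN for
    fixed parameters).  These are exact standard errors when the residuals
    are variance-standardized (as the Poisson-MLE transform makes them);
    for unweighted residuals multiply by ``sqrt(cost / (m - n_free))``.
    """

    x: np.ndarray
    cost: float
    n_iter: int
    n_feval: int
    status: str
    message: str = ""
    stderr: Optional[np.ndarray] = None

    @property
    def success(self) -> bool:
        return self.status in ("ftol", "xtol", "gtol")


def euclidean_norm(v: np.ndarray) -> float:
    """Overflow-safe Euclidean norm ``||v||_2``.

    Scales by the largest magnitude before squaring, so entries near the
    floating-point maximum do not overflow.  Raises :class:`LMError` on
    non-finite entries (the signal of an invalid residual vector).
    """
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size == 0:
        return 0.0
    if not np.all(np.isfinite(v)):
        raise LMError("non-finite entry in vector")
    vmax = float(np.max(np.abs(v)))
    if vmax == 0.0:
        return 0.0
    scaled = v / vmax
    return vmax * math.sqrt(float(np.dot(scaled, scaled)))


def forward_difference_jacobian(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    f0: np.ndarray,
    cfg: LMConfig,
    fixed_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One-sided forward-difference Jacobian, columns for free parameters only.

    ``J[i, j] ~ (f(x + h_j e_j) - f0_i) / h_j`` with
    ``h_j = fd_step_scale * max(|x_j|, 1)``.
    """
    x = np.asarray(x, dtype=np.float64)
    f0 = np.asarray(f0, dtype=np.float64)
    if fixed_mask is None:
        fixed_mask = np.zeros(x.size, dtype=bool)
    free_idx = np.flatnonzero(~fixed_mask)
    J = np.empty((f0.size, free_idx.size), dtype=np.float64)
    for col, j in enumerate(free_idx):
        h = cfg.fd_step_scale * max(abs(float(x[j])), 1.0)
        xp = x.copy()
        xp[j] += h
        fp = np.asarray(residual_fn(xp), dtype=np.float64)
        if not np.all(np.isfinite(fp)):
            raise LMError(
                f"residual function returned non-finite values while probing "
                f"parameter index {j}"
            )
        J[:, col] = (fp - f0) / h
    return J


@dataclass
class QRFactors:
    """Pivoted Householder QR factorization ``J P = Q R``.

    ``qr`` stores the Householder vectors in and below the diagonal and the
    strict upper triangle of R above it (Minpack layout); ``rdiag`` is the
    diagonal of R, ``perm`` the column permutation (``J[:, perm] = Q R``) and
    ``acnorm`` the original column norms of J (in original column order).
    """

    qr: np.ndarray
    rdiag: np.ndarray
    perm: np.ndarray
    acnorm: np.ndarray

    @property
    def m(self) -> int:
        return self.qr.shape[0]

    @property
    def n(self) -> int:
        return self.qr.shape[1]

    @property
    def R(self) -> np.ndarray:
        """Upper-triangular factor as a dense (n, n) array."""
        n = self.n
        r = np.triu(self.qr[:n, :n], k=1)
        np.fill_diagonal(r, self.rdiag)
        return r

    def apply_qt(self, v: np.ndarray) -> np.ndarray:
        """Return ``Q^T v`` (length m)."""
        v = np.array(v, dtype=np.float64)
        for j in range(self.n):
            w = self.qr[j:, j]
            if self.qr[j, j] != 0.0:
                v[j:] -= (np.dot(w, v[j:]) / self.qr[j, j]) * w
        return v

    def apply_q(self, v: np.ndarray) -> np.ndarray:
        """Return ``Q v`` (length m)."""
        v = np.array(v, dtype=np.float64)
        for j in range(self.n - 1, -1, -1):
            w = self.qr[j:, j]
            if self.qr[j, j] != 0.0:
                v[j:] -= (np.dot(w, v[j:]) / self.qr[j, j]) * w
        return v

    def q_thin(self) -> np.ndarray:
        """Explicit thin orthogonal factor (m, n), mainly for testing."""
        q = np.empty((self.m, self.n), dtype=np.float64)
        for i in range(self.n):
            e = np.zeros(self.m)
            e[i] = 1.0
            q[:, i] = self.apply_q(e)
        return q


def qr_householder_pivot(J: np.ndarray) -> QRFactors:
    """Householder QR with column pivoting on the largest remaining norm.

    At each stage the column of maximal remaining norm is moved to the front
    (first index wins ties), so ``|rdiag|`` is non-increasing and rank
    deficiency shows up as a (near-)zero trailing diagonal of R.
    """
    a = np.array(J, dtype=np.float64)
    if a.ndim != 2:
        raise LMError("J must be 2-D")
    m, n = a.shape
    if m < n:
        raise LMError(f"J must have m >= n (got {m} x {n})")
    acnorm = np.array([euclidean_norm(a[:, j]) for j in range(n)])
    rdiag = acnorm.copy()
    wa = rdiag.copy()
    perm = np.arange(n)

    for j in range(n):
        # pivot: column of maximal remaining norm (first index on ties)
        kmax = j + int(np.argmax(rdiag[j:]))
        if kmax != j:
            a[:, [j, kmax]] = a[:, [kmax, j]]
            rdiag[kmax] = rdiag[j]
            wa[kmax] = wa[j]
            perm[[j, kmax]] = perm[[kmax, j]]

        ajnorm = euclidean_norm(a[j:, j])
        if ajnorm == 0.0:
            rdiag[j] = 0.0
            continue
        if a[j, j] < 0.0:
            ajnorm = -ajnorm
        a[j:, j] /= ajnorm
        a[j, j] += 1.0

        if j + 1 < n:
            w = a[j:, j]
            t = (w @ a[j:, j + 1 :]) / a[j, j]
            a[j:, j + 1 :] -= np.outer(w, t)
            # downdate pivot norms; recompute when cancellation degrades them
            for k in range(j + 1, n):
                if rdiag[k] == 0.0:
                    continue
                temp = a[j, k] / rdiag[k]
                rdiag[k] *= math.sqrt(max(0.0, 1.0 - temp * temp))
                if 0.05 * (rdiag[k] / wa[k]) ** 2 <= _EPS:
                    rdiag[k] = euclidean_norm(a[j + 1 :, k])
                    wa[k] = rdiag[k]
        rdiag[j] = -ajnorm

    return QRFactors(qr=a, rdiag=rdiag, perm=perm, acnorm=acnorm)


def _singular_threshold(rdiag: np.ndarray, m: int) -> float:
    n = rdiag.size
    return max(m, n) * _EPS * (abs(float(rdiag[0])) if n else 0.0)


def _qrsolv(
    R: np.ndarray,
    perm: np.ndarray,
    diag: np.ndarray,
    qtb: np.ndarray,
    lam: float,
    m_rows: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the damped subproblem in the pivoted basis.

    Minimizes ``|| [R; sqrt(lam) D_pi] z - [qtb; 0] ||`` by eliminating the
    appended diagonal rows with Givens rotations, i.e. solves
    ``(R^T R + lam D_pi^T D_pi) z = R^T qtb`` through the factored augmented
    system.  ``diag`` is in original parameter order; ``perm`` maps pivoted
    to original indices.  Returns ``(z, S)`` with S the upper-triangular
    factor satisfying ``S^T S = R^T R + lam D_pi^2``.
    """
    n = R.shape[0]
    S = np.triu(np.array(R, dtype=np.float64))
    z = np.array(qtb[:n], dtype=np.float64)

    if lam > 0.0:
        sq = math.sqrt(lam)
        for j in range(n):
            dpj = sq * float(diag[perm[j]])
            if dpj == 0.0:
                continue
            # appended row: single entry dpj at column j, rhs 0; rotate it
            # through rows j..n-1, where it picks up fill to the right
            row = np.zeros(n)
            row[j] = dpj
            rhs = 0.0
            for k in range(j, n):
                if row[k] == 0.0:
                    continue
                skk = S[k, k]
                rk = row[k]
                if abs(skk) < abs(rk):
                    cot = skk / rk
                    s = 1.0 / math.sqrt(1.0 + cot * cot)
                    c = s * cot
                else:
                    tan = rk / skk
                    c = 1.0 / math.sqrt(1.0 + tan * tan)
                    s = c * tan
                srow = S[k, k:].copy()
                arow = row[k:].copy()
                S[k, k:] = c * srow + s * arow
                row[k:] = -s * srow + c * arow
                row[k] = 0.0
                t = c * z[k] + s * rhs
                rhs = -s * z[k] + c * rhs
                z[k] = t

    # back substitution with rank handling: treat near-zero diagonal entries
    # (relative to the leading one) as exactly singular and zero those
    # components — the minimum-norm-flavoured solution in the pivoted basis.
    x = np.zeros(n)
    sd = np.abs(np.diag(S))
    tol = _singular_threshold(np.diag(S), m_rows)
    nsing = n
    for j in range(n):
        if sd[j] <= tol:
            nsing = j
            break
    for j in range(nsing - 1, -1, -1):
        x[j] = (z[j] - float(S[j, j + 1 : nsing] @ x[j + 1 : nsing])) / S[j, j]
    return x, S


def solve_damped(
    qr: QRFactors, qtf: np.ndarray, D: np.ndarray, lam: float
) -> np.ndarray:
    """Step ``delta`` solving ``(J^T J + lam D^T D) delta = -J^T f``.

    ``qtf`` is ``Q^T f`` (at least the first n entries are used); ``D`` is
    the diagonal scaling vector in original parameter order.  The system is
    solved through the factored augmented least-squares form, never by
    forming ``J^T J``.  With ``lam = 0`` and a rank-deficient J the
    rank-revealing pivoted factorization yields the solution with dependent
    components zeroed (no error).
    """
    if lam < 0.0:
        raise LMError("lam must be >= 0")
    D = np.asarray(D, dtype=np.float64)
    if np.any(D <= 0.0):
        raise LMError("scaling D must be > 0")
    n = qr.n
    b = -np.asarray(qtf, dtype=np.float64)[:n]
    z, _ = _qrsolv(qr.R, qr.perm, D, b, lam, qr.m)
    delta = np.zeros(n)
    delta[qr.perm] = z
    return delta


def determine_damping(
    qr: QRFactors,
    qtf: np.ndarray,
    D: np.ndarray,
    trust_radius: float,
    lam0: float = 0.0,
) -> tuple[float, np.ndarray, str]:
    """Find the damping factor matching the scaled step to the trust radius.

    Safeguarded Newton iteration on ``lam`` (the classic Minpack ``lmpar``
    scheme): if the undamped Gauss-Newton step already satisfies
    ``||D delta|| <= trust_radius`` return ``lam = 0`` and that step;
    otherwise find ``lam > 0`` such that ``||D delta(lam)||`` is within 10%
    of the trust radius.  Returns ``(lam, delta, status)`` where status is
    ``"ok"`` or ``"bracket_limit"`` if the iteration cap (10) was reached
    (the last bracketed ``lam`` is returned).
    """
    if trust_radius <= 0.0:
        raise LMError("trust_radius must be > 0")
    D = np.asarray(D, dtype=np.float64)
    n = qr.n
    R = qr.R
    perm = qr.perm
    b = -np.asarray(qtf, dtype=np.float64)[:n]

    # Gauss-Newton step (lam = 0), rank-deficient trailing part zeroed
    z, _ = _qrsolv(R, perm, D, b, 0.0, qr.m)
    x = np.zeros(n)
    x[perm] = z
    dxnorm = euclidean_norm(D * x)
    fp = dxnorm - trust_radius
    if fp <= 0.1 * trust_radius:
        return 0.0, x, "ok"

    tol = _singular_threshold(np.diag(R), qr.m)
    full_rank = bool(np.all(np.abs(qr.rdiag) > tol))

    # lower bound on lam from the Newton step of phi at 0 (full rank only)
    parl = 0.0
    if full_rank:
        wa = (D * x)[perm] * D[perm] / dxnorm
        # forward solve R^T y = wa
        y = np.zeros(n)
        for j in range(n):
            y[j] = (wa[j] - float(R[:j, j] @ y[:j])) / R[j, j]
        temp = euclidean_norm(y)
        parl = ((fp / trust_radius) / temp) / temp

    # upper bound from the gradient norm
    wg = (R.T @ b) / np.where(D[perm] > 0, D[perm], 1.0)
    gnorm = euclidean_norm(wg)
    paru = gnorm / trust_radius
    if paru == 0.0:
        paru = _DWARF / min(trust_radius, 0.1)

    par = min(max(lam0, parl), paru)
    if par == 0.0:
        par = gnorm / dxnorm

    status = "bracket_limit"
    for _ in range(10):
        if par == 0.0:
            par = max(_DWARF, 0.001 * paru)
        z, S = _qrsolv(R, perm, D, b, par, qr.m)
        x = np.zeros(n)
        x[perm] = z
        dxnorm = euclidean_norm(D * x)
        fp_old = fp
        fp = dxnorm - trust_radius
        if abs(fp) <= 0.1 * trust_radius or (
            parl == 0.0 and fp <= fp_old and fp_old < 0.0
        ):
            status = "ok"
            break
        # Newton correction on lam using the S factor
        wa = (D * x)[perm] * D[perm] / dxnorm
        y = np.zeros(n)
        for j in range(n):
            y[j] = (wa[j] - float(S[:j, j] @ y[:j])) / S[j, j]
        temp = euclidean_norm(y)
        parc = ((fp / trust_radius) / temp) / temp
        if fp > 0.0:
            parl = max(parl, par)
        else:
            paru = min(paru, par)
        par = max(parl, par + parc)
    return par, x, status


def _estimate_stderr(J: np.ndarray) -> Optional[np.ndarray]:
    """sqrt(diag((J^T J)^{-1})) via the SVD; None when J is rank deficient."""
    try:
        u, s, vt = np.linalg.svd(J, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical edge
        return None
    if s.size == 0 or s[-1] <= s[0] * 1e-12:
        return None
    cov_diag = ((vt.T / s) ** 2).sum(axis=1)
    return np.sqrt(cov_diag)


def lm_fit(problem: FitProblem, cfg: Optional[LMConfig] = None) -> FitResult:
    """Levenberg-Marquardt minimization of ``||residual_fn(x)||^2``.

    Iterates trust-region damped Gauss-Newton steps from ``problem.x0``;
    every accepted step strictly decreases the cost.  Terminates on relative
    cost change (``ftol``), relative step size (``xtol``), scaled gradient
    (``gtol``) or the iteration cap.  A non-finite residual at ``x0`` (or a
    non-finite ``x0``) yields an immediate ``failure`` status rather than an
    exception; structural errors (``m < n_free``) raise :class:`LMError`.
    """
    if cfg is None:
        cfg = LMConfig()
    x = np.array(problem.x0, dtype=np.float64)
    fixed = problem.fixed_mask
    free_idx = np.flatnonzero(~fixed)
    n_free = free_idx.size
    if n_free < 1:
        raise LMError("at least one free parameter required")

    def clamp(xv: np.ndarray) -> np.ndarray:
        if problem.lower is not None:
            xv = np.maximum(xv, problem.lower)
        if problem.upper is not None:
            xv = np.minimum(xv, problem.upper)
        return xv

    if not np.all(np.isfinite(x)):
        return FitResult(x=x, cost=np.inf, n_iter=0, n_feval=0,
                         status="failure", message="non-finite x0")
    n_feval = 1
    try:
        f = np.asarray(problem.residual_fn(x), dtype=np.float64).ravel()
        fnorm = euclidean_norm(f)
    except LMError as exc:
        return FitResult(x=x, cost=np.inf, n_iter=0, n_feval=n_feval,
                         status="failure", message=str(exc))
    if not np.all(np.isfinite(f)):
        return FitResult(x=x, cost=np.inf, n_iter=0, n_feval=n_feval,
                         status="failure", message="non-finite residual at x0")
    m = f.size
    if problem.m is not None and problem.m != m:
        raise LMError(f"declared m={problem.m} but residual has length {m}")
    if m < n_free:
        raise LMError(f"m={m} < n_free={n_free}: underdetermined problem")

    if cfg.scaling_mode == "fixed":
        diag = (np.ones(n_free) if cfg.fixed_scale is None
                else np.asarray(cfg.fixed_scale, dtype=np.float64)[free_idx])
        if np.any(diag <= 0):
            raise LMError("fixed_scale entries must be > 0")
    else:
        diag = np.ones(n_free)

    status = "max_iter"
    message = ""
    n_iter = 0
    delta_tr = 0.0
    xnorm = 0.0
    par = 0.0
    J = None

    for outer in range(cfg.max_iter):
        try:
            if problem.jac_fn is not None:
                Jfull = np.asarray(problem.jac_fn(x), dtype=np.float64)
                J = Jfull[:, free_idx]
                if not np.all(np.isfinite(J)):
                    raise LMError("non-finite analytic Jacobian")
            else:
                J = forward_difference_jacobian(
                    problem.residual_fn, x, f, cfg, fixed
                )
                n_feval += n_free
        except LMError as exc:
            status, message = "failure", str(exc)
            break

        qrf = qr_householder_pivot(J)
        acnorm = qrf.acnorm  # column norms, free-parameter order

        if outer == 0:
            if cfg.scaling_mode == "auto":
                diag = np.where(acnorm == 0.0, 1.0, acnorm)
            xnorm = euclidean_norm(diag * x[free_idx])
            delta_tr = cfg.trust_factor * xnorm
            if delta_tr == 0.0:
                delta_tr = cfg.trust_factor
        elif cfg.scaling_mode == "auto":
            diag = np.maximum(diag, acnorm)

        qtf = qrf.apply_qt(f)[: qrf.n]

        # scaled gradient test: J^T f in the pivoted basis is R^T qtf
        if fnorm != 0.0:
            rtqtf = qrf.R.T @ qtf
            denom = acnorm[qrf.perm] * fnorm
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(denom > 0, np.abs(rtqtf) / denom, 0.0)
            gnorm = float(np.max(g)) if g.size else 0.0
        else:
            gnorm = 0.0
        if gnorm <= cfg.gtol:
            status = "gtol"
            message = "scaled gradient below gtol"
            break

        done = False
        while True:
            par, step_p, _ = determine_damping(qrf, qtf, diag, delta_tr, par)
            x_trial = x.copy()
            x_trial[free_idx] = x[free_idx] + step_p
            x_trial = clamp(x_trial)
            step_eff = x_trial[free_idx] - x[free_idx]
            pnorm = euclidean_norm(diag * step_eff)
            if outer == 0:
                delta_tr = min(delta_tr, pnorm) if pnorm > 0 else delta_tr

            n_feval += 1
            f_trial = np.asarray(
                problem.residual_fn(x_trial), dtype=np.float64
            ).ravel()
            if np.all(np.isfinite(f_trial)):
                fnorm1 = euclidean_norm(f_trial)
            else:
                fnorm1 = np.inf

            # actual and predicted relative reductions (Minpack forms)
            if np.isfinite(fnorm1) and 0.1 * fnorm1 < fnorm:
                actred = 1.0 - (fnorm1 / fnorm) ** 2
            else:
                actred = -1.0
            wa3 = qrf.R @ step_eff[qrf.perm]
            temp1 = euclidean_norm(wa3) / fnorm if fnorm > 0 else 0.0
            temp2 = (math.sqrt(par) * pnorm) / fnorm if fnorm > 0 else 0.0
            prered = temp1 * temp1 + 2.0 * temp2 * temp2
            dirder = -(temp1 * temp1 + temp2 * temp2)
            ratio = actred / prered if prered > 0.0 else 0.0

            # trust-region update: shrink x0.5 below 1/4, grow x2 above 3/4
            if ratio <= 0.25:
                delta_tr = 0.5 * min(delta_tr, 10.0 * pnorm)
                par *= 2.0
            elif ratio >= 0.75 or par == 0.0:
                delta_tr = 2.0 * pnorm
                par *= 0.5

            accepted = ratio > 1e-4 and fnorm1 < fnorm
            if accepted:
                x = x_trial
                f = f_trial
                fnorm = fnorm1
                xnorm = euclidean_norm(diag * x[free_idx])
                n_iter += 1

            # convergence tests
            if (abs(actred) <= cfg.ftol and prered <= cfg.ftol
                    and ratio <= 2.0 and accepted):
                status, message, done = "ftol", "relative cost change", True
            if delta_tr <= cfg.xtol * xnorm:
                status, message, done = "xtol", "relative step size", True
            if pnorm == 0.0 and not accepted:
                status, message, done = "xtol", "step underflow", True
            if fnorm == 0.0:
                status, message, done = "ftol", "zero cost", True
            if done or accepted:
                break
            # rejected: trust radius has shrunk, retry the inner loop
            if delta_tr <= _DWARF:
                status, message, done = "xtol", "trust radius underflow", True
                break
        if done:
            break

    stderr_free = _estimate_stderr(J) if J is not None else None
    stderr = None
    if stderr_free is not None:
        stderr = np.full(x.size, np.nan)
        stderr[free_idx] = stderr_free
    return FitResult(
        x=x,
        cost=fnorm * fnorm,
        n_iter=n_iter,
        n_feval=n_feval,
        status=status,
        message=message,
        stderr=stderr,
    )


def _safe_fit(problem: FitProblem, cfg: LMConfig) -> FitResult:
    try:
        return lm_fit(problem, cfg)
    except Exception as exc:  # isolate per-fit failures inside a batch
        x0 = np.asarray(getattr(problem, "x0", np.array([])), dtype=np.float64)
        return FitResult(x=x0, cost=np.inf, n_iter=0, n_feval=0,
                         status="failure", message=str(exc))


def batch_fit(
    problems: Sequence[FitProblem],
    cfg: Optional[LMConfig] = None,
    workers: int = 1,
) -> list[FitResult]:
    """Fit a batch of independent problems; order-preserving and deterministic.

    Results are bitwise identical to ``[lm_fit(p) for p in problems]``
    regardless of ``workers`` — each fit is independent, so parallel
    scheduling cannot change any result.  A failing fit is recorded in its
    own :class:`FitResult` (status ``failure``) and never aborts the batch.
    """
    if cfg is None:
        cfg = LMConfig()
    problems = list(problems)
    if not problems:
        return []
    if workers <= 1:
        return [_safe_fit(p, cfg) for p in problems]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda p: _safe_fit(p, cfg), problems))
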