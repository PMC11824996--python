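"""Time-stepping for Caputo fractional systems.

Three schemes are provided:

* :func:`abm_solve` — the fractional Adams–Bashforth–Moulton
  predictor–corrector (PECE) applied to the Volterra integral form of a
  left-Caputo initial-value problem.
* :func:`l1_forward_solve` — the implicit L1 discretization of the left
  Caputo derivative with a per-step Newton iteration on the 5x5 (or
  d x d) linearized system.
* :func:`l1_backward_solve` — the right-Caputo L1 scheme marching
  backwards from a zero terminal condition, for linear (adjoint-type)
  systems.

Both L1 schemes keep the full history kernel, so the work is O(N^2) in
the number of steps; no short-memory truncation is applied unless
requested.  At ``alpha = 1`` the L1 history weights vanish identically
and the forward scheme reduces to backward Euler; for the five-state
tumor model a numba-compiled backward-Euler path makes fine classical
grids affordable.

:func:`mittag_leffler` supplies the one-parameter Mittag-Leffler
function E_alpha(z), the closed-form solution kernel of the linear
relaxation test problem, used as an independent accuracy oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .model import RATE_FIELDS, ScaledParameters, Trajectory, rhs, jacobian

__all__ = [
    "TimeGrid",
    "mittag_leffler",
    "l1_weights",
    "abm_solve",
    "l1_forward_solve",
    "l1_backward_solve",
    "simulate",
    "SolverError",
]


class SolverError(RuntimeError):
    """A time step failed (singular system, Newton stall, overflow)."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid on [0, t_final] with n_steps intervals."""

    t_final: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.t_final <= 0 or self.n_steps < 1:
            raise ValueError("need t_final > 0 and n_steps >= 1")

    @property
    def dt(self) -> float:
        return self.t_final / self.n_steps

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_final, self.n_steps + 1)


# ---------------------------------------------------------------------------
# Mittag-Leffler oracle
# ---------------------------------------------------------------------------

def mittag_leffler(alpha: float, z: float) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) for real z.

    Power series ``sum_k z^k / Gamma(alpha k + 1)`` evaluated in
    arbitrary precision (the series suffers catastrophic cancellation
    for large negative arguments), switching to the algebraic
    asymptotic expansion ``-sum_{k>=1} z^{-k} / Gamma(1 - alpha k)``
    for large negative z.  ``E_1(z) = exp(z)`` exactly.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return math.exp(z)
    if z == 0.0:
        return 1.0
    import mpmath as mp

    if z < -30.0:
        # asymptotic series; truncate at the smallest term
        acc = 0.0
        prev = math.inf
        for k in range(1, 60):
            g = _gamma(1.0 - alpha * k)
            if not np.isfinite(g) or g == 0.0:
                continue
            term = -(z ** (-k)) / g
            if abs(term) > prev:
                break
            acc += term
            prev = abs(term)
        return float(acc)

    # series needs ~ |z|^{1/alpha} digits of guard precision
    guard = int(2.0 * abs(z) ** (1.0 / alpha)) + 30
    with mp.workdps(min(guard, 2000)):
        s = mp.mpf(1)
        term_k = mp.mpf(1)
        zm = mp.mpf(z)
        for k in range(1, 10000):
            term_k = zm ** k / mp.gamma(alpha * k + 1)
            s += term_k
            if abs(term_k) < mp.mpf(10) ** (-40) * max(1, abs(s)):
                break
        else:
            raise SolverError("Mittag-Leffler series did not converge")
        return float(s)


# ---------------------------------------------------------------------------
# L1 weights
# ---------------------------------------------------------------------------

def l1_weights(alpha: float, n: int) -> np.ndarray:
    """Left-Caputo L1 weights delta(j, n) = (n-j)^(1-a) - (n-j+1)^(1-a), j=1..n.

    ``delta(n, n) = -1`` always; for alpha < 1 the weights increase
    toward 0 as the lag n-j grows, and at alpha = 1 every weight with
    j < n vanishes (the scheme collapses to a one-step difference).
    """
    j = np.arange(1, n + 1)
    lag = (n - j).astype(float)
    lead = np.where(lag == 0.0, 0.0, lag ** (1.0 - alpha))  # 0^0 := 0 at alpha = 1
    return lead - (lag + 1.0) ** (1.0 - alpha)


def l1_leading_coefficient(alpha: float, dt: float) -> float:
    """B0 = -dt^(-alpha) / Gamma(2 - alpha) (so that delta(n,n) * B0 > 0)."""
    return -(dt ** (-alpha)) / _gamma(2.0 - alpha)


# ---------------------------------------------------------------------------
# Adams-Bashforth-Moulton predictor-corrector
# ---------------------------------------------------------------------------

def abm_solve(f, y0, alpha: float, grid: TimeGrid, corrector_passes: int = 1) -> np.ndarray:
    """Fractional ABM (PECE) solution of ``D^alpha y = f(t, y)``, ``y(0) = y0``.

    Rectangle-rule predictor and trapezoid-weighted corrector on the
    equivalent Volterra integral equation, with full history.  Returns
    an array of shape ``(n_steps + 1, d)``.
    """
    t = grid.times
    h = grid.dt
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    d = y0.size
    N = grid.n_steps
    y = np.empty((N + 1, d))
    fh = np.empty((N + 1, d))
    y[0] = y0
    fh[0] = np.atleast_1d(f(t[0], y[0]))

    k = np.arange(N + 2, dtype=float)
    pow_a = k ** alpha
    pow_a1 = k ** (alpha + 1.0)
    c_pred = h ** alpha / _gamma(alpha + 1.0)
    c_corr = h ** alpha / _gamma(alpha + 2.0)

    for n in range(N):
        j = np.arange(n + 1)
        b = pow_a[n + 1 - j] - pow_a[n - j]
        y_pred = y0 + c_pred * (b[:, None] * fh[: n + 1]).sum(axis=0)
        # corrector weights a_j, j = 0..n, plus weight 1 on the new node
        a = np.empty(n + 1)
        a[0] = pow_a1[n] - (n - alpha) * pow_a[n + 1]
        if n >= 1:
            jj = j[1:]
            a[1:] = pow_a1[n - jj + 2] + pow_a1[n - jj] - 2.0 * pow_a1[n - jj + 1]
        hist = (a[:, None] * fh[: n + 1]).sum(axis=0)
        y_new = y_pred
        for _ in range(corrector_passes):
            y_new = y0 + c_corr * (hist + np.atleast_1d(f(t[n + 1], y_new)))
        if not np.all(np.isfinite(y_new)):
            raise SolverError(f"ABM overflow/NaN at step {n + 1}")
        y[n + 1] = y_new
        fh[n + 1] = np.atleast_1d(f(t[n + 1], y[n + 1]))
    return y


# ---------------------------------------------------------------------------
# L1 forward scheme with Newton linearization
# ---------------------------------------------------------------------------

def l1_forward_solve(f, jac, y0, alpha: float, grid: TimeGrid,
                     newton_tol: float = 1e-10, max_newton: int = 25) -> np.ndarray:
    """Implicit L1 solution of ``D^alpha y = f(t, y)`` with Newton steps.

    At step n the nonlinear system
    ``B0 * sum_j delta(j,n) (y_j - y_{j-1}) = f(t_n, y_n)`` is solved
    for ``y_n`` by Newton iteration on the d x d linearized system
    ``(c I - J_f) dy = -G`` with ``c = dt^-alpha / Gamma(2-alpha)``,
    starting from the previous node.  ``jac(t, y)`` supplies the
    Jacobian of ``f``.
    """
    t = grid.times
    h = grid.dt
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    d = y0.size
    N = grid.n_steps
    y = np.empty((N + 1, d))
    y[0] = y0
    B0 = l1_leading_coefficient(alpha, h)
    c = -B0  # = delta(n,n) * B0 > 0
    eye = np.eye(d)
    dy_hist = np.empty((N, d))  # increments y_j - y_{j-1}, j = 1..N

    for n in range(1, N + 1):
        if alpha == 1.0:
            hist = np.zeros(d)
        else:
            w = l1_weights(alpha, n)[: n - 1]  # delta(j, n), j = 1..n-1
            hist = B0 * (w[:, None] * dy_hist[: n - 1]).sum(axis=0)
        yn = y[n - 1].copy()
        converged = False
        for _ in range(max_newton):
            G = hist + c * (yn - y[n - 1]) - np.atleast_1d(f(t[n], yn))
            A = c * eye - np.atleast_2d(jac(t[n], yn))
            try:
                step = np.linalg.solve(A, -G)
            except np.linalg.LinAlgError as exc:
                raise SolverError(f"singular step matrix at step {n}") from exc
            yn = yn + step
            if np.max(np.abs(step)) < newton_tol:
                converged = True
                break
        if not converged:
            raise SolverError(f"Newton failed to converge at step {n} (t={t[n]:g})")
        if not np.all(np.isfinite(yn)):
            raise SolverError(f"L1 overflow/NaN at step {n}")
        y[n] = yn
        dy_hist[n - 1] = yn - y[n - 1]
    return y


# ---------------------------------------------------------------------------
# Right-Caputo L1 backward scheme (linear adjoint systems)
# ---------------------------------------------------------------------------

def l1_backward_solve(coupling, source, alpha: float, grid: TimeGrid) -> np.ndarray:
    """Right-Caputo L1 march for ``D^alpha_{t,tf} lam = C(t) lam + s(t)``.

    ``coupling`` has shape ``(N+1, d, d)`` and ``source`` ``(N+1, d)``,
    giving the affine right-hand side at each node; the terminal
    condition is ``lam(t_f) = 0`` (transversality).  The scheme uses the
    mirrored weights ``xi(m) = m^(1-a) - (m-1)^(1-a)`` and solves one
    d x d linear system per node from ``n = N-1`` down to ``0``; at
    ``alpha = 1`` it reduces to implicit Euler run backwards in time.
    """
    coupling = np.asarray(coupling, dtype=float)
    source = np.asarray(source, dtype=float)
    N = grid.n_steps
    d = source.shape[1]
    if coupling.shape != (N + 1, d, d) or source.shape != (N + 1, d):
        raise ValueError("coupling/source shapes disagree with the grid")
    h = grid.dt
    c = (h ** (-alpha)) / _gamma(2.0 - alpha)  # D0
    m = np.arange(N + 2, dtype=float)
    xi = m ** (1.0 - alpha) - np.maximum(m - 1.0, 0.0) ** (1.0 - alpha)  # xi[m], xi[1] = 1
    lam = np.zeros((N + 1, d))
    eye = np.eye(d)
    dl = np.zeros((N, d))  # dl[j-1] = lam_{j-1} - lam_j

    for n in range(N - 1, -1, -1):
        if alpha == 1.0 or n + 2 > N:
            hist = np.zeros(d)
        else:
            j = np.arange(n + 2, N + 1)
            hist = (xi[j - n][:, None] * dl[j - 1]).sum(axis=0)
        b = c * lam[n + 1] - c * hist + source[n]
        A = c * eye - coupling[n]
        try:
            lam[n] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular adjoint system at node {n}") from exc
        dl[n] = lam[n] - lam[n + 1]
    return lam


# ---------------------------------------------------------------------------
# Numba backward-Euler fast path for the tumor model at alpha = 1
# ---------------------------------------------------------------------------

_BE_KERNEL = None


def _get_be_kernel():
    """Compile (once) the model-specific backward-Euler loop.

    The kernel hard-codes the five model equations and their Jacobian;
    it is kept in lock-step with :func:`oncofrac.model.rhs` and checked
    against it in the test suite.
    """
    global _BE_KERNEL
    if _BE_KERNEL is not None:
        return _BE_KERNEL
    import numba

    @numba.njit(cache=True)
    def _be_loop(y0, h, N, v_arr, p, stem_sign, tol, maxit):  # pragma: no cover - compiled
        r1, b1, p1, p2, p3, p4, kT, kN, hh, kS, rho, mu, r2, b2, g1, g2 = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
            p[10], p[11], p[12], p[13], p[14], p[15])
        y = np.empty((N + 1, 5))
        y[0] = y0
        A = np.empty((5, 5))
        for n in range(1, N + 1):
            v = v_arr[n]
            yn = y[n - 1].copy()
            for _ in range(maxit):
                T, E, Nn, S, M = yn[0], yn[1], yn[2], yn[3], yn[4]
                f0 = r1 * T * (1.0 - b1 * T) - p3 * E * T - kT * M * T
                f1 = rho - mu * E + p1 * E * S / (S + 1.0) - p2 * (T + M) * E
                f2 = r2 * Nn * (1.0 - b2 * Nn) + hh * S * Nn - p4 * T * Nn - kN * M * Nn
                f3 = stem_sign * g1 * S - kS * M * S
                f4 = v - g2 * M
                # residual of backward Euler: (y - y_prev)/h - f
                G0 = (yn[0] - y[n - 1, 0]) / h - f0
                G1 = (yn[1] - y[n - 1, 1]) / h - f1
                G2 = (yn[2] - y[n - 1, 2]) / h - f2
                G3 = (yn[3] - y[n - 1, 3]) / h - f3
                G4 = (yn[4] - y[n - 1, 4]) / h - f4
                A[:, :] = 0.0
                A[0, 0] = 1.0 / h - (r1 * (1.0 - 2.0 * b1 * T) - p3 * E - kT * M)
                A[0, 1] = p3 * T
                A[0, 4] = kT * T
                A[1, 0] = p2 * E
                A[1, 1] = 1.0 / h - (-mu + p1 * S / (S + 1.0) - p2 * (T + M))
                A[1, 3] = -p1 * E / (S + 1.0) ** 2
                A[1, 4] = p2 * E
                A[2, 0] = p4 * Nn
                A[2, 2] = 1.0 / h - (r2 - 2.0 * r2 * b2 * Nn + hh * S - p4 * T - kN * M)
                A[2, 3] = -hh * Nn
                A[2, 4] = kN * Nn
                A[3, 3] = 1.0 / h - (stem_sign * g1 - kS * M)
                A[3, 4] = kS * S
                A[4, 4] = 1.0 / h + g2
                G = np.array([G0, G1, G2, G3, G4])
                step = np.linalg.solve(A, -G)
                yn = yn + step
                if np.max(np.abs(step)) < tol:
                    break
            y[n] = yn
        return y

    _BE_KERNEL = _be_loop
    return _BE_KERNEL


# ---------------------------------------------------------------------------
# Model-level driver
# ---------------------------------------------------------------------------

def _control_array(control, times: np.ndarray, default_v: float) -> np.ndarray:
    if control is None:
        return np.full(times.shape, default_v)
    if np.isscalar(control):
        return np.full(times.shape, float(control))
    if callable(control):
        return np.array([float(control(t)) for t in times])
    arr = np.asarray(control, dtype=float)
    if arr.shape != times.shape:
        raise ValueError("control array length disagrees with the grid")
    return arr


def simulate(sp: ScaledParameters, y0, grid: TimeGrid, control=None,
             method: str = "abm", newton_tol: float = 1e-10, max_newton: int = 25,
             corrector_passes: int = 1) -> Trajectory:
    """Integrate the five-compartment model on a uniform grid.

    ``control`` may be None (use the configured constant ``v``), a
    scalar, a callable ``v(t)`` or a per-node array; ``method`` is
    ``"abm"`` or ``"l1"``.  Returns a :class:`Trajectory` carrying the
    applied control.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    t = grid.times
    v_arr = _control_array(control, t, sp.v)
    h = grid.dt

    def node_v(time: float) -> float:
        return v_arr[min(int(round(time / h)), grid.n_steps)]

    def f(time, y):
        return rhs(y, time, node_v(time), sp)

    if method == "abm":
        y = abm_solve(f, y0, sp.alpha, grid, corrector_passes=corrector_passes)
    elif method == "l1":
        if sp.alpha == 1.0:
            kernel = _get_be_kernel()
            y = kernel(y0, h, grid.n_steps, v_arr, sp.rate_array(),
                       float(sp.stem_sign), newton_tol, max_newton)
            if not np.all(np.isfinite(y)):
                raise SolverError("backward-Euler path produced non-finite states")
        else:
            def jf(time, y):
                return jacobian(y, sp)

            y = l1_forward_solve(f, jf, y0, sp.alpha, grid,
                                 newton_tol=newton_tol, max_newton=max_newton)
    else:
        raise ValueError(f"unknown method {method!r} (expected 'abm' or 'l1')")
    return Trajectory(times=t, states=y, control=v_arr)
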