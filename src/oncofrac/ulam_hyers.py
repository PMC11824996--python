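"""Quantitative Ulam-Hyers stability certificates.

For the Volterra integral form of the Caputo system, a Lipschitz
constant ``kappa`` of the vector field (in the sum-of-components
1-norm) over a compact state box, together with the horizon factor
``Psi(T, alpha) = T^alpha / Gamma(alpha + 1)``, yields the contraction
number ``Omega = Psi * kappa``.  When ``Omega < 1`` the solution is
unique on [0, T] and Ulam-Hyers stable: any function satisfying the
system up to defect ``delta`` lies within ``Psi * delta / (1 - Omega)``
of the true solution.

The quadratic vector field has no global Lipschitz constant, so
``kappa`` is deliberately defined over a user-stated compact box (the
sup of the induced 1-norm of the Jacobian over a deterministic lattice),
making certificates reproducible and honest about their domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .model import FractionalOrder, ScaledParameters, jacobian, rhs

__all__ = ["UHCertificate", "lipschitz_bound", "affine_growth_bound",
           "uh_certificate", "default_box"]


@dataclass(frozen=True)
class UHCertificate:
    """Constants of the fixed-point analysis and the Omega < 1 verdict.

    ``horizon_max`` is the largest horizon with Omega = 1, i.e.
    ``(Gamma(alpha+1)/kappa)^(1/alpha)``; ``sigma``/``tau`` report the
    fitted affine growth bound ``sup ||f(H)||_1 <= sigma ||H||_1 + tau``
    over the same box (no tightness claim).
    """

    kappa: float
    psi: float
    omega: float
    horizon: float
    alpha: float
    box: np.ndarray
    verdict: str  # certified | not_certified
    horizon_max: float
    sigma: float | None = None
    tau: float | None = None


def default_box(y0, equilibrium_point=None) -> np.ndarray:
    """Componentwise box [0, 2 * max(initial, equilibrium)] (floor 1)."""
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    hi = np.maximum(np.abs(y0), 1.0)
    if equilibrium_point is not None:
        hi = np.maximum(hi, np.abs(np.asarray(equilibrium_point, dtype=float)))
    return np.stack([np.zeros_like(hi), 2.0 * hi], axis=1)


def _lattice(box: np.ndarray, resolution: int) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.ndim != 2 or box.shape[1] != 2:
        raise ValueError("box must have shape (d, 2)")
    if not np.all(np.isfinite(box)) or np.any(box[:, 1] < box[:, 0]):
        raise ValueError("box must be finite with lower <= upper")
    axes = [np.linspace(lo, hi, resolution) if hi > lo else np.array([lo])
            for lo, hi in box]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def lipschitz_bound(sp: ScaledParameters, box, resolution: int = 5) -> float:
    """Sup of the induced 1-norm of the Jacobian over a lattice of the box.

    The induced 1-norm (max column absolute sum) is the operator norm
    matching the sum-of-components state norm; for the model's quadratic
    field the column sums are affine in the state, so the sup over the
    box is attained at lattice vertices and a coarse deterministic
    lattice is exact up to the bilinear cross terms.
    """
    pts = _lattice(box, resolution)
    kappa = 0.0
    for x in pts:
        J = jacobian(x, sp)
        kappa = max(kappa, float(np.max(np.abs(J).sum(axis=0))))
    return kappa


def affine_growth_bound(sp: ScaledParameters, box, resolution: int = 5) -> tuple[float, float]:
    """Fitted (sigma, tau) with ||f(H)||_1 <= sigma ||H||_1 + tau on the lattice.

    ``sigma`` is taken as the Lipschitz bound over the box and ``tau``
    as the smallest intercept making the bound hold at every lattice
    point; valid on the lattice by construction, with no tightness claim.
    """
    sigma = lipschitz_bound(sp, box, resolution)
    tau = 0.0
    for x in _lattice(box, resolution):
        f1 = float(np.abs(rhs(x, 0.0, sp.v, sp)).sum())
        tau = max(tau, f1 - sigma * float(np.abs(x).sum()))
    return sigma, max(tau, 0.0)


def uh_certificate(kappa: float, order: FractionalOrder, horizon: float,
                   box=None, sigma: float | None = None,
                   tau: float | None = None) -> UHCertificate:
    """Assemble the Ulam-Hyers certificate for a given Lipschitz bound.

    ``psi = horizon^alpha / Gamma(alpha + 1)``, ``omega = psi * kappa``;
    the verdict is ``certified`` iff ``omega < 1``.
    """
    if kappa < 0 or horizon < 0:
        raise ValueError("kappa and horizon must be >= 0")
    alpha = order.alpha
    g = float(_gamma(alpha + 1.0))
    psi = horizon ** alpha / g
    omega = psi * kappa
    try:
        horizon_max = math.inf if kappa == 0.0 else (g / kappa) ** (1.0 / alpha)
    except OverflowError:
        horizon_max = math.inf
    return UHCertificate(
        kappa=kappa, psi=psi, omega=omega, horizon=horizon, alpha=alpha,
        box=None if box is None else np.asarray(box, dtype=float),
        verdict="certified" if omega < 1.0 else "not_certified",
        horizon_max=horizon_max, sigma=sigma, tau=tau,
    )
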