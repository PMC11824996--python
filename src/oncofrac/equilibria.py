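"""Equilibria of the chemo-stem-cell model and fractional (Matignon) stability.

Branches
--------
tumor_free
    ``T* = 0``, ``S* = 0``, drug at its infusion steady state
    ``M* = v^alpha / gamma2^alpha``; effector and normal cells at the
    balance of source against mortality and of logistic growth against
    drug kill.  Exists when normal-cell proliferation exceeds the
    drug-dependent threshold ``kN^a * v^a / gamma2^a``.
coexisting
    Positive tumor burden; ``T*`` solves a quadratic obtained by
    substituting the effector balance ``E(T)`` into the tumor equation.
dead
    Same ``(T, E)`` fixed points restricted to ``N = 0`` (the patient is
    not alive); reported but not used for treatment conclusions.

Stability uses the Matignon condition: an equilibrium of the order-alpha
system is locally asymptotically stable iff every Jacobian eigenvalue
satisfies ``|arg(lambda)| > alpha * pi / 2``.  For a complex-conjugate
pair from the quadratic factor ``lambda^2 + c1 lambda + c2`` the verdict
flips at a closed-form critical order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import FractionalOrder, ScaledParameters, jacobian, rhs

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "DegenerateParameterError",
    "tumor_free_equilibrium",
    "coexisting_equilibria",
    "dead_equilibria",
    "tumor_free_stability_conditions",
    "classify_stability",
    "factored_eigenvalues",
    "critical_alpha",
    "MARGINAL_TOL",
]

#: tolerance (radians) inside which |arg| - alpha*pi/2 counts as marginal
MARGINAL_TOL = 1e-10


class DegenerateParameterError(ValueError):
    """A denominator in a closed-form equilibrium vanished."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the vector field with its existence bookkeeping.

    ``existence_margins`` maps a condition name to a signed margin; the
    branch exists in the biologically meaningful sense iff every margin
    is positive (and all components are finite).
    """

    point: np.ndarray
    branch: str  # tumor_free | coexisting | dead
    exists: bool
    existence_margins: dict[str, float] = field(default_factory=dict)

    def residual(self, sp: ScaledParameters) -> float:
        """Max-norm of the vector field at the point, relative to state size.

        The infusion entering the drug line is the one consistent with
        the stored drug level (``v_t = gamma2^a * M*``), so branches
        computed with an overridden M* (e.g. the no-chemotherapy case)
        are checked against their own steady infusion.
        """
        f = rhs(self.point, 0.0, sp.gamma2 * self.point[4], sp)
        scale = max(1.0, float(np.max(np.abs(self.point))))
        return float(np.max(np.abs(f)) / scale)


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    matignon_margin: float  # min_i |arg(lambda_i)| - alpha*pi/2, radians
    verdict: str  # stable | unstable | marginal
    c1: float
    c2: float
    critical_alpha: float | None


def _drug_level(sp: ScaledParameters, m_star: float | None) -> float:
    return sp.drug_equilibrium if m_star is None else float(m_star)


def tumor_free_equilibrium(sp: ScaledParameters, m_star: float | None = None) -> Equilibrium:
    """Closed-form tumor-free fixed point ``(0, E0*, N0*, 0, M*)``.

    ``E0* = rho^a / (mu^a + p2^a M*)`` and
    ``N0* = 1/b2^a - kN^a M* / (r2^a b2^a)``; the branch exists iff
    ``N0* > 0``, i.e. ``r2^a > kN^a v^a / gamma2^a``.  ``m_star``
    overrides the default infusion steady state (useful for the
    no-chemotherapy case ``M* = 0`` with a nonzero configured ``v``).
    """
    M = _drug_level(sp, m_star)
    denom_e = sp.mu + sp.p2 * M
    denom_n = sp.r2 * sp.b2
    if denom_e <= 0.0 or denom_n <= 0.0:
        raise DegenerateParameterError("degenerate parameters: zero denominator in tumor-free closed form")
    E = sp.rho / denom_e
    N = 1.0 / sp.b2 - sp.kN * M / denom_n
    margins = {"normal_growth_vs_drug": sp.r2 - sp.kN * M}
    point = np.array([0.0, E, N, 0.0, M])
    return Equilibrium(point=point, branch="tumor_free",
                       exists=bool(N > 0.0 and np.all(np.isfinite(point))),
                       existence_margins=margins)


def _tumor_quadratic_roots(sp: ScaledParameters, M: float) -> list[float]:
    """Positive real roots of the tumor fixed-point quadratic.

    Substituting ``E(T) = rho / (mu + p2 (T + M*))`` into
    ``r1 (1 - b1 T) = p3 E(T) + kT M*`` and clearing the denominator
    gives ``a2 T^2 + a1 T + a0 = 0`` with the coefficients below.
    Roots are kept when real and in ``(0, 1/b1]`` (the logistic cap).
    """
    A = sp.mu + sp.p2 * M
    a2 = -sp.r1 * sp.b1 * sp.p2
    a1 = sp.r1 * sp.p2 - sp.r1 * sp.b1 * A - sp.kT * M * sp.p2
    a0 = sp.r1 * A - sp.p3 * sp.rho - sp.kT * M * A
    if a2 == 0.0 and a1 == 0.0:
        return []
    roots = np.roots([a2, a1, a0]) if a2 != 0.0 else np.array([-a0 / a1])
    cap = 1.0 / sp.b1
    out = []
    for z in roots:
        if abs(z.imag) <= 1e-12 * max(1.0, abs(z.real)):
            T = float(z.real)
            if 0.0 < T <= cap * (1.0 + 1e-12):
                out.append(min(T, cap))
    return sorted(out)


def coexisting_equilibria(sp: ScaledParameters, m_star: float | None = None) -> list[Equilibrium]:
    """All fixed points with positive tumor burden (``S* = 0``).

    Every positive real root ``T*`` of the tumor quadratic is returned
    with the induced ``E* = rho/(mu + p2 (T* + M*))`` and
    ``N* = 1/b2 - (p4 T* + kN M*)/(r2 b2)``.  The branch exists iff
    additionally ``N* > 0``; an empty list means no positive root.
    """
    M = _drug_level(sp, m_star)
    out = []
    for T in _tumor_quadratic_roots(sp, M):
        E = sp.rho / (sp.mu + sp.p2 * (T + M))
        N = 1.0 / sp.b2 - (sp.p4 * T + sp.kN * M) / (sp.r2 * sp.b2)
        margins = {
            "tumor_growth_vs_kill": sp.r1 - sp.p3 * E - sp.kT * M,
            "normal_growth_vs_load": sp.r2 - sp.p4 * T - sp.kN * M,
        }
        point = np.array([T, E, N, 0.0, M])
        out.append(Equilibrium(point=point, branch="coexisting",
                               exists=bool(N > 0.0 and np.all(np.isfinite(point))),
                               existence_margins=margins))
    return out


def dead_equilibria(sp: ScaledParameters, m_star: float | None = None) -> list[Equilibrium]:
    """Fixed points on the ``N = 0`` hyperplane (normal cells extinct).

    The normal-cell equation is trivially satisfied at ``N = 0``, so the
    dead branch carries the tumor-free effector balance ``(0, E0*)`` and
    every positive tumor root ``(T*, E*)``, all with ``S* = 0`` and the
    drug at ``M*``.
    """
    M = _drug_level(sp, m_star)
    denom_e = sp.mu + sp.p2 * M
    if denom_e <= 0.0:
        raise DegenerateParameterError("degenerate parameters: zero effector denominator")
    out = [Equilibrium(point=np.array([0.0, sp.rho / denom_e, 0.0, 0.0, M]),
                       branch="dead", exists=True)]
    for T in _tumor_quadratic_roots(sp, M):
        E = sp.rho / (sp.mu + sp.p2 * (T + M))
        out.append(Equilibrium(point=np.array([T, E, 0.0, 0.0, M]),
                               branch="dead", exists=True))
    return out


def tumor_free_stability_conditions(sp: ScaledParameters, eq: Equilibrium) -> dict[str, tuple[bool, float]]:
    """The three sufficient conditions for tumor-free local stability.

    Returns ``name -> (holds, margin)`` for
    ``kS M* > gamma1`` (drug clears stem cells),
    ``2 r2 b2 N0* + kN M* > r2`` (normal logistic damping), and
    ``p3 E0* + kT M* > r1`` (immune + drug kill beats tumor growth).
    """
    if eq.branch != "tumor_free":
        raise ValueError("stability conditions apply to the tumor_free branch only")
    _, E, N, _, M = eq.point
    margins = {
        "stem_clearance": sp.kS * M - sp.gamma1,
        "normal_damping": 2.0 * sp.r2 * sp.b2 * N + sp.kN * M - sp.r2,
        "tumor_suppression": sp.p3 * E + sp.kT * M - sp.r1,
    }
    return {name: (m > 0.0, m) for name, m in margins.items()}


def critical_alpha(c1: float, c2: float) -> float | None:
    """Closed-form critical order for the quadratic factor ``l^2 + c1 l + c2``.

    For a complex pair with ``c1 > 0`` returns the closed form
    ``(2/pi) * arctan(sqrt(4 c2 - c1^2) / c1)``; for ``c1 = 0`` (pair
    on the imaginary axis) the wedge closes exactly at 1.  Real roots
    (``c1^2 >= 4 c2``) have alpha-independent verdicts and return
    ``None``, as does ``c1 < 0``.

    .. caution::
       For ``c1 > 0`` the pair ``(-c1 +- i sqrt(4c2 - c1^2))/2`` lies in
       the open left half plane, where ``|arg| = pi - arctan(...) >
       pi/2``: the Matignon cone is satisfied for *every* order in
       (0, 1] and no instability occurs at the returned value.  The
       closed form is the true wedge-crossing order of the mirrored
       right-half-plane pair (``c1 -> -c1``), so it is a conservative
       threshold here.  :func:`classify_stability` always applies the
       exact eigenvalue test and is authoritative for verdicts.
    """
    disc = 4.0 * c2 - c1 * c1
    if disc <= 0.0 or c1 < 0.0:
        return None
    if c1 == 0.0:
        return 1.0
    return 2.0 / math.pi * math.atan(math.sqrt(disc) / c1)


def classify_stability(eq: Equilibrium, order: FractionalOrder, sp: ScaledParameters) -> StabilityReport:
    """Matignon classification of an equilibrium at fractional order alpha.

    Eigenvalues come from the full numeric 5x5 Jacobian; the quadratic
    coefficients ``c1 = -(e11 + e22)``, ``c2 = e11 e22 - e12 e21`` of
    the tumor-effector block are reported alongside for the factored
    cross-check and the critical order.
    """
    J = jacobian(eq.point, sp)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite Jacobian")
    lam = np.linalg.eigvals(J)
    alpha = order.alpha
    threshold = alpha * math.pi / 2.0
    args = np.abs(np.angle(lam))
    zero = np.abs(lam) == 0.0
    if np.any(zero):
        margin = float(np.min(args[~zero]) - threshold) if not np.all(zero) else 0.0
        verdict = "marginal"
    else:
        margin = float(np.min(args) - threshold)
        if margin > MARGINAL_TOL:
            verdict = "stable"
        elif margin < -MARGINAL_TOL:
            verdict = "unstable"
        else:
            verdict = "marginal"
    c1 = float(-(J[0, 0] + J[1, 1]))
    c2 = float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
    return StabilityReport(eigenvalues=lam, matignon_margin=margin, verdict=verdict,
                           c1=c1, c2=c2, critical_alpha=critical_alpha(c1, c2))


def factored_eigenvalues(eq: Equilibrium, sp: ScaledParameters) -> np.ndarray:
    """Eigenvalues via the factored characteristic polynomial.

    At the reported branches (all with ``S* = 0``) the characteristic
    polynomial factors as
    ``(e33 - l)(e44 - l)(e55 - l)(l^2 + c1 l + c2)``: three explicit
    eigenvalues from the normal, stem and drug rows plus the roots of
    the tumor-effector quadratic block.  Provided as an independent
    cross-check of the dense eigensolve.
    """
    J = jacobian(eq.point, sp)
    c1 = -(J[0, 0] + J[1, 1])
    c2 = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    quad = np.roots([1.0, c1, c2])
    return np.concatenate((np.array([J[2, 2], J[3, 3], J[4, 4]], dtype=complex), quad))
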