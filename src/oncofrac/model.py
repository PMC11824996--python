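"""Core model: parameters, states, fractional-order rate scaling, vector field, Jacobian.

The model couples five compartments — tumor cells ``T``, effector-immune
cells ``E``, normal cells ``N``, stem cells ``S`` and the amount of
chemotherapeutic agent ``M`` — under a Caputo fractional derivative of
order ``alpha`` in (0, 1].  To keep the dimensions of every term
consistent when the time-derivative order changes, each first-order rate
constant enters the dynamics raised to the power ``alpha`` (a standard
convention for fractionalized compartment models); the drug infusion
``v(t)`` is the one exception, entering the dynamics unexponentiated.

State ordering is ``(T, E, N, S, M)`` everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

STATE_NAMES: tuple[str, ...] = ("T", "E", "N", "S", "M")

#: parameter fields that are rates and therefore alpha-exponentiated
RATE_FIELDS: tuple[str, ...] = (
    "r1", "b1", "p1", "p2", "p3", "p4",
    "kT", "kN", "h", "kS", "rho", "mu",
    "r2", "b2", "gamma1", "gamma2",
)

_POSITIVE_FIELDS = ("b1", "b2", "gamma2", "mu")


class ParameterError(ValueError):
    """Raised for parameter values outside the model's admissible range."""


@dataclass(frozen=True)
class FractionalOrder:
    """Caputo derivative order, restricted to (0, 1].

    ``alpha = 1`` recovers the classical first-order system and is
    admitted so that every fractional routine can be checked against its
    integer-order limit.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0) or not np.isfinite(self.alpha):
            raise ParameterError(f"fractional order must lie in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ModelParameters:
    """Biological rate constants (defaults: the baseline parameter set).

    Units: proliferation/decay/response rates in day^-1; the reciprocal
    carrying capacities ``b1``, ``b2`` in cells^-1; the bilinear
    interaction rates ``p1..p4``, ``kN``, ``h``, ``kS`` in
    day^-1 cells^-1; ``rho`` is the constant effector source; ``v`` is
    the constant drug-infusion baseline (dimensionless dose/day).

    ``stem_sign`` selects the sign of the intrinsic stem-cell term
    ``stem_sign * gamma1 * S``: +1 follows the model equations as
    written (exponential stem growth when no drug is present), while -1
    treats ``gamma1`` as the stem-cell decay rate its description
    suggests.  Equilibria are unaffected (every reported branch has
    ``S* = 0``).
    """

    r1: float = 0.00431
    b1: float = 1.02e-9
    p1: float = 3.41e-11
    p2: float = 2e-11
    p3: float = 6.41e-11
    p4: float = 3.41e-11
    kT: float = 0.08
    kN: float = 2e-11
    h: float = 3e-11
    kS: float = 2e-11
    rho: float = 0.33
    mu: float = 0.204
    r2: float = 0.00431 / 2
    b2: float = 1.02e-9 / 2
    gamma1: float = 0.1
    gamma2: float = 1.0
    v: float = 1.0
    stem_sign: int = +1

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"rate {name!r} must be finite and >= 0, got {value}")
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ParameterError(f"parameter {name!r} must be > 0")
        if not np.isfinite(self.v) or self.v < 0:
            raise ParameterError(f"infusion v must be finite and >= 0, got {self.v}")
        if self.stem_sign not in (+1, -1):
            raise ParameterError(f"stem_sign must be +1 or -1, got {self.stem_sign}")

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScaledParameters:
    """Rates raised to the power ``alpha``; ``v`` kept raw for the dynamics.

    Steady-drug equilibrium formulas use ``M* = v**alpha / gamma2**alpha``
    (exposed as :attr:`drug_equilibrium`); at ``alpha = 1`` the two
    conventions agree.
    """

    alpha: float
    r1: float
    b1: float
    p1: float
    p2: float
    p3: float
    p4: float
    kT: float
    kN: float
    h: float
    kS: float
    rho: float
    mu: float
    r2: float
    b2: float
    gamma1: float
    gamma2: float
    v: float
    stem_sign: int

    @property
    def drug_equilibrium(self) -> float:
        """Steady drug level M* = v^alpha / gamma2^alpha under constant infusion."""
        return self.v ** self.alpha / self.gamma2

    def rate_array(self) -> np.ndarray:
        """Scaled rates as a flat array in RATE_FIELDS order (numba kernels)."""
        return np.array([getattr(self, n) for n in RATE_FIELDS], dtype=float)


def scale_parameters(params: ModelParameters, order: FractionalOrder) -> ScaledParameters:
    """Raise every rate constant to the power ``alpha``.

    At ``alpha = 1`` this is the identity.  The infusion baseline ``v``
    is carried through unchanged (the dynamics use raw ``v(t)``).
    """
    alpha = order.alpha
    scaled = {name: getattr(params, name) ** alpha for name in RATE_FIELDS}
    return ScaledParameters(alpha=alpha, v=params.v, stem_sign=params.stem_sign, **scaled)


@dataclass(frozen=True)
class SystemState:
    """Point state (T, E, N, S, M): cell densities and drug amount."""

    T: float
    E: float
    N: float
    S: float
    M: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.E, self.N, self.S, self.M], dtype=float)

    @classmethod
    def from_array(cls, y) -> "SystemState":
        y = np.asarray(y, dtype=float)
        return cls(*(float(c) for c in y))


@dataclass
class Trajectory:
    """Solution of the system on a uniform time grid.

    ``states`` has one row per node in (T, E, N, S, M) order;
    ``control`` holds the infusion value applied at each node.
    """

    times: np.ndarray
    states: np.ndarray
    control: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape[0] != self.times.size:
            raise ValueError("times and states lengths disagree")
        if self.times[0] != 0.0:
            raise ValueError("trajectory grids start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.shape != self.times.shape:
                raise ValueError("control length disagrees with grid")

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.times}
        for k, name in enumerate(STATE_NAMES):
            data[name] = self.states[:, k]
        if self.control is not None:
            data["v"] = self.control
        return pd.DataFrame(data)

    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _state_array(state) -> np.ndarray:
    if isinstance(state, SystemState):
        return state.as_array()
    return np.asarray(state, dtype=float)


def rhs(state, t: float, v_t: float, sp: ScaledParameters) -> np.ndarray:
    """Vector field of the five-compartment model with alpha-scaled rates.

    dT = r1 T (1 - b1 T) - p3 E T - kT M T
    dE = rho - mu E + p1 E S / (S + 1) - p2 (T + M) E
    dN = r2 N (1 - b2 N) + h S N - p4 T N - kN M N
    dS = stem_sign * gamma1 S - kS M S
    dM = v(t) - gamma2 M

    (every rate already exponentiated by alpha; ``v_t`` raw).
    """
    T, E, N, S, M = _state_array(state)
    dT = sp.r1 * T * (1.0 - sp.b1 * T) - sp.p3 * E * T - sp.kT * M * T
    dE = sp.rho - sp.mu * E + sp.p1 * E * S / (S + 1.0) - sp.p2 * (T + M) * E
    dN = sp.r2 * N * (1.0 - sp.b2 * N) + sp.h * S * N - sp.p4 * T * N - sp.kN * M * N
    dS = sp.stem_sign * sp.gamma1 * S - sp.kS * M * S
    dM = v_t - sp.gamma2 * M
    return np.array([dT, dE, dN, dS, dM])


def jacobian(state, sp: ScaledParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`rhs` with respect to (T, E, N, S, M)."""
    T, E, N, S, M = _state_array(state)
    J = np.zeros((5, 5))
    # tumor row
    J[0, 0] = sp.r1 * (1.0 - 2.0 * sp.b1 * T) - sp.p3 * E - sp.kT * M
    J[0, 1] = -sp.p3 * T
    J[0, 4] = -sp.kT * T
    # effector row
    J[1, 0] = -sp.p2 * E
    J[1, 1] = -sp.mu + sp.p1 * S / (S + 1.0) - sp.p2 * (T + M)
    J[1, 3] = sp.p1 * E / (S + 1.0) ** 2
    J[1, 4] = -sp.p2 * E
    # normal row
    J[2, 0] = -sp.p4 * N
    J[2, 2] = sp.r2 - 2.0 * sp.r2 * sp.b2 * N + sp.h * S - sp.p4 * T - sp.kN * M
    J[2, 3] = sp.h * N
    J[2, 4] = -sp.kN * N
    # stem row
    J[3, 3] = sp.stem_sign * sp.gamma1 - sp.kS * M
    J[3, 4] = -sp.kS * S
    # drug row
    J[4, 4] = -sp.gamma2
    return J


def assert_admissible(y, tol: float = 1e-8) -> None:
    """Check the nonnegativity a biologically admissible state must satisfy.

    Trajectories launched from nonnegative initial data remain in the
    closed positive orthant; numerically we tolerate excursions down to
    ``-tol`` rather than clipping (clipping is opt-in downstream).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state encountered")
    if np.min(y) < -tol:
        k = int(np.argmin(y))
        raise FloatingPointError(
            f"state component {STATE_NAMES[k]} = {y.min():g} below admissible tolerance"
        )


def parameters_from_mapping(mapping: dict) -> ModelParameters:
    """Build parameters from a flat name->value mapping; unknown keys rejected."""
    known = {f.name for f in fields(ModelParameters)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**mapping)
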