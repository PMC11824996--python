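"""Flat-text scenario configuration, built-in scenarios and tabular output.

A scenario is a flat key -> value mapping (YAML, one level deep): the
biological rates by name, the fractional order ``alpha``, the initial
state ``T0..M0``, the grid (``t_final``, ``n_steps``), the control mode
and, for optimized runs, the sweep settings (``B1``, ``B2``,
``delta_tol`` ...).  Missing keys fall back to the baseline parameter
set; unknown keys are rejected by name.  The whole pipeline is
deterministic — ``seed`` is accepted and recorded for forward
compatibility but nothing draws random numbers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from .focp import ControlWeights, FBSConfig
from .model import (FractionalOrder, ModelParameters, Trajectory,
                    parameters_from_mapping, STATE_NAMES)
from .solvers import TimeGrid

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "loads_config",
           "save_config", "dumps_config", "builtin_scenarios",
           "write_trajectory", "write_records"]

#: baseline initial state (T0, E0, N0, S0, M0)
DEFAULT_INITIAL_STATE = (2.0, 0.1, 1.0, 0.5, 0.5)
DEFAULT_ALPHA = 0.95
#: fractional orders examined in the standard scenario sweep
ALPHA_SET = (0.65, 0.75, 0.85, 0.95)

_PARAM_KEYS = ("r1", "b1", "p1", "p2", "p3", "p4", "kT", "kN", "h", "kS",
               "rho", "mu", "r2", "b2", "gamma1", "gamma2", "v", "stem_sign")
_STATE_KEYS = ("T0", "E0", "N0", "S0", "M0")
_GRID_KEYS = ("t_final", "n_steps")
_FOCP_KEYS = ("B1", "B2", "delta_tol", "max_sweeps", "relaxation", "v_init",
              "focp_gamma2", "state_solver")
_OTHER_KEYS = ("alpha", "control_mode", "solver", "seed")
_KNOWN_KEYS = set(_PARAM_KEYS) | set(_STATE_KEYS) | set(_GRID_KEYS) \
    | set(_FOCP_KEYS) | set(_OTHER_KEYS)


class ConfigError(ValueError):
    """Configuration file could not be turned into a valid scenario."""


@dataclass
class ScenarioConfig:
    """A complete, defaulted simulation/optimization scenario."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    alpha: float = DEFAULT_ALPHA
    initial_state: tuple = DEFAULT_INITIAL_STATE
    t_final: float = 50.0
    n_steps: int = 1000
    control_mode: str = "none"  # none | constant | optimal
    solver: str = "abm"  # abm | l1
    focp: FBSConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        FractionalOrder(self.alpha)  # validates the range
        if self.control_mode not in ("none", "constant", "optimal"):
            raise ConfigError(f"control_mode must be none|constant|optimal, got {self.control_mode!r}")
        if self.solver not in ("abm", "l1"):
            raise ConfigError(f"solver must be abm|l1, got {self.solver!r}")
        if self.control_mode == "optimal" and self.focp is None:
            self.focp = FBSConfig(horizon=self.t_final, n_steps=self.n_steps)

    @property
    def order(self) -> FractionalOrder:
        return FractionalOrder(self.alpha)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(t_final=self.t_final, n_steps=self.n_steps)

    def initial_array(self) -> np.ndarray:
        return np.asarray(self.initial_state, dtype=float)

    def constant_infusion(self) -> float:
        """Infusion applied in a plain simulation run: 0 unless constant mode."""
        return self.parameters.v if self.control_mode == "constant" else 0.0


def _flatten(cfg: ScenarioConfig) -> dict:
    out: dict = {}
    for key in _PARAM_KEYS:
        out[key] = getattr(cfg.parameters, key)
    for key, val in zip(_STATE_KEYS, cfg.initial_state):
        out[key] = float(val)
    out.update(alpha=cfg.alpha, t_final=cfg.t_final, n_steps=cfg.n_steps,
               control_mode=cfg.control_mode, solver=cfg.solver, seed=cfg.seed)
    if cfg.focp is not None:
        out.update(B1=cfg.focp.weights.B1, B2=cfg.focp.weights.B2,
                   delta_tol=cfg.focp.delta_tol, max_sweeps=cfg.focp.max_sweeps,
                   relaxation=cfg.focp.relaxation, v_init=cfg.focp.v_init,
                   focp_gamma2=cfg.focp.gamma2, state_solver=cfg.focp.state_solver)
    return out


def _build(mapping: dict) -> ScenarioConfig:
    unknown = set(mapping) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        params = parameters_from_mapping(
            {k: (int(mapping[k]) if k == "stem_sign" else float(mapping[k]))
             for k in _PARAM_KEYS if k in mapping})
        base = ScenarioConfig()
        state = tuple(float(mapping.get(k, d))
                      for k, d in zip(_STATE_KEYS, DEFAULT_INITIAL_STATE))
        focp = None
        control_mode = str(mapping.get("control_mode", base.control_mode))
        t_final = float(mapping.get("t_final", base.t_final))
        n_steps = int(mapping.get("n_steps", base.n_steps))
        if control_mode == "optimal" or any(k in mapping for k in _FOCP_KEYS):
            focp = FBSConfig(
                horizon=t_final, n_steps=n_steps,
                delta_tol=float(mapping.get("delta_tol", 1e-3)),
                max_sweeps=int(mapping.get("max_sweeps", 200)),
                relaxation=float(mapping.get("relaxation", 0.5)),
                v_init=float(mapping.get("v_init", 0.5)),
                weights=ControlWeights(B1=float(mapping.get("B1", 1.0)),
                                       B2=float(mapping.get("B2", 1.0))),
                gamma2=(None if mapping.get("focp_gamma2", 0.1) is None
                        else float(mapping.get("focp_gamma2", 0.1))),
                state_solver=str(mapping.get("state_solver", "l1")),
            )
        return ScenarioConfig(
            parameters=params,
            alpha=float(mapping.get("alpha", DEFAULT_ALPHA)),
            initial_state=state, t_final=t_final, n_steps=n_steps,
            control_mode=control_mode,
            solver=str(mapping.get("solver", base.solver)),
            focp=focp, seed=int(mapping.get("seed", 0)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def loads_config(text: str) -> ScenarioConfig:
    try:
        mapping = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse configuration: {exc}") from exc
    if not isinstance(mapping, dict):
        raise ConfigError("configuration must be a flat key: value mapping")
    for key, val in mapping.items():
        if isinstance(val, (dict, list)):
            raise ConfigError(f"configuration must be flat; key {key!r} is nested")
    return _build(mapping)


def load_config(path) -> ScenarioConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def dumps_config(cfg: ScenarioConfig) -> str:
    buf = io.StringIO()
    yaml.safe_dump(_flatten(cfg), buf, sort_keys=True, default_flow_style=False)
    return buf.getvalue()


def save_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_config(cfg))


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Named study scenarios over the standard fractional-order sweep.

    * ``no_chemo`` — no drug (v = 0, M0 = 0): stem cells and effectors
      left to face the tumor alone.
    * ``constant_chemo`` — fixed infusion v(t) = 0.5.
    * ``focp_default`` — optimized schedule on the desk-scale grid
      (50 days, 1000 steps, B1 = B2 = 1, drug decay 0.1/day).
    * ``focp_full_grid`` — optimized schedule on the full-fidelity
      grid (120 days at step 0.001; expensive).

    Keys are suffixed ``_aXX`` for alpha in {0.65, 0.75, 0.85, 0.95};
    bare names alias alpha = 0.95.
    """
    out: dict[str, ScenarioConfig] = {}

    def add(name: str, **kw) -> None:
        for a in ALPHA_SET:
            out[f"{name}_a{int(round(a * 100)):02d}"] = ScenarioConfig(alpha=a, **kw)
        out[name] = ScenarioConfig(alpha=DEFAULT_ALPHA, **kw)

    no_chemo_state = (2.0, 0.1, 1.0, 0.5, 0.0)
    add("no_chemo", parameters=ModelParameters(v=0.0),
        initial_state=no_chemo_state, control_mode="none")
    add("constant_chemo", parameters=ModelParameters(v=0.5), control_mode="constant")
    add("focp_default", control_mode="optimal",
        focp=FBSConfig(horizon=50.0, n_steps=1000))
    add("focp_full_grid", t_final=120.0, n_steps=120_000, control_mode="optimal",
        focp=FBSConfig(horizon=120.0, n_steps=120_000))
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Delimited-text trajectory: columns t, T, E, N, S, M[, v]."""
    df = traj.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g")


def _clean(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, np.ndarray):
        return [_clean(x) for x in v.tolist()]
    if isinstance(v, complex):
        return {"re": float(v.real), "im": float(v.imag)}
    if isinstance(v, (np.floating, np.integer)):
        return float(v)
    if isinstance(v, dict):
        return {k: _clean(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_clean(x) for x in v]
    return v


def records_to_text(records: list[dict]) -> str:
    """Structured text (YAML stream) for equilibrium/stability/UH records."""
    return yaml.safe_dump([_clean(r) for r in records], sort_keys=False)


def write_records(records: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(records_to_text(records))
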