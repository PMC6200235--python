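"""Run configuration for the attachment-excavation model.

All lengths are expressed in the same abstract unit as the domain side
length ``l`` (default 1.0).  The canonical parameter set is:

======================  ========  =======================================
key                     default   meaning
======================  ========  =======================================
``l``                   1.0       side length of the square domain
``N_x``, ``N_y``        100       lattice partitions per axis
``w_ex``                0.1 l     excavation-zone (EZ) width
``h_ex``                0.15 l    EZ total length (= 3 w_ex / 2)
``d_s``                 0.02 l    antenna sensing distance
``d_w``                 0.02 l    minimum wax thickness (= w_ex / 5)
``sigma``               0.15      EZ area fraction (worker density proxy)
``p_x``                 0.5       probability of x-direction wax growth
======================  ========  =======================================

From these the module derives the lattice cell size, the EZ translation
and rotation speeds, the analytic EZ area and the number of EZs needed to
realise the area fraction ``sigma``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "DerivedKinematics",
    "validate_config",
    "derive_kinematics",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a run configuration violates a model invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Validated model parameters (lengths in units of the domain side)."""

    l: float = 1.0
    N_x: int = 100
    N_y: int = 100
    w_ex: float = 0.1
    h_ex: float = 0.15
    d_s: float = 0.02
    d_w: float = 0.02
    sigma: float = 0.15
    p_x: float = 0.5
    seed_wax_cells: int = 1  # half-width: block side = 2*seed_wax_cells + 1
    rng_seed: int = 0
    t_max: int = 2000
    # Coefficient in the omega_ex / v_ex formulas; sqrt(2) is the diagonal
    # of a unit lattice cell.  Exposed so the literal reading "2" can be run.
    diag_coeff: float = math.sqrt(2.0)
    # None -> derived from sigma (>= 1); an explicit integer overrides it,
    # 0 giving a growth-only run.
    n_ez: int | None = None
    # Fraction of the cell size used as the ray sampling step.
    ray_step_frac: float = 0.25
    # In a FREE-FREE head-to-body collision, teleport the struck EZ
    # (figure-caption reading); False teleports the striking one instead.
    body_hit_teleports_struck: bool = True

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class DerivedKinematics:
    """Quantities derived from a :class:`SimulationConfig`."""

    dx: float
    dy: float
    v_ex: float
    omega_ex: float
    ez_area: float
    n_ez: int

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


_FIELD_NAMES = {f.name for f in fields(SimulationConfig)}


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key {key!r}: {msg}")


def validate_config(raw: Mapping[str, Any] | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a key-value mapping.

    Missing keys take the canonical defaults; unknown keys are rejected.

    Raises
    ------
    ConfigError
        If a value is out of range or the EZ geometry is degenerate.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**raw)

    _check(cfg.l > 0, "l", "domain side must be > 0")
    _check(int(cfg.N_x) == cfg.N_x and cfg.N_x > 0, "N_x", "must be a positive integer")
    _check(int(cfg.N_y) == cfg.N_y and cfg.N_y > 0, "N_y", "must be a positive integer")
    _check(cfg.N_x == cfg.N_y, "N_y", "square domain requires N_x == N_y")
    _check(cfg.w_ex > 0, "w_ex", "EZ width must be > 0")
    _check(cfg.h_ex > cfg.w_ex / 2, "h_ex",
           f"EZ length must exceed w_ex/2 = {cfg.w_ex / 2:g} (rectangle length L <= 0)")
    _check(cfg.d_s > 0, "d_s", "sensing distance must be > 0")
    _check(cfg.d_w > 0, "d_w", "minimum thickness must be > 0")
    _check(cfg.d_w < cfg.w_ex, "d_w",
           f"minimum thickness must be < w_ex = {cfg.w_ex:g} (thickness rule degenerate)")
    _check(0.0 < cfg.sigma < 1.0, "sigma", "area fraction must lie in (0, 1)")
    _check(0.5 <= cfg.p_x <= 1.0, "p_x", "growth anisotropy must lie in [0.5, 1]")
    _check(cfg.seed_wax_cells >= 0, "seed_wax_cells", "must be >= 0")
    _check(2 * cfg.seed_wax_cells + 1 <= min(cfg.N_x, cfg.N_y), "seed_wax_cells",
           "seed block larger than the lattice")
    _check(cfg.t_max >= 0, "t_max", "must be >= 0")
    _check(cfg.diag_coeff > 0, "diag_coeff", "must be > 0")
    if cfg.n_ez is not None:
        _check(int(cfg.n_ez) == cfg.n_ez and cfg.n_ez >= 0, "n_ez",
               "explicit EZ count must be a non-negative integer")
    _check(0 < cfg.ray_step_frac <= 1, "ray_step_frac", "must lie in (0, 1]")
    return cfg


def derive_kinematics(config: SimulationConfig) -> DerivedKinematics:
    """Derive cell size, EZ speeds, EZ area and EZ count from a config.

    The EZ area is that of the box-plus-semicircle shape,

        A = pi * w_ex^2 / 8 + w_ex * (h_ex - w_ex / 2),

    and the EZ count realises the area fraction ``sigma``:
    n_ez = round(sigma * l^2 / A) (half-up, at least 1 unless overridden).
    """
    dx = config.l / config.N_x
    dy = config.l / config.N_y
    L = config.h_ex - config.w_ex / 2
    ez_area = math.pi * config.w_ex ** 2 / 8 + config.w_ex * L
    omega_ex = config.diag_coeff * dx / L
    v_ex = (config.diag_coeff / 5.0) * dx
    if config.n_ez is not None:
        n_ez = int(config.n_ez)
    else:
        n_ez = max(1, math.floor(config.sigma * config.l ** 2 / ez_area + 0.5))
    return DerivedKinematics(dx=dx, dy=dy, v_ex=v_ex, omega_ex=omega_ex,
                             ez_area=ez_area, n_ez=n_ez)


def load_config(path: str) -> SimulationConfig:
    """Read a YAML (or JSON) configuration file and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path!r} must contain a mapping")
    return validate_config(raw)
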