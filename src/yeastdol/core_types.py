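"""Configuration, agent, grid and field types, plus colony initialization.

The model world is a square 2D lattice. Each site holds at most one
"cell block" — a coarse-grained agent standing in for a small group of
yeast cells — in one of two metabolic states:

* ``dark``  — gluconeogenic: takes up aspartate, budgets it between an
  internal nitrogen pool (fraction ``f``) and a carbon pool (the rest,
  converted with yield ``Y``), and leaks a fraction ``Pf`` of its carbon
  pool into the environment as trehalose.
* ``light`` — glycolytic: consumes extracellular trehalose for carbon and
  aspartate for nitrogen.

Aspartate is assumed non-limiting and is never tracked spatially; the
only extracellular state is the diffusing trehalose field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field, fields, replace

import numpy as np

DARK = "dark"
LIGHT = "light"

#: minimum carbon reserve either cell type needs before it may divide
C_MIN = 1.0
#: minimum nitrogen reserve for a dark block (light blocks need ExN times this)
N_MIN = 1.0

BOUNDARY_CONDITIONS = ("no_flux", "absorbing")
LIGHT_RULES = ("exn_on_n", "exn_on_c")


@dataclass
class SimulationConfig:
    """All model parameters plus runtime settings.

    Parameters
    ----------
    f : float
        Fraction of the dark-block aspartate flux allocated to the
        nitrogen pool, in [0, 1].
    AspU : float
        Aspartate uptake rate relative to the maximal trehalose uptake
        rate ``Cmax`` (dimensionless, >= 0).
    Y : float
        Yield converting aspartate-carbon flux into internal C units,
        in (0, 1].
    Pf : float
        Fraction of the internal C pool secreted as trehalose per time
        step, in [0, 1].
    secretion_cap : float
        Absolute upper limit on trehalose secreted by one dark block in
        one time step.
    ExN : float
        Multiplier (>= 1) on the light-block minimum nitrogen reserve.
    g : float
        Division probability per time step once reserves suffice.
    Cmax : float
        Maximal trehalose consumed by a light block per time step.
    T_DL, P_DL : float
        Dark-to-light switching threshold (trehalose units) and
        probability per time step.
    T_LD, P_LD : float
        Light-to-dark switching threshold and probability per time step.
    D_eff : float
        Scaled trehalose diffusion constant (grid lengths squared per
        time step); must satisfy the FTCS stability bound
        ``D_eff * dt / dx**2 <= 0.25`` with unit spacing.
    grid_shape : tuple of int
        Lattice dimensions (rows, columns).
    n_steps : int
        Number of time steps to simulate.
    seed : int
        RNG seed driving every stochastic choice.
    init_radius : float
        Radius (grid lengths) of the initial circular colony.
    init_dark_fraction : float
        Probability that each initial block is dark.
    boundary_condition : str
        Diffusion boundary handling, ``no_flux`` or ``absorbing``.
    light_rule : str
        Which reserve the light-block ExN multiplier scales:
        ``exn_on_n`` (default; C >= 1, N >= ExN) or the alternative
        ``exn_on_c`` (C >= ExN, N >= 1) kept for sensitivity checks.
    """

    f: float = 0.125
    AspU: float = 4.0
    Y: float = 0.31
    Pf: float = 0.049
    secretion_cap: float = 0.12
    ExN: float = 4.0
    g: float = 0.04
    Cmax: float = 0.05
    T_DL: float = 1.5
    P_DL: float = 0.5
    T_LD: float = 1e-4
    P_LD: float = 1e-4
    D_eff: float = 0.24
    grid_shape: tuple[int, int] = (201, 201)
    n_steps: int = 750
    seed: int = 0
    init_radius: float = 20.0
    init_dark_fraction: float = 0.97
    boundary_condition: str = "no_flux"
    light_rule: str = "exn_on_n"

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


CONFIG_KEYS = tuple(fld.name for fld in fields(SimulationConfig))


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


class StabilityError(ConfigError):
    """The FTCS stability criterion D_eff * dt / dx**2 <= 0.25 is violated."""


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {message}")


def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Check every invariant; return ``cfg`` unchanged if all hold.

    Raises
    ------
    ConfigError
        Naming the offending field, for any out-of-range value.
    StabilityError
        If the explicit diffusion scheme would be unstable.
    """
    _require(0.0 <= cfg.f <= 1.0, "f", f"must lie in [0, 1], got {cfg.f}")
    _require(cfg.AspU >= 0.0, "AspU", f"must be >= 0, got {cfg.AspU}")
    _require(0.0 < cfg.Y <= 1.0, "Y", f"must lie in (0, 1], got {cfg.Y}")
    _require(0.0 <= cfg.Pf <= 1.0, "Pf", f"must lie in [0, 1], got {cfg.Pf}")
    _require(cfg.secretion_cap >= 0.0, "secretion_cap",
             f"must be >= 0, got {cfg.secretion_cap}")
    _require(cfg.ExN >= 1.0, "ExN", f"must be >= 1, got {cfg.ExN}")
    for name in ("g", "P_DL", "P_LD", "init_dark_fraction"):
        value = getattr(cfg, name)
        _require(0.0 <= value <= 1.0, name,
                 f"is a probability and must lie in [0, 1], got {value}")
    _require(cfg.Cmax > 0.0, "Cmax", f"must be > 0, got {cfg.Cmax}")
    _require(cfg.T_DL > cfg.T_LD > 0.0, "T_DL/T_LD",
             f"thresholds must satisfy T_DL > T_LD > 0, "
             f"got T_DL={cfg.T_DL}, T_LD={cfg.T_LD}")
    if cfg.D_eff < 0.0:
        raise ConfigError(f"D_eff: must be >= 0, got {cfg.D_eff}")
    # dt = dx = 1 by construction of the scaled diffusion constant
    if cfg.D_eff > 0.25:
        raise StabilityError(
            f"D_eff: FTCS stability requires D_eff * dt / dx**2 <= 0.25 "
            f"with dt = dx = 1, got {cfg.D_eff}")
    shape = tuple(cfg.grid_shape)
    _require(len(shape) == 2 and all(isinstance(s, int) and s > 0 for s in shape),
             "grid_shape", f"must be a pair of positive integers, got {cfg.grid_shape}")
    _require(int(cfg.n_steps) == cfg.n_steps and cfg.n_steps >= 0,
             "n_steps", f"must be a non-negative integer, got {cfg.n_steps}")
    _require(cfg.init_radius >= 0.0, "init_radius",
             f"must be >= 0, got {cfg.init_radius}")
    _require(cfg.boundary_condition in BOUNDARY_CONDITIONS, "boundary_condition",
             f"must be one of {BOUNDARY_CONDITIONS}, got {cfg.boundary_condition!r}")
    _require(cfg.light_rule in LIGHT_RULES, "light_rule",
             f"must be one of {LIGHT_RULES}, got {cfg.light_rule!r}")
    return cfg


class CellBlock:
    """One lattice agent with a metabolic state and internal C/N pools."""

    __slots__ = ("state", "x", "y", "C", "N", "last_division_step")

    def __init__(self, state: str, x: int, y: int,
                 C: float = 0.0, N: float = 0.0,
                 last_division_step: int | None = None):
        self.state = state
        self.x = x
        self.y = y
        self.C = C
        self.N = N
        self.last_division_step = last_division_step

    @property
    def position(self) -> tuple[int, int]:
        return (self.x, self.y)

    def copy(self) -> "CellBlock":
        return CellBlock(self.state, self.x, self.y, self.C, self.N,
                         self.last_division_step)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"CellBlock({self.state!r}, x={self.x}, y={self.y}, "
                f"C={self.C:.6g}, N={self.N:.6g})")


class ColonyGrid:
    """Occupancy map: each lattice site holds at most one block."""

    def __init__(self, shape: tuple[int, int]):
        self.shape = tuple(shape)
        self._occupancy: dict[tuple[int, int], CellBlock] = {}

    def __len__(self) -> int:
        return len(self._occupancy)

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.shape[0] and 0 <= y < self.shape[1]

    def is_occupied(self, x: int, y: int) -> bool:
        return (x, y) in self._occupancy

    def block_at(self, x: int, y: int) -> CellBlock | None:
        return self._occupancy.get((x, y))

    def place(self, block: CellBlock) -> None:
        key = (block.x, block.y)
        if not self.in_bounds(*key):
            raise ValueError(f"site {key} outside grid {self.shape}")
        if key in self._occupancy:
            raise ValueError(f"site {key} is already occupied")
        self._occupancy[key] = block

    def blocks(self) -> list[CellBlock]:
        return list(self._occupancy.values())


class TrehaloseField:
    """Non-negative trehalose concentration per lattice site."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("field must be a 2D array")
        if np.any(self.values < 0):
            raise ValueError("field entries must be non-negative")

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "TrehaloseField":
        return cls(np.zeros(shape, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "TrehaloseField":
        return TrehaloseField(self.values.copy())


def grid_center(shape: tuple[int, int]) -> tuple[int, int]:
    """Center lattice site: the midpoint rounded down for even extents."""
    return ((shape[0] - 1) // 2, (shape[1] - 1) // 2)


def disk_sites(center: tuple[int, int], radius: float) -> list[tuple[int, int]]:
    """Integer lattice sites within Euclidean distance ``radius`` of center."""
    cx, cy = center
    r = int(math.floor(radius))
    out = []
    r2 = radius * radius
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            if dx * dx + dy * dy <= r2:
                out.append((cx + dx, cy + dy))
    return out


def initialize_colony(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ColonyGrid, TrehaloseField, list[CellBlock]]:
    """Seed an approximately circular colony at the grid center.

    One block is placed at every lattice site within ``init_radius`` of
    the center; each is independently dark with probability
    ``init_dark_fraction``, otherwise light. All internal pools start at
    zero and the trehalose field is identically zero. With the default
    radius of 20 grid lengths this places 1257 blocks.
    """
    shape = tuple(cfg.grid_shape)
    center = grid_center(shape)
    sites = disk_sites(center, cfg.init_radius)
    for (x, y) in sites:
        if not (0 <= x < shape[0] and 0 <= y < shape[1]):
            raise ConfigError(
                f"init_radius: disk of radius {cfg.init_radius} at {center} "
                f"does not fit inside grid {shape}")
    grid = ColonyGrid(shape)
    blocks: list[CellBlock] = []
    draws = rng.random(len(sites))
    for (x, y), u in zip(sites, draws):
        state = DARK if u < cfg.init_dark_fraction else LIGHT
        block = CellBlock(state, x, y)
        grid.place(block)
        blocks.append(block)
    return grid, TrehaloseField.zeros(shape), blocks
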