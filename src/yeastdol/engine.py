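"""Simulation engine: seeded runs, per-step agent sweep, diffusion.

Each time step processes every existing block exactly once, in a fresh
uniform-random order (a fixed raster order would bias growth). For each
block: the switching check, then the metabolic update with the field at
the block's own site adjusted immediately, then the division attempt
(eligibility, the ``g`` draw, site choice). Daughters are inserted into
the grid at once but are not processed again until the next step. After
the sweep the trehalose field diffuses by one FTCS step.

A single seeded RNG drives every draw in a documented order, so a run
is bit-for-bit reproducible from (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .cell_dynamics import (choose_division_site, dark_metabolic_update,
                            eligible_to_divide, light_metabolic_update,
                            perform_division, try_switch_dark_to_light,
                            try_switch_light_to_dark)
from .core_types import (DARK, LIGHT, CellBlock, ColonyGrid, SimulationConfig,
                         TrehaloseField, grid_center, initialize_colony,
                         validate_config)
from .diffusion import StencilParams, ftcs_values


class BoundaryContactWarning(UserWarning):
    """The colony reached the outermost grid ring; growth is now confined."""


class BoundaryContactError(RuntimeError):
    """Raised instead of the warning when on_boundary='abort'."""


@dataclass
class SummaryRecord:
    """Per-step colony aggregates."""

    step: int
    n_dark: int
    n_light: int
    total_extracellular_trehalose: float
    colony_radius: float
    n_divisions_dark: int = 0
    n_divisions_light: int = 0
    n_blocks_at_secretion_cap: int = 0

    @property
    def n_blocks(self) -> int:
        return self.n_dark + self.n_light


@dataclass
class Snapshot:
    """Full colony state at one step, in array form."""

    step: int
    x: np.ndarray
    y: np.ndarray
    state: np.ndarray  # strings 'dark' / 'light'
    C: np.ndarray
    N: np.ndarray
    field: np.ndarray
    grid_shape: tuple[int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.x)


@dataclass
class Trajectory:
    """Outcome of one simulation: per-step records plus optional snapshots."""

    config: SimulationConfig
    seed: int
    records: list[SummaryRecord]
    snapshots: list[Snapshot] = dataclass_field(default_factory=list)
    division_intervals: dict[str, list[int]] = dataclass_field(
        default_factory=lambda: {DARK: [], LIGHT: []})

    @property
    def final_record(self) -> SummaryRecord:
        return self.records[-1]

    @property
    def final_snapshot(self) -> Snapshot | None:
        return self.snapshots[-1] if self.snapshots else None

    def records_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class SimState:
    """Mutable simulation state threaded through ``step``."""

    grid: ColonyGrid
    field: TrehaloseField
    blocks: list[CellBlock]
    step: int = 0
    n_dark: int = 0
    n_light: int = 0
    colony_radius: float = 0.0
    boundary_reached: bool = False


def _distance_from_center(x: int, y: int, shape: tuple[int, int]) -> float:
    cx, cy = grid_center(shape)
    return math.hypot(x - cx, y - cy)


def _on_outer_ring(x: int, y: int, shape: tuple[int, int]) -> bool:
    return x == 0 or y == 0 or x == shape[0] - 1 or y == shape[1] - 1


def make_initial_state(cfg: SimulationConfig,
                       rng: np.random.Generator) -> SimState:
    grid, field, blocks = initialize_colony(cfg, rng)
    state = SimState(grid=grid, field=field, blocks=blocks)
    state.n_dark = sum(1 for b in blocks if b.state == DARK)
    state.n_light = len(blocks) - state.n_dark
    shape = grid.shape
    state.colony_radius = max(
        (_distance_from_center(b.x, b.y, shape) for b in blocks), default=0.0)
    return state


def step(state: SimState, cfg: SimulationConfig, rng: np.random.Generator,
         on_boundary: str = "warn",
         trajectory: Trajectory | None = None) -> SummaryRecord:
    """Advance the state by one time step; returns the step's record.

    ``on_boundary`` is ``'warn'`` (default) or ``'abort'``: what to do
    the first time a daughter lands on the outermost grid ring. When a
    ``trajectory`` is given, inter-division intervals are appended to it.
    """
    state.step += 1
    now = state.step
    grid, field, blocks = state.grid, state.field, state.blocks
    values = field.values
    shape = grid.shape
    n_div_dark = n_div_light = n_capped = 0

    n_existing = len(blocks)
    order = rng.permutation(n_existing) if n_existing else ()
    for idx in order:
        block = blocks[idx]
        x, y = block.x, block.y
        local = values[x, y]
        if block.state == DARK:
            if try_switch_dark_to_light(block, local, cfg, rng):
                state.n_dark -= 1
                state.n_light += 1
                continue
            secreted = dark_metabolic_update(block, cfg)
            if secreted:
                values[x, y] = local + secreted
                if secreted >= cfg.secretion_cap:
                    n_capped += 1
        else:
            if try_switch_light_to_dark(block, local, cfg, rng):
                state.n_light -= 1
                state.n_dark += 1
                continue
            consumed = light_metabolic_update(block, local, cfg)
            if consumed:
                values[x, y] = local - consumed

        if eligible_to_divide(block, cfg) and rng.random() < cfg.g:
            site = choose_division_site((block.x, block.y), grid, rng)
            if site is None:
                continue
            prev = block.last_division_step
            daughter = perform_division(block, site, now)
            grid.place(daughter)
            blocks.append(daughter)
            if daughter.state == DARK:
                state.n_dark += 1
                n_div_dark += 1
            else:
                state.n_light += 1
                n_div_light += 1
            if trajectory is not None and prev is not None:
                trajectory.division_intervals[daughter.state].append(now - prev)
            dist = _distance_from_center(site[0], site[1], shape)
            if dist > state.colony_radius:
                state.colony_radius = dist
            if not state.boundary_reached and _on_outer_ring(*site, shape):
                state.boundary_reached = True
                msg = (f"colony reached the grid boundary at step {now} "
                       f"(site {site}); growth is now confined")
                if on_boundary == "abort":
                    raise BoundaryContactError(msg)
                warnings.warn(msg, BoundaryContactWarning, stacklevel=2)

    params = StencilParams(cfg.D_eff,
                           boundary_condition=cfg.boundary_condition)
    field.values = ftcs_values(values, params)

    return SummaryRecord(
        step=now,
        n_dark=state.n_dark,
        n_light=state.n_light,
        total_extracellular_trehalose=float(field.values.sum()),
        colony_radius=state.colony_radius,
        n_divisions_dark=n_div_dark,
        n_divisions_light=n_div_light,
        n_blocks_at_secretion_cap=n_capped,
    )


def take_snapshot(state: SimState) -> Snapshot:
    blocks = state.blocks
    n = len(blocks)
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    st = np.empty(n, dtype=object)
    c = np.empty(n, dtype=np.float64)
    nn = np.empty(n, dtype=np.float64)
    for i, b in enumerate(blocks):
        x[i], y[i], st[i], c[i], nn[i] = b.x, b.y, b.state, b.C, b.N
    return Snapshot(step=state.step, x=x, y=y, state=st, C=c, N=nn,
                    field=state.field.values.copy(),
                    grid_shape=state.grid.shape)


def run(cfg: SimulationConfig, snapshot_every: int | None = None,
        on_boundary: str = "warn", keep_final_snapshot: bool = True,
        progress: bool = False) -> Trajectory:
    """Run a full simulation from a validated config.

    Records one :class:`SummaryRecord` per step including step 0
    (``n_steps + 1`` records in total). Snapshots are kept every
    ``snapshot_every`` steps if given; the final state is always
    snapshotted unless ``keep_final_snapshot`` is False.
    """
    validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    state = make_initial_state(cfg, rng)
    trajectory = Trajectory(config=cfg, seed=cfg.seed, records=[])
    trajectory.records.append(SummaryRecord(
        step=0, n_dark=state.n_dark, n_light=state.n_light,
        total_extracellular_trehalose=float(state.field.values.sum()),
        colony_radius=state.colony_radius))
    if snapshot_every:
        trajectory.snapshots.append(take_snapshot(state))

    steps = range(1, cfg.n_steps + 1)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            steps = tqdm(steps, desc="simulating")
        except ImportError:
            pass
    for t in steps:
        record = step(state, cfg, rng, on_boundary=on_boundary,
                      trajectory=trajectory)
        trajectory.records.append(record)
        if snapshot_every and t % snapshot_every == 0:
            trajectory.snapshots.append(take_snapshot(state))
    if keep_final_snapshot and (
            not trajectory.snapshots
            or trajectory.snapshots[-1].step != state.step):
        trajectory.snapshots.append(take_snapshot(state))
    return trajectory
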