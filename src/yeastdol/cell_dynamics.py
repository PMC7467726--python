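"""Per-block update rules: switching, metabolism, division.

Each time step a block is processed once, in this order:

1. switching check (dark->light above ``T_DL``; light->dark below
   ``T_LD``) — a block that switches does nothing else this step;
2. metabolic update — a dark block takes up ``AspU * Cmax`` aspartate,
   routes fraction ``f`` to nitrogen and the rest to carbon with yield
   ``Y``, then secretes ``Pf`` of its carbon pool as trehalose (capped
   at ``secretion_cap``); a light block consumes local trehalose up to
   ``Cmax`` for carbon and gains ``AspU * Cmax`` nitrogen;
3. division — once C and N reserves reach the state-specific minima the
   block divides with probability ``g`` into an empty 4-neighbor site,
   preferring the candidate with the most occupied neighbors, each
   daughter inheriting half the mother's pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import (C_MIN, DARK, LIGHT, N_MIN, CellBlock, ColonyGrid,
                         SimulationConfig)

NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class UpdateOutcome:
    """Effects of one algorithm pass for one block."""

    block_after: CellBlock
    secreted: float = 0.0
    consumed_trehalose: float = 0.0
    switched: bool = False
    divided: bool = False
    daughter: CellBlock | None = None


def try_switch_dark_to_light(block: CellBlock, local_trehalose: float,
                             cfg: SimulationConfig,
                             rng: np.random.Generator) -> bool:
    """Dark block switches to light iff local trehalose exceeds T_DL and
    a uniform draw falls below P_DL. Pools are retained across the switch.
    The random draw is consumed only when the threshold condition holds.
    """
    if local_trehalose > cfg.T_DL and rng.random() < cfg.P_DL:
        block.state = LIGHT
        return True
    return False


def try_switch_light_to_dark(block: CellBlock, local_trehalose: float,
                             cfg: SimulationConfig,
                             rng: np.random.Generator) -> bool:
    """Light block switches to dark iff local trehalose is below T_LD and
    a uniform draw falls below P_LD."""
    if local_trehalose < cfg.T_LD and rng.random() < cfg.P_LD:
        block.state = DARK
        return True
    return False


def dark_metabolic_update(block: CellBlock, cfg: SimulationConfig) -> float:
    """Aspartate budgeting and trehalose secretion for a dark block.

    The block consumes ``AspU * Cmax`` aspartate: fraction ``f`` is added
    to the N pool directly, the remaining ``1 - f`` is converted to C
    with yield ``Y``. From the updated C pool a fraction ``Pf`` is
    secreted as trehalose, limited by ``secretion_cap``, and deducted
    from the pool. Returns the secreted amount (the caller adds it to
    the field at the block's site).
    """
    uptake = cfg.AspU * cfg.Cmax
    block.N += cfg.f * uptake
    c_tmp = block.C + (1.0 - cfg.f) * uptake * cfg.Y
    secreted = min(cfg.Pf * c_tmp, cfg.secretion_cap)
    block.C = c_tmp - secreted
    return secreted


def light_metabolic_update(block: CellBlock, local_trehalose: float,
                           cfg: SimulationConfig) -> float:
    """Trehalose and aspartate consumption for a light block.

    Consumes all local trehalose up to ``Cmax`` into the C pool and
    gains ``AspU * Cmax`` nitrogen (aspartate is non-limiting). Returns
    the trehalose consumed (the caller removes it from the field).
    """
    consumed = min(local_trehalose, cfg.Cmax)
    block.C += consumed
    block.N += cfg.AspU * cfg.Cmax
    return consumed


def eligible_to_divide(block: CellBlock, cfg: SimulationConfig) -> bool:
    """Reserve check before the division draw.

    Dark blocks need C >= 1 and N >= 1. Light blocks need the same
    carbon minimum but ExN times the nitrogen (their higher nucleotide
    synthesis rate); the ``exn_on_c`` rule variant instead scales the
    carbon minimum.
    """
    if block.state == DARK:
        return block.C >= C_MIN and block.N >= N_MIN
    if cfg.light_rule == "exn_on_c":
        return block.C >= cfg.ExN * C_MIN and block.N >= N_MIN
    return block.C >= C_MIN and block.N >= cfg.ExN * N_MIN


def choose_division_site(position: tuple[int, int], grid: ColonyGrid,
                         rng: np.random.Generator) -> tuple[int, int] | None:
    """Pick an empty 4-neighbor site for the daughter, or None.

    Among empty in-bounds neighbors, the one with the most occupied
    4-neighbors is preferred; ties are broken uniformly at random.
    """
    x, y = position
    best: list[tuple[int, int]] = []
    best_count = -1
    for dx, dy in NEIGHBOR_OFFSETS:
        nx, ny = x + dx, y + dy
        if not grid.in_bounds(nx, ny) or grid.is_occupied(nx, ny):
            continue
        count = 0
        for ddx, ddy in NEIGHBOR_OFFSETS:
            if grid.is_occupied(nx + ddx, ny + ddy):
                count += 1
        if count > best_count:
            best = [(nx, ny)]
            best_count = count
        elif count == best_count:
            best.append((nx, ny))
    if not best:
        return None
    if len(best) == 1:
        return best[0]
    return best[int(rng.integers(len(best)))]


def perform_division(block: CellBlock, site: tuple[int, int],
                     step: int) -> CellBlock:
    """Split the mother in place; return the daughter at ``site``.

    Each of the two resulting blocks carries half the mother's
    pre-division C and N pools and the mother's state.
    """
    half_c = block.C / 2.0
    half_n = block.N / 2.0
    block.C = half_c
    block.N = half_n
    block.last_division_step = step
    return CellBlock(block.state, site[0], site[1], half_c, half_n,
                     last_division_step=step)


def update_block(block: CellBlock, local_trehalose: float,
                 cfg: SimulationConfig,
                 rng: np.random.Generator) -> UpdateOutcome:
    """Switching plus metabolism for one block (division is handled by
    the engine, which owns grid occupancy)."""
    if block.state == DARK:
        if try_switch_dark_to_light(block, local_trehalose, cfg, rng):
            return UpdateOutcome(block, switched=True)
        secreted = dark_metabolic_update(block, cfg)
        return UpdateOutcome(block, secreted=secreted)
    if try_switch_light_to_dark(block, local_trehalose, cfg, rng):
        return UpdateOutcome(block, switched=True)
    consumed = light_metabolic_update(block, local_trehalose, cfg)
    return UpdateOutcome(block, consumed_trehalose=consumed)
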