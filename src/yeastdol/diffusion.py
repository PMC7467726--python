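"""Explicit FTCS diffusion of the extracellular trehalose field.

One forward-time centered-space step with unit grid spacing and unit
time step:

    u'(x, y) = u(x, y) + D_eff * (u(x+1, y) + u(x-1, y)
                                  + u(x, y+1) + u(x, y-1) - 4 u(x, y))

Stability (and hence positivity preservation) requires
``D_eff * dt / dx**2 <= 0.25``. The boundary is handled either by edge
replication (``no_flux``: zero normal gradient, conserves total mass)
or by zero padding (``absorbing``: mass leaks out at the rim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import BOUNDARY_CONDITIONS, StabilityError, TrehaloseField


@dataclass(frozen=True)
class StencilParams:
    D_eff: float
    dt: float = 1.0
    dx: float = 1.0
    boundary_condition: str = "no_flux"

    @property
    def coefficient(self) -> float:
        return self.D_eff * self.dt / (self.dx * self.dx)


def _check(p: StencilParams) -> float:
    if p.boundary_condition not in BOUNDARY_CONDITIONS:
        raise ValueError(f"unknown boundary condition {p.boundary_condition!r}")
    r = p.coefficient
    if r > 0.25:
        raise StabilityError(
            f"FTCS requires D_eff * dt / dx**2 <= 0.25, got {r}")
    return r


def ftcs_values(values: np.ndarray, p: StencilParams) -> np.ndarray:
    """One FTCS step on a raw 2D array (used by the engine's inner loop)."""
    r = _check(p)
    mode = "edge" if p.boundary_condition == "no_flux" else "constant"
    padded = np.pad(values, 1, mode=mode)
    lap = (padded[:-2, 1:-1] + padded[2:, 1:-1]
           + padded[1:-1, :-2] + padded[1:-1, 2:]
           - 4.0 * values)
    return values + r * lap


def ftcs_step(field: TrehaloseField, p: StencilParams) -> TrehaloseField:
    """One FTCS step on a trehalose field; returns a new field."""
    return TrehaloseField(ftcs_values(field.values, p))


def total_mass(field: TrehaloseField | np.ndarray) -> float:
    """Sum of all field entries (conserved under no-flux diffusion)."""
    values = field.values if isinstance(field, TrehaloseField) else field
    return float(np.sum(values))
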