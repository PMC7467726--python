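"""Colony observables and (f, AspU) parameter sweeps.

These are pure functions of trajectories and snapshots: computing a
metric never mutates a stored run. The sweeps rerun the simulator over
a parameter grid with shared seeds across values, so regime comparisons
(colony size, light fraction) are paired per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_types import DARK, LIGHT, SimulationConfig, grid_center
from .engine import Snapshot, SummaryRecord, Trajectory, run

#: sweep grids covering the documented regimes
DEFAULT_F_VALUES = (0.0, 0.125, 0.25, 0.5, 0.75, 1.0)
DEFAULT_ASPU_VALUES = (1.0, 2.0, 4.0, 6.0, 8.0)


def light_fraction(record: SummaryRecord) -> float:
    """Share of blocks in the light state, n_light / (n_dark + n_light)."""
    total = record.n_dark + record.n_light
    if total == 0:
        raise ValueError("light_fraction is undefined for an empty colony")
    return record.n_light / total


def secretion_cap_fraction(record: SummaryRecord) -> float | None:
    """Fraction of dark blocks that hit the secretion cap this step,
    or None when there are no dark blocks."""
    if record.n_dark == 0:
        return None
    return record.n_blocks_at_secretion_cap / record.n_dark


def mean_secretion_cap_fraction(trajectory: Trajectory) -> float | None:
    """Run-averaged fraction of dark blocks at the secretion cap."""
    per_step = [f for r in trajectory.records[1:]
                if (f := secretion_cap_fraction(r)) is not None]
    return float(np.mean(per_step)) if per_step else None


def radial_state_profile(snapshot: Snapshot, n_bins: int) -> pd.DataFrame:
    """Bin blocks by distance from the grid center into equal-width annuli.

    Returns a frame with one row per annulus: bin index, inner/outer
    radius, and dark/light block counts. Counts across bins sum to the
    snapshot's block count.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if snapshot.n_blocks == 0:
        raise ValueError("radial profile of an empty snapshot is undefined")
    cx, cy = grid_center(snapshot.grid_shape)
    r = np.hypot(snapshot.x - cx, snapshot.y - cy)
    r_max = float(r.max())
    width = r_max / n_bins if r_max > 0 else 1.0
    idx = np.minimum((r / width).astype(np.int64), n_bins - 1)
    is_light = snapshot.state == LIGHT
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin": b,
            "r_inner": b * width,
            "r_outer": (b + 1) * width,
            "n_dark": int(np.sum(mask & ~is_light)),
            "n_light": int(np.sum(mask & is_light)),
        })
    return pd.DataFrame(rows)


def division_interval_stats(trajectory: Trajectory) -> dict[str, dict | None]:
    """Mean and spread of steps between consecutive divisions, per state.

    A state with no recorded inter-division intervals maps to None.
    """
    out: dict[str, dict | None] = {}
    for state in (DARK, LIGHT):
        intervals = trajectory.division_intervals.get(state, [])
        if not intervals:
            out[state] = None
        else:
            arr = np.asarray(intervals, dtype=float)
            out[state] = {
                "mean": float(arr.mean()),
                "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n": int(len(arr)),
            }
    return out


@dataclass
class SweepResult:
    """Completed runs over one parameter axis, seeds shared across values."""

    parameter: str
    values: tuple[float, ...]
    seeds: tuple[int, ...]
    runs: pd.DataFrame  # one row per (value, seed)
    summary: pd.DataFrame  # per-value mean/std of size and light fraction


def _sweep(cfg: SimulationConfig, parameter: str, values, seeds,
           progress: bool = False) -> SweepResult:
    rows = []
    for value in values:
        for seed in seeds:
            run_cfg = cfg.replace(**{parameter: value, "seed": int(seed)})
            trajectory = run(run_cfg, keep_final_snapshot=False,
                             progress=progress)
            final = trajectory.final_record
            rows.append({
                "param_value": value,
                "seed": int(seed),
                "final_n_dark": final.n_dark,
                "final_n_light": final.n_light,
                "final_n_blocks": final.n_blocks,
                "final_light_fraction": light_fraction(final),
                "final_total_trehalose": final.total_extracellular_trehalose,
                "colony_radius": final.colony_radius,
            })
    runs = pd.DataFrame(rows)
    summary = (runs.groupby("param_value")
               .agg(mean_n_blocks=("final_n_blocks", "mean"),
                    std_n_blocks=("final_n_blocks", "std"),
                    mean_light_fraction=("final_light_fraction", "mean"),
                    std_light_fraction=("final_light_fraction", "std"))
               .reset_index())
    return SweepResult(parameter=parameter, values=tuple(values),
                       seeds=tuple(int(s) for s in seeds), runs=runs,
                       summary=summary)


def sweep_f(cfg: SimulationConfig, values=DEFAULT_F_VALUES,
            seeds=(0, 1, 2, 3, 4), progress: bool = False) -> SweepResult:
    """Vary the nitrogen-allocation fraction f at fixed run length."""
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError("f values must lie in [0, 1]")
    return _sweep(cfg, "f", values, seeds, progress=progress)


def sweep_aspu(cfg: SimulationConfig, values=DEFAULT_ASPU_VALUES,
               seeds=(0, 1, 2, 3, 4), progress: bool = False) -> SweepResult:
    """Vary the relative aspartate uptake rate AspU at fixed run length."""
    if any(v <= 0.0 for v in values):
        raise ValueError("AspU values must be positive")
    return _sweep(cfg, "AspU", values, seeds, progress=progress)


# colors for rendered colonies: empty agar, dark blocks, light blocks
_BACKGROUND = (210, 200, 180)
_DARK_COLOR = (60, 40, 90)
_LIGHT_COLOR = (250, 240, 150)


def colony_image(snapshot: Snapshot) -> np.ndarray:
    """RGB array with one pixel per lattice site."""
    img = np.empty((*snapshot.grid_shape, 3), dtype=np.uint8)
    img[:] = _BACKGROUND
    is_light = snapshot.state == LIGHT
    img[snapshot.x[~is_light], snapshot.y[~is_light]] = _DARK_COLOR
    img[snapshot.x[is_light], snapshot.y[is_light]] = _LIGHT_COLOR
    return img


def render_colony(snapshot: Snapshot, path, scale: int = 3) -> None:
    """Write a raster image of the colony (dark blocks dark, light
    blocks light, empty sites background)."""
    from PIL import Image

    img = colony_image(snapshot)
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    Image.fromarray(img).save(path)
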