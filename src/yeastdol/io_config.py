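"""Configuration files, snapshot readers/writers, summaries, manifests.

On-disk formats are all plain text:

* config — flat YAML key/value, keys named after the model symbols
  (``f``, ``AspU``, ``Y``, ``Pf``, ``ExN``, ``g``, ``Cmax``, ``T_DL``,
  ``P_DL``, ``T_LD``, ``P_LD``, ``D_eff``, ``secretion_cap``) plus
  runtime keys; unknown keys are rejected.
* agents — CSV with columns (step, x, y, state, C, N), floats printed
  at 17 significant digits so round-trips are bit-stable.
* field — whitespace-delimited matrix, one row per grid row, same
  precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_types import (CONFIG_KEYS, CellBlock, ColonyGrid, ConfigError,
                         SimulationConfig, TrehaloseField, validate_config)
from .engine import SimState, Snapshot, Trajectory

FLOAT_FMT = "%.17g"
AGENT_COLUMNS = ("step", "x", "y", "state", "C", "N")


def load_config(path) -> SimulationConfig:
    """Read a YAML config file; unspecified keys take the model defaults.

    Raises a :class:`ConfigError` on unknown keys or out-of-range values.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of keys to values")
    unknown = sorted(set(raw) - set(CONFIG_KEYS))
    if unknown:
        raise ConfigError(
            f"{path}: unknown keys {unknown}; valid keys are {sorted(CONFIG_KEYS)}")
    if "grid_shape" in raw:
        shape = raw["grid_shape"]
        try:
            raw["grid_shape"] = (int(shape[0]), int(shape[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise ConfigError(
                f"grid_shape: expected a pair of integers, got {shape!r}") from exc
    cfg = SimulationConfig(**raw)
    return validate_config(cfg)


def save_config(cfg: SimulationConfig, path) -> Path:
    """Write the fully resolved configuration (including seed) as YAML."""
    path = Path(path)
    data = dataclasses.asdict(cfg)
    data["grid_shape"] = list(cfg.grid_shape)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def _agents_path(directory: Path, step: int) -> Path:
    return directory / f"agents_{step}.csv"


def _field_path(directory: Path, step: int) -> Path:
    return directory / f"field_{step}.txt"


def write_snapshot(snapshot: Snapshot, directory) -> list[Path]:
    """Write one snapshot as an agents CSV plus a field matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    agents = pd.DataFrame({
        "step": np.full(snapshot.n_blocks, snapshot.step, dtype=np.int64),
        "x": snapshot.x,
        "y": snapshot.y,
        "state": snapshot.state,
        "C": snapshot.C,
        "N": snapshot.N,
    })
    apath = _agents_path(directory, snapshot.step)
    agents.to_csv(apath, index=False, float_format=FLOAT_FMT)
    fpath = _field_path(directory, snapshot.step)
    np.savetxt(fpath, snapshot.field, fmt=FLOAT_FMT)
    return [apath, fpath]


def read_snapshot(directory, step: int) -> Snapshot:
    """Read a snapshot back; validates columns and field non-negativity."""
    directory = Path(directory)
    apath = _agents_path(directory, step)
    fpath = _field_path(directory, step)
    for p in (apath, fpath):
        if not p.exists():
            raise FileNotFoundError(f"missing snapshot file {p}")
    agents = pd.read_csv(apath, float_precision="round_trip")
    if tuple(agents.columns) != AGENT_COLUMNS:
        raise ValueError(
            f"{apath}: expected columns {AGENT_COLUMNS}, got {tuple(agents.columns)}")
    field = np.loadtxt(fpath, ndmin=2)
    if np.any(field < 0):
        raise ValueError(f"{fpath}: field entries must be non-negative")
    return Snapshot(
        step=step,
        x=agents["x"].to_numpy(np.int64),
        y=agents["y"].to_numpy(np.int64),
        state=agents["state"].to_numpy(object),
        C=agents["C"].to_numpy(np.float64),
        N=agents["N"].to_numpy(np.float64),
        field=field,
        grid_shape=field.shape,
    )


def state_from_snapshot(snapshot: Snapshot) -> SimState:
    """Rebuild a runnable simulation state from a snapshot (resume/analyze)."""
    grid = ColonyGrid(snapshot.grid_shape)
    blocks = []
    for x, y, st, c, n in zip(snapshot.x, snapshot.y, snapshot.state,
                              snapshot.C, snapshot.N):
        block = CellBlock(str(st), int(x), int(y), float(c), float(n))
        grid.place(block)
        blocks.append(block)
    state = SimState(grid=grid, field=TrehaloseField(snapshot.field.copy()),
                     blocks=blocks, step=snapshot.step)
    state.n_dark = sum(1 for b in blocks if b.state == "dark")
    state.n_light = len(blocks) - state.n_dark
    from .engine import _distance_from_center

    state.colony_radius = max(
        (_distance_from_center(b.x, b.y, grid.shape) for b in blocks),
        default=0.0)
    return state


def write_summary(trajectory: Trajectory, path) -> Path:
    """One SummaryRecord per row, headers as the record field names."""
    path = Path(path)
    trajectory.records_frame().to_csv(path, index=False,
                                      float_format=FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: SimulationConfig, directory, files,
                   start_step: int = 0, end_step: int | None = None) -> Path:
    """Write a JSON run manifest with config, seed and file checksums."""
    from . import __version__

    directory = Path(directory)
    data = dataclasses.asdict(cfg)
    data["grid_shape"] = list(cfg.grid_shape)
    manifest = {
        "config": data,
        "seed": cfg.seed,
        "package_version": __version__,
        "start_step": start_step,
        "end_step": cfg.n_steps if end_step is None else end_step,
        "files": {Path(p).name: _sha256(Path(p)) for p in files},
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_run(trajectory: Trajectory, directory) -> Path:
    """Write a complete run directory: summary, snapshots, config, manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = [write_summary(trajectory, directory / "summary.csv")]
    for snap in trajectory.snapshots:
        files.extend(write_snapshot(snap, directory))
    files.append(save_config(trajectory.config,
                             directory / "config_resolved.yaml"))
    write_manifest(trajectory.config, directory, files)
    return directory
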