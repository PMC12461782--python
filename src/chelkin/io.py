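"""Plain-text readers/writers for the pipeline's file formats.

* COLVAR-style trajectories: whitespace columns with a ``#! FIELDS``
  header naming them (time lig_coord wat_coord); times must be
  monotonic, dt is inferred from the deltas.
* Free-energy grids: ``#`` headers per axis (name, min, bin width,
  count) followed by one value per line in row-major order with the
  ligand axis fastest-varying; unvisited cells are written as ``inf``.
* Species levels: delimited table with columns species, n_lig,
  delta_g_kj_mol, sigma_kj_mol.
* Reports: JSON with sorted keys (byte-stable for fixed inputs).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .equilibrium import FreeEnergySurface, SpeciesLevels
from .msm import CoordTrajectory

__all__ = [
    "read_colvar",
    "write_colvar",
    "read_colvar_glob",
    "read_fes_grid",
    "write_fes_grid",
    "read_levels",
    "write_levels",
    "write_report",
]


def read_colvar(path: str | Path, replica_id: int = 0) -> CoordTrajectory:
    """Parse a COLVAR-style file into a coordination trajectory."""
    path = Path(path)
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    fields = parts[2:]
                continue
            if line.startswith("#"):
                continue
            if fields is None:
                raise ValueError(f"{path}:{lineno}: data before '#! FIELDS' header")
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparseable line") from e
    if fields is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    for need in ("time", "lig_coord", "wat_coord"):
        if need not in fields:
            raise ValueError(f"{path}: missing field {need!r} (have {fields})")
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(fields):
        raise ValueError(f"{path}: column count does not match the FIELDS header")
    t = arr[:, fields.index("time")]
    dts = np.diff(t)
    bad = np.flatnonzero(dts <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: non-monotonic time at data row {int(bad[0]) + 2}"
        )
    frames = arr[:, [fields.index("lig_coord"), fields.index("wat_coord")]]
    return CoordTrajectory(dt=float(np.median(dts)), frames=frames, replica_id=replica_id)


def write_colvar(path: str | Path, traj: CoordTrajectory) -> None:
    path = Path(path)
    t = np.arange(traj.frames.shape[0]) * traj.dt
    with path.open("w") as fh:
        fh.write("#! FIELDS time lig_coord wat_coord\n")
        for ti, (l, w) in zip(t, traj.frames):
            fh.write(f"{ti:.6f} {l:.10g} {w:.10g}\n")


def read_colvar_glob(pattern: str) -> list[CoordTrajectory]:
    """Read a multi-replica set matched by a glob pattern."""
    paths = sorted(Path().glob(pattern)) if not Path(pattern).is_absolute() else sorted(
        Path(pattern).parent.glob(Path(pattern).name)
    )
    if not paths:
        raise FileNotFoundError(f"no trajectory files match {pattern!r}")
    return [read_colvar(p, replica_id=i) for i, p in enumerate(paths)]


def write_fes_grid(path: str | Path, fes: FreeEnergySurface) -> None:
    """Write the grid with the ligand axis fastest-varying."""
    path = Path(path)

    def step(ax: np.ndarray) -> float:
        return float(ax[1] - ax[0]) if ax.size > 1 else 1.0

    with path.open("w") as fh:
        fh.write(f"# axis lig min {fes.axis_lig[0]:.10g} width {step(fes.axis_lig):.10g} n {fes.axis_lig.size}\n")
        fh.write(f"# axis wat min {fes.axis_wat[0]:.10g} width {step(fes.axis_wat):.10g} n {fes.axis_wat.size}\n")
        fh.write(f"# temperature {fes.temperature:.10g}\n")
        for j in range(fes.axis_wat.size):
            for i in range(fes.axis_lig.size):
                v = fes.values[i, j]
                fh.write("inf\n" if not math.isfinite(v) else f"{v:.10g}\n")


def read_fes_grid(path: str | Path) -> FreeEnergySurface:
    path = Path(path)
    axes: dict[str, tuple[float, float, int]] = {}
    temperature = 300.0
    body: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "axis":
                    name = parts[1]
                    kv = dict(zip(parts[2::2], parts[3::2]))
                    axes[name] = (float(kv["min"]), float(kv["width"]), int(kv["n"]))
                elif parts and parts[0] == "temperature":
                    temperature = float(parts[1])
                continue
            body.append(float(line))
    for need in ("lig", "wat"):
        if need not in axes:
            raise ValueError(f"{path}: missing axis header for {need!r}")
    (l0, lw, ln), (w0, ww, wn) = axes["lig"], axes["wat"]
    if len(body) != ln * wn:
        raise ValueError(f"{path}: expected {ln * wn} grid values, found {len(body)}")
    # ligand axis fastest-varying: reshape (n_wat, n_lig) then transpose
    values = np.asarray(body, dtype=float).reshape(wn, ln).T
    if not np.isfinite(values).any():
        raise ValueError(f"{path}: no visited cells (every value is inf)")
    axis_lig = l0 + lw * np.arange(ln)
    axis_wat = w0 + ww * np.arange(wn)
    return FreeEnergySurface(values, axis_lig, axis_wat, temperature)


def write_levels(path: str | Path, levels: SpeciesLevels, n_lig: Iterable[int] | None = None) -> None:
    if n_lig is None:
        n_lig = range(levels.n_species)
    pd.DataFrame(
        {
            "species": levels.labels,
            "n_lig": list(n_lig),
            "delta_g_kj_mol": levels.delta_g,
            "sigma_kj_mol": levels.sigma,
        }
    ).to_csv(path, index=False)


def read_levels(path: str | Path) -> SpeciesLevels:
    df = pd.read_csv(path)
    for col in ("species", "delta_g_kj_mol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sigma = df["sigma_kj_mol"].to_numpy() if "sigma_kj_mol" in df.columns else None
    return SpeciesLevels(
        labels=[str(s) for s in df["species"]],
        delta_g=df["delta_g_kj_mol"].to_numpy(),
        sigma=sigma,
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    return obj


def write_report(path: str | Path, report: dict) -> None:
    """Deterministic JSON dump (sorted keys, fixed float rendering)."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")
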