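"""File plumbing: multi-model PDB trajectories, XYZ geometries, selection
configs and CSV/JSON result writers.

Trajectories travel as multi-model PDB (one MODEL block per frame, box on
CRYST1), read back through MDAnalysis.  Atom groups, masses and frame
times come from a YAML selection config — bead fixtures are not real
elements, so element-based mass guessing is never trusted.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .trajectory import CaptureSeries, DensityProfile, MetricSeries, MSDCurve, Trajectory


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """One MODEL block per frame; box lengths on CRYST1; element column set."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"CRYST1{traj.box[0]:9.3f}{traj.box[1]:9.3f}{traj.box[2]:9.3f}"
            f"  90.00  90.00  90.00 P 1           1\n"
        )
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(traj.n_atoms):
                el = traj.elements[a][:2]
                name = el.ljust(3)
                x, y, z = traj.coords[f, a]
                fh.write(
                    f"HETATM{a + 1:5d}  {name:<3s}BEA A{(a % 9999) + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_selections(
    traj: Trajectory,
    path: str | Path,
    dt: float | None = None,
) -> None:
    """Selection config matching a written trajectory: groups as inclusive
    index ranges, per-atom masses, elements, box and frame times."""
    ranges = {
        name: _to_ranges(idx) for name, idx in traj.groups.items()
    }
    doc = {
        "groups": ranges,
        "masses": [float(m) for m in traj.masses],
        "elements": list(traj.elements),
        "box": [float(b) for b in traj.box],
        "times": {"t0": float(traj.times[0]),
                  "dt": float(dt if dt is not None
                              else (traj.times[1] - traj.times[0]
                                    if traj.times.size > 1 else 1.0))},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _to_ranges(idx: np.ndarray) -> list[list[int]]:
    idx = np.sort(np.asarray(idx, dtype=int))
    ranges: list[list[int]] = []
    for i in idx:
        if ranges and i == ranges[-1][1] + 1:
            ranges[-1][1] = int(i)
        else:
            ranges.append([int(i), int(i)])
    return ranges


def _from_ranges(ranges: Sequence[Sequence[int]]) -> np.ndarray:
    return np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in ranges]
    ) if ranges else np.array([], dtype=int)


def read_trajectory(pdb_path: str | Path, selections_path: str | Path) -> Trajectory:
    """Load a multi-model PDB plus its selection config into a Trajectory."""
    import MDAnalysis as mda

    sel = yaml.safe_load(Path(selections_path).read_text())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing on bead names
        u = mda.Universe(str(pdb_path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])

    n_frames, n_atoms = coords.shape[:2]
    masses = np.asarray(sel["masses"], dtype=float)
    if masses.size != n_atoms:
        raise ValueError(
            f"selection config lists {masses.size} masses for {n_atoms} atoms"
        )
    times_cfg = sel.get("times", {"t0": 0.0, "dt": 1.0})
    times = times_cfg["t0"] + times_cfg["dt"] * np.arange(n_frames)
    if "box" in sel:
        box = np.asarray(sel["box"], dtype=float)
    elif u.dimensions is not None:
        box = np.asarray(u.dimensions[:3], dtype=float)
    else:
        raise ValueError("no box in selection config or trajectory header")
    groups = {name: _from_ranges(r) for name, r in sel["groups"].items()}
    return Trajectory(
        coords=coords.astype(float),
        masses=masses,
        elements=list(sel.get("elements", ["X"] * n_atoms)),
        groups=groups,
        box=box,
        times=times,
    )


# ---------------------------------------------------------------------------
# XYZ geometries
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Standard XYZ: atom count, comment, then `element x y z` lines (Å)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    n = int(lines[0].split()[0])
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ line {i + 3}: {line!r}")
        elements.append(parts[0])
        coords[i] = [float(x) for x in parts[1:4]]
    if len(elements) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(elements)}")
    return elements, coords


def write_xyz(path: str | Path, elements: Sequence[str], coords: np.ndarray,
              comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    with Path(path).open("w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el:<2s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_timeseries_csv(series: CaptureSeries | MetricSeries, path: str | Path) -> None:
    values = series.counts if isinstance(series, CaptureSeries) else series.values
    with Path(path).open("w") as fh:
        fh.write("time_ns,value\n")
        for t, v in zip(series.times, values):
            fh.write(f"{t:.6g},{v:.10g}\n")


def write_msd_csv(curve: MSDCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("lag_ns,msd_A2\n")
        for t, v in zip(curve.lag_times, curve.values):
            fh.write(f"{t:.6g},{v:.10g}\n")


def write_density_csv(profile: DensityProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("z_lo,z_hi,density_Da_per_A3,linear_density_Da_per_A\n")
        for lo, hi, d, ld in zip(profile.edges[:-1], profile.edges[1:],
                                 profile.density, profile.linear_density):
            fh.write(f"{lo:.6g},{hi:.6g},{d:.10g},{ld:.10g}\n")


def write_json_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
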