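"""Consensus ranking of ensemble-docking scores.

Ensemble docking screens a ligand library against many receptor
conformations (MD snapshots of the nanoparticle), several grid boxes per
conformation, and several poses per run.  Each pose carries one docking
energy (kcal/mol, negative = favourable).  This module collapses those
energies into five fusion statistics per ligand — minimum, arithmetic mean,
geometric mean, harmonic mean, median — ranks each statistic across the
library (rank 1 = most negative energy), and selects ligands whose
per-metric ranks agree: the statistical mode of the five ranks must fall
within the first ``top_k`` positions and occur in at least ``min_metrics``
of the five metrics.

Sign conventions
----------------
All energies are expected to be strictly negative (the docking convention).
The geometric mean of negative numbers is ill-defined for even sample
sizes, so it is computed on magnitudes with the negative sign re-applied:
``-(prod |DE_i|)^(1/n)``.  The harmonic mean ``n / sum(1/DE_i)`` is well
defined for all-negative input and equals the negated harmonic mean of the
magnitudes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRICS = ("min_value", "arithmetic_mean", "geometric_mean", "harmonic_mean", "median")

#: CSV column order for fusion tables (fixed, documented interface).
FUSION_COLUMNS = ["ligand_id", *METRICS, *(f"rank_{m}" for m in METRICS)]

#: CSV column order for consensus results.
CONSENSUS_COLUMNS = [
    "ligand_id",
    "mode",
    "multiplicity",
    "mode_in_top_k",
    "mode_in_min_metrics",
    "selected",
]


class DockingParseError(ValueError):
    """Raised for malformed or duplicated docking records."""


@dataclass(frozen=True)
class DockingPose:
    """One docked pose: its campaign coordinates and Vina energy (kcal/mol)."""

    ligand_id: str
    conformation_id: int
    grid_id: int
    pose_index: int  # 1-based, as in Vina output
    energy: float

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError(f"pose_index must be >= 1, got {self.pose_index}")
        if not math.isfinite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")


@dataclass(frozen=True)
class ScoreVector:
    """Per-ligand energies retained after pose aggregation."""

    ligand_id: str
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.energies) == 0:
            raise ValueError(f"empty ScoreVector for ligand {self.ligand_id!r}")
        if not all(math.isfinite(e) for e in self.energies):
            raise ValueError(f"non-finite energy for ligand {self.ligand_id!r}")


@dataclass(frozen=True)
class CampaignPlan:
    """Bookkeeping of a docking/simulation campaign's size."""

    n_ligands: int
    n_conformations: int
    n_grids: int
    poses_per_run: int
    n_runs: int
    n_evaluations: int
    n_systems: int | None = None
    n_replicas: int | None = None
    ns_per_replica: float | None = None
    total_time_ns: float | None = None


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of the mode-based consensus selection."""

    selected: tuple[str, ...]
    table: pd.DataFrame = field(repr=False)
    top_k: int = 5
    min_metrics: int = 3


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_pdbqt(
    path: str | Path,
    ligand_id: str,
    conformation_id: int,
    grid_id: int,
) -> list[DockingPose]:
    """Parse one Vina PDBQT output file into :class:`DockingPose` records.

    Energies are taken from ``REMARK VINA RESULT`` lines (field 4 of the
    record, kcal/mol); pose indices follow the order of appearance,
    starting at 1.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    poses: list[DockingPose] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("REMARK VINA RESULT"):
                continue
            fields = line.split()
            try:
                energy = float(fields[3])
            except (IndexError, ValueError) as exc:
                raise DockingParseError(
                    f"{path}:{lineno}: malformed energy field in {line.rstrip()!r}"
                ) from exc
            poses.append(
                DockingPose(
                    ligand_id=ligand_id,
                    conformation_id=conformation_id,
                    grid_id=grid_id,
                    pose_index=len(poses) + 1,
                    energy=energy,
                )
            )
    if not poses:
        logger.warning("no pose records found in %s", path)
    return poses


def parse_docking_results(
    files: Mapping[str | Path, tuple[str, int, int]],
) -> list[DockingPose]:
    """Parse a batch of PDBQT files.

    ``files`` maps each path to its ``(ligand_id, conformation_id,
    grid_id)`` coordinates, as declared by the campaign layout in the
    config (the mapping is never inferred from file names).  Duplicate
    pose coordinates across files raise :class:`DockingParseError`.
    """
    poses: list[DockingPose] = []
    seen: set[tuple[str, int, int, int]] = set()
    for path, (ligand_id, conf_id, grid_id) in files.items():
        for pose in parse_pdbqt(path, ligand_id, conf_id, grid_id):
            key = (pose.ligand_id, pose.conformation_id, pose.grid_id, pose.pose_index)
            if key in seen:
                raise DockingParseError(f"duplicate pose record {key} (file {path})")
            seen.add(key)
            poses.append(pose)
    return poses


def parse_scores_csv(path: str | Path) -> list[DockingPose]:
    """Read a tabular score file.

    Required header: ``ligand_id,conformation_id,grid_id,pose_index,energy``.
    """
    df = pd.read_csv(path)
    required = ["ligand_id", "conformation_id", "grid_id", "pose_index", "energy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DockingParseError(f"{path}: missing columns {missing}")
    key_cols = required[:4]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise DockingParseError(f"{path}: duplicate pose record {first}")
    if not np.isfinite(df["energy"]).all():
        bad = int((~np.isfinite(df["energy"])).idxmax())
        raise DockingParseError(f"{path}: non-finite energy at row {bad}")
    return [
        DockingPose(str(r.ligand_id), int(r.conformation_id), int(r.grid_id),
                    int(r.pose_index), float(r.energy))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Aggregation and fusion
# ---------------------------------------------------------------------------

def aggregate_poses(
    poses: Iterable[DockingPose],
    policy: str = "best-per-run",
    expected_runs: int | None = None,
    min_coverage: float = 0.5,
) -> list[ScoreVector]:
    """Collapse poses into one :class:`ScoreVector` per ligand.

    ``best-per-run`` keeps the minimum (best) energy of each
    (conformation, grid) run; ``all-poses`` keeps every pose energy.
    Ligands covering fewer than ``min_coverage`` of ``expected_runs``
    (when given) are excluded with a warning — partial campaigns happen
    when individual dockings fail.
    """
    if policy not in ("best-per-run", "all-poses"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    by_ligand: dict[str, dict[tuple[int, int], list[float]]] = {}
    for p in poses:
        by_ligand.setdefault(p.ligand_id, {}).setdefault(
            (p.conformation_id, p.grid_id), []
        ).append(p.energy)

    vectors: list[ScoreVector] = []
    for ligand_id in sorted(by_ligand):
        runs = by_ligand[ligand_id]
        if expected_runs is not None and len(runs) < min_coverage * expected_runs:
            logger.warning(
                "ligand %s excluded: only %d of %d runs present (< %.0f%% coverage)",
                ligand_id, len(runs), expected_runs, 100 * min_coverage,
            )
            continue
        if policy == "best-per-run":
            energies = tuple(min(runs[k]) for k in sorted(runs))
        else:
            energies = tuple(e for k in sorted(runs) for e in runs[k])
        vectors.append(ScoreVector(ligand_id, energies))
    return vectors


def fuse_scores(energies: Sequence[float]) -> dict[str, float]:
    """The five fusion metrics of one score vector.

    Requires strictly negative energies; a zero energy makes the harmonic
    mean undefined and mixed signs make the geometric mean ambiguous.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty score vector")
    if not np.isfinite(e).all():
        raise ValueError("non-finite energy in score vector")
    if np.any(e == 0.0):
        raise ValueError("zero energy: harmonic mean undefined")
    if np.any(e > 0) and np.any(e < 0):
        raise ValueError("mixed-sign energies: geometric mean ambiguous")
    if np.any(e > 0):
        raise ValueError("positive energies violate the docking sign convention")
    return {
        "min_value": float(e.min()),
        "arithmetic_mean": float(e.mean()),
        # signed-magnitude convention: -(prod |DE|)^(1/n), via logs for stability
        "geometric_mean": float(-np.exp(np.mean(np.log(np.abs(e))))),
        "harmonic_mean": float(e.size / np.sum(1.0 / e)),
        "median": float(np.median(e)),
    }


def fusion_table(vectors: Iterable[ScoreVector]) -> pd.DataFrame:
    """Fuse and rank a whole library; one row per ligand.

    Columns: the five metrics plus ``rank_<metric>`` for each.  Rows are
    sorted by ``ligand_id`` so reruns are bit-identical.
    """
    rows = {v.ligand_id: fuse_scores(v.energies) for v in vectors}
    if not rows:
        raise ValueError("no score vectors to fuse")
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "ligand_id"
    for m in METRICS:
        df[f"rank_{m}"] = rank_metric(df[m])
    return df


def rank_metric(values: pd.Series) -> pd.Series:
    """Competition ranks: 1 = most negative; ties share the minimum rank."""
    if values.isna().any():
        bad = values.index[values.isna()][0]
        raise ValueError(f"missing metric value for ligand {bad!r}")
    ranks = rankdata(values.to_numpy(), method="min")
    return pd.Series(ranks.astype(int), index=values.index)


def _mode_smallest(ranks: Sequence[int]) -> tuple[int, int]:
    """Mode of a rank vector; multimodal ties resolve to the smallest value."""
    counts = Counter(ranks)
    best_count = max(counts.values())
    mode = min(v for v, c in counts.items() if c == best_count)
    return mode, best_count


def consensus_select(
    ranks: pd.DataFrame,
    top_k: int = 5,
    min_metrics: int = 3,
) -> ConsensusResult:
    """Mode-based consensus over the five per-metric ranks.

    A ligand is selected iff (1) the mode of its five ranks is ``<= top_k``
    and (2) that mode occurs in at least ``min_metrics`` of the metrics.
    ``ranks`` may be a full fusion table or just the ``rank_*`` columns.
    """
    rank_cols = [f"rank_{m}" for m in METRICS]
    missing_cols = [c for c in rank_cols if c not in ranks.columns]
    if missing_cols:
        raise ValueError(f"missing rank columns: {missing_cols}")
    sub = ranks[rank_cols]
    if sub.isna().any(axis=None):
        bad = sub.index[sub.isna().any(axis=1)][0]
        raise ValueError(f"missing metric ranks for ligand {bad!r}")

    records = []
    for ligand_id, row in sub.sort_index().iterrows():
        mode, mult = _mode_smallest([int(r) for r in row])
        crit1 = mode <= top_k
        crit2 = mult >= min_metrics
        records.append(
            {
                "ligand_id": ligand_id,
                "mode": mode,
                "multiplicity": mult,
                "mode_in_top_k": crit1,
                "mode_in_min_metrics": crit2,
                "selected": crit1 and crit2,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("ligand_id")
    selected = tuple(table.index[table["selected"]])
    return ConsensusResult(selected=selected, table=table,
                           top_k=top_k, min_metrics=min_metrics)


def enumerate_campaign(
    n_ligands: int,
    n_conformations: int,
    n_grids: int,
    poses_per_run: int,
    n_systems: int | None = None,
    n_replicas: int | None = None,
    ns_per_replica: float | None = None,
) -> CampaignPlan:
    """Exact size arithmetic of a screening + simulation campaign.

    ``n_runs = n_ligands * n_conformations * n_grids`` and
    ``n_evaluations = n_runs * poses_per_run``; the optional simulation
    factors give ``total_time_ns = n_systems * n_replicas * ns_per_replica``.
    """
    factors = {
        "n_ligands": n_ligands,
        "n_conformations": n_conformations,
        "n_grids": n_grids,
        "poses_per_run": poses_per_run,
    }
    for name, value in factors.items():
        if int(value) != value or value <= 0:
            raise ValueError(f"{name} must be a positive integer, got {value}")
    sim = (n_systems, n_replicas, ns_per_replica)
    total_time_ns = None
    if any(v is not None for v in sim):
        if any(v is None for v in sim):
            raise ValueError("n_systems, n_replicas and ns_per_replica go together")
        if n_systems <= 0 or n_replicas <= 0 or ns_per_replica <= 0:
            raise ValueError("simulation factors must be positive")
        total_time_ns = n_systems * n_replicas * float(ns_per_replica)
    n_runs = n_ligands * n_conformations * n_grids
    return CampaignPlan(
        n_ligands=n_ligands,
        n_conformations=n_conformations,
        n_grids=n_grids,
        poses_per_run=poses_per_run,
        n_runs=n_runs,
        n_evaluations=n_runs * poses_per_run,
        n_systems=n_systems,
        n_replicas=n_replicas,
        ns_per_replica=ns_per_replica,
        total_time_ns=total_time_ns,
    )


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def write_fusion_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index()[FUSION_COLUMNS].to_csv(path, index=False)


def write_consensus_csv(result: ConsensusResult, path: str | Path) -> None:
    result.table.reset_index()[CONSENSUS_COLUMNS].to_csv(path, index=False)
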