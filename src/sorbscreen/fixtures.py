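"""Seeded generators for every input the analysis modules consume.

Emulates, at bead resolution, the systems the analyses were designed
for: a calcium-alginate-chitosan (CAC) nanoparticle sphere-packed from
16-mer polyelectrolyte chains and Ca2+ ions, docking-score tables with
planted top candidates, Brownian ligand trajectories with a known
diffusion coefficient, and deterministic approach-and-stick trajectories
with constructed per-frame capture counts.  Every generator takes a seed
and is bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .trajectory import CaptureSeries, Trajectory

# Nominal residue masses for the bead chains (Da): ionised uronate for the
# alginate G/M monomers, protonated glucosamine for chitosan C.  Fixture
# constants, not measured quantities.
MONOMER_MASS = {"G": 176.0, "M": 176.0, "C": 161.0}
MONOMER_CHARGE = {"G": -1, "M": -1, "C": +1}  # formal charges at pH 7
CALCIUM_MASS = 40.08
CALCIUM_CHARGE = +2

#: The three 16-mer chain patterns: an 8+8 block copolymer, an alternating
#: GM copolymer, and a pure chitosan chain.
CHAIN_PATTERNS = {
    "G8M8": "G" * 8 + "M" * 8,
    "GM8": "GM" * 8,
    "C16": "C" * 16,
}


@dataclass(frozen=True)
class PackingSpec:
    """Random rigid placement of molecules in a sphere (or spherical shell).

    ``templates`` holds one (n_atoms, 3) coordinate array per molecule to
    place; every inter-molecule atom pair must end up >= ``tolerance`` Å
    apart and all atoms inside ``radius`` (for shell placement the
    centroids must satisfy r_inner < |c| <= r_outer).
    """

    templates: tuple
    radius: float
    tolerance: float = 4.0
    shell: tuple[float, float] | None = None
    seed: int | None = None
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.shell is not None and not self.shell[0] < self.shell[1]:
            raise ValueError("shell requires r_inner < r_outer")


class PackingError(RuntimeError):
    pass


def chain_sequence(pattern: str) -> str:
    try:
        return CHAIN_PATTERNS[pattern]
    except KeyError:
        raise ValueError(f"unknown chain pattern {pattern!r}; have {sorted(CHAIN_PATTERNS)}")


def helix_template(n_beads: int, bead_spacing: float = 5.0,
                   helix_radius: float = 4.0, turn: float = 1.2) -> np.ndarray:
    """Compact helical bead-chain template, centred on its centroid.

    Consecutive beads sit ``bead_spacing`` apart; the helix keeps all
    intra-chain bead distances >= 4 Å while spanning far less than a
    straight chain, so 16-mers fit inside small packing spheres.
    """
    chord = 2.0 * helix_radius * math.sin(turn / 2.0)
    if chord >= bead_spacing:
        raise ValueError("helix turn too wide for the requested bead spacing")
    dz = math.sqrt(bead_spacing**2 - chord**2)
    i = np.arange(n_beads)
    coords = np.stack(
        [
            helix_radius * np.cos(i * turn),
            helix_radius * np.sin(i * turn),
            i * dz,
        ],
        axis=1,
    )
    return coords - coords.mean(axis=0)


def pack_sphere(spec: PackingSpec) -> list[np.ndarray]:
    """Place molecules by rejection sampling.

    Each molecule gets a uniform random rotation and a centre drawn
    uniformly in the sphere (or shell); a placement is accepted when all
    its atoms stay inside the sphere and no inter-molecule atom pair is
    closer than the tolerance.  Raises :class:`PackingError` when the
    attempt cap is exceeded.
    """
    rng = np.random.default_rng(spec.seed)
    placed: list[np.ndarray] = []
    occupied: list[np.ndarray] = []
    tree: cKDTree | None = None

    for mol_i, template in enumerate(spec.templates):
        template = np.atleast_2d(np.asarray(template, dtype=float))
        for attempt in range(spec.max_attempts):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            if spec.shell is None:
                # uniform in the ball via radius ~ U^(1/3)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                center = direction * spec.radius * rng.uniform() ** (1.0 / 3.0)
            else:
                r_in, r_out = spec.shell
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                r = (r_in**3 + (r_out**3 - r_in**3) * rng.uniform()) ** (1.0 / 3.0)
                center = direction * r
            coords = rot.apply(template - template.mean(axis=0)) + center
            if spec.shell is None:
                if np.any(np.linalg.norm(coords, axis=1) > spec.radius):
                    continue
            else:
                if np.any(np.linalg.norm(coords, axis=1) > spec.shell[1]):
                    continue
            if tree is not None:
                dmin, _ = tree.query(coords, k=1)
                if np.min(dmin) < spec.tolerance:
                    continue
            placed.append(coords)
            occupied.append(coords)
            tree = cKDTree(np.concatenate(occupied))
            break
        else:
            raise PackingError(
                f"could not place molecule {mol_i} after {spec.max_attempts} "
                "attempts; lower the density or the tolerance"
            )
    return placed


@dataclass(frozen=True)
class CACSystem:
    """Bead-level CAC nanoparticle: coordinates plus per-bead metadata."""

    coords: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    labels: list[str]
    groups: dict[str, np.ndarray] = field(repr=False)


def build_cac_fixture(
    n_alg_block: int = 25,
    n_alg_alt: int = 25,
    n_chitosan: int = 50,
    n_calcium: int = 640,
    radius: float = 70.0,
    tolerance: float = 4.0,
    seed: int | None = None,
) -> CACSystem:
    """Sphere-packed bead nanoparticle of alginate/chitosan 16-mers + Ca2+.

    Defaults reproduce the full-particle composition (25 + 25 alginate
    chains, 50 chitosan chains, 640 calcium ions in a 70 Å sphere); the
    smaller capture-study system is (10, 10, 20, 320) at 40 Å.  Chains are
    one bead per monomer on a compact helix; ions are single beads.
    Groups: ``matrix`` (all chain beads) and ``ion``.
    """
    for name, n in {"n_alg_block": n_alg_block, "n_alg_alt": n_alg_alt,
                    "n_chitosan": n_chitosan, "n_calcium": n_calcium}.items():
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    chain_specs = (
        [("G8M8", helix_template(16))] * n_alg_block
        + [("GM8", helix_template(16))] * n_alg_alt
        + [("C16", helix_template(16))] * n_chitosan
    )
    ion_template = np.zeros((1, 3))
    templates = [t for _, t in chain_specs] + [ion_template] * n_calcium
    placed = pack_sphere(
        PackingSpec(templates=tuple(templates), radius=radius,
                    tolerance=tolerance, seed=seed)
    )

    coords, masses, charges, labels = [], [], [], []
    matrix_idx, ion_idx = [], []
    for (pattern, _), mol in zip(chain_specs, placed[: len(chain_specs)]):
        seq = chain_sequence(pattern)
        for monomer, xyz in zip(seq, mol):
            matrix_idx.append(len(labels))
            coords.append(xyz)
            masses.append(MONOMER_MASS[monomer])
            charges.append(MONOMER_CHARGE[monomer])
            labels.append(monomer)
    for mol in placed[len(chain_specs):]:
        ion_idx.append(len(labels))
        coords.append(mol[0])
        masses.append(CALCIUM_MASS)
        charges.append(CALCIUM_CHARGE)
        labels.append("Ca")
    return CACSystem(
        coords=np.array(coords) if coords else np.empty((0, 3)),
        masses=np.array(masses),
        charges=np.array(charges, dtype=int),
        labels=labels,
        groups={
            "matrix": np.array(matrix_idx, dtype=int),
            "ion": np.array(ion_idx, dtype=int),
        },
    )


# ---------------------------------------------------------------------------
# Docking-score tables
# ---------------------------------------------------------------------------

def gen_docking_scores(
    n_ligands: int = 624,
    n_conformations: int = 20,
    n_grids: int = 4,
    poses_per_run: int = 9,
    background_mean: float = -5.7,
    background_sd: float = 0.6,
    planted: Sequence[str] = (),
    delta: float = -5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic ensemble-docking score table with planted top candidates.

    One row per (ligand, conformation, grid, pose); the defaults
    enumerate the full screening campaign (624 x 20 x 4 x 9 = 449,280
    rows).  Background energies are N(background_mean, background_sd)
    truncated strictly negative; ligands named in ``planted`` draw their
    energies shifted by ``delta`` (must be negative: more favourable).
    Poses within a run are sorted best-first, as a docking engine emits
    them.
    """
    if planted and delta >= 0:
        raise ValueError("planted energy shift delta must be negative")
    rng = np.random.default_rng(seed)
    ligand_ids = [f"L{i:04d}" for i in range(n_ligands)]
    planted_set = set(planted)
    unknown = planted_set - set(ligand_ids)
    if unknown:
        raise ValueError(f"planted ligands not in the library: {sorted(unknown)}")

    n_runs = n_conformations * n_grids
    rows = []
    for lig in ligand_ids:
        mu = background_mean + (delta if lig in planted_set else 0.0)
        e = rng.normal(mu, background_sd, size=(n_runs, poses_per_run))
        e = np.minimum(e, -0.01)  # docking convention: strictly negative
        e.sort(axis=1)  # pose 1 = best energy
        for run in range(n_runs):
            conf, grid = divmod(run, n_grids)
            for pose in range(poses_per_run):
                rows.append((lig, conf, grid, pose + 1, e[run, pose]))
    return pd.DataFrame(
        rows, columns=["ligand_id", "conformation_id", "grid_id", "pose_index", "energy"]
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def gen_brownian_traj(
    n_particles: int = 50,
    d_coeff: float = 0.1,
    dt: float = 0.1,
    n_steps: int = 2000,
    box: float | Sequence[float] = 1000.0,
    seed: int | None = None,
) -> Trajectory:
    """Free Brownian point particles with diffusion coefficient ``d_coeff``
    (Å²/ns): Gaussian steps of variance 2 D dt per axis, unwrapped
    coordinates.  D = 0 yields a static trajectory."""
    if d_coeff < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    start = rng.uniform(0.25, 0.75, size=(n_particles, 3)) * box
    steps = rng.normal(0.0, math.sqrt(2.0 * d_coeff * dt),
                       size=(n_steps, n_particles, 3))
    coords = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    return Trajectory(
        coords=coords,
        masses=np.ones(n_particles),
        elements=["C"] * n_particles,
        groups={"ligand": np.arange(n_particles)},
        box=box,
        times=np.arange(n_steps + 1) * dt,
    )


def gen_capture_traj(
    schedule: Mapping[int, int | None],
    n_frames: int = 50,
    dt: float = 1.0,
    cutoff: float = 3.5,
    start_distance: float = 60.0,
    seed: int | None = None,
) -> tuple[Trajectory, CaptureSeries]:
    """Deterministic approach-and-stick trajectory with known capture counts.

    ``schedule`` maps each copy index to the frame at which its distance
    to the single-bead matrix first equals the cutoff exactly (then it
    sticks), or None for copies that never approach.  Returns the
    trajectory and the constructed ground-truth capture series.  The seed
    only randomises approach directions; counts are schedule-determined.
    """
    n_copies = len(schedule)
    if n_copies == 0:
        raise ValueError("empty schedule")
    for copy_i, frame in schedule.items():
        if frame is not None and not 0 <= frame < n_frames:
            raise ValueError(
                f"copy {copy_i}: scheduled frame {frame} outside 0..{n_frames - 1}"
            )
    rng = np.random.default_rng(seed)
    box = np.full(3, 4.0 * start_distance)
    center = box / 2.0

    # axis-aligned approach directions keep the contact distance exact
    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    n_atoms = 1 + n_copies
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, 0, :] = center  # matrix bead
    counts = np.zeros(n_frames, dtype=int)
    for i, copy_i in enumerate(sorted(schedule)):
        frame = schedule[copy_i]
        direction = axes[rng.integers(len(axes))]
        if frame is None:
            coords[:, 1 + i, :] = center + direction * start_distance
            continue
        for f in range(n_frames):
            if f >= frame:
                dist = cutoff
            elif frame == 0:
                dist = cutoff
            else:
                # linear approach that lands exactly on the cutoff at `frame`
                dist = start_distance + (cutoff - start_distance) * f / frame
            coords[f, 1 + i, :] = center + direction * dist
        counts[frame:] += 1

    traj = Trajectory(
        coords=coords,
        masses=np.concatenate([[1000.0], np.full(n_copies, 100.0)]),
        elements=["P"] + ["C"] * n_copies,
        groups={
            "matrix": np.array([0]),
            **{f"copy_{c}": np.array([1 + i])
               for i, c in enumerate(sorted(schedule))},
        },
        box=box,
        times=np.arange(n_frames) * dt,
    )
    series = CaptureSeries(times=traj.times.copy(), counts=counts,
                           n_copies=n_copies, cutoff=cutoff)
    return traj, series


def gen_slab_traj(
    slab_masses: Sequence[tuple[float, float, float]],
    box: Sequence[float] = (100.0, 100.0, 240.0),
    atom_mass: float = 12.0,
    n_frames: int = 1,
    seed: int | None = None,
) -> Trajectory:
    """Slab mass distribution along z for density-profile tests.

    ``slab_masses`` lists (z_lo, z_hi, total_mass) slabs; each slab is
    filled with ``total_mass / atom_mass`` atoms uniformly random in x, y
    and in its z range (z centred so the box spans [-box_z/2, box_z/2)).
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    coords_once = []
    for z_lo, z_hi, mass in slab_masses:
        n = int(round(mass / atom_mass))
        if abs(n * atom_mass - mass) > 1e-9:
            raise ValueError(f"slab mass {mass} is not a multiple of atom mass {atom_mass}")
        xy = rng.uniform(0.0, box[:2], size=(n, 2))
        z = rng.uniform(z_lo, z_hi, size=(n, 1))
        coords_once.append(np.concatenate([xy, z], axis=1))
    frame = np.concatenate(coords_once) if coords_once else np.empty((0, 3))
    n_atoms = frame.shape[0]
    return Trajectory(
        coords=np.repeat(frame[None], n_frames, axis=0),
        masses=np.full(n_atoms, atom_mass),
        elements=["C"] * n_atoms,
        groups={"all": np.arange(n_atoms)},
        box=box,
        times=np.arange(n_frames, dtype=float),
    )
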