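"""Trajectory-based sorption analytics.

Everything measured on MD trajectories of ligand copies around a
polyelectrolyte nanoparticle: capture counting and kinetics (how many
copies sit within a contact cutoff of the matrix per frame), axis-binned
mass density profiles (adsorption vs absorption), mean square
displacement and diffusion coefficients, RMSD/radius-of-gyration series,
hierarchical clustering of conformers with representative frames,
hydrogen-bond / salt-bridge counts, and replicate capture statistics.

The in-memory container is a plain :class:`Trajectory` (frames x atoms
Cartesian coordinates in Å, per-atom masses in Da, named atom groups, an
orthorhombic box, frame times in ns); file I/O lives in
:mod:`sorbscreen.io`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Frames x atoms coordinates with static topology metadata.

    coords : (n_frames, n_atoms, 3) Å
    masses : (n_atoms,) Da
    elements : per-atom element/bead symbols
    groups : name -> atom index array (e.g. ``matrix``, ``copy_0``, ``ion``)
    box : orthorhombic box lengths (3,) Å
    times : (n_frames,) ns, strictly increasing
    """

    coords: np.ndarray
    masses: np.ndarray
    elements: list[str]
    groups: dict[str, np.ndarray]
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.masses.size:
            raise ValueError("masses length must match atom count")
        if len(self.elements) != self.masses.size:
            raise ValueError("elements length must match atom count")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.times.size != self.coords.shape[0]:
            raise ValueError("times length must match frame count")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"unknown atom group {name!r}; have {sorted(self.groups)}")


@dataclass(frozen=True)
class CaptureSeries:
    """Per-frame number of ligand copies in contact with the matrix."""

    times: np.ndarray
    counts: np.ndarray
    n_copies: int
    cutoff: float

    def __post_init__(self) -> None:
        if np.any(self.counts < 0) or np.any(self.counts > self.n_copies):
            raise ValueError("counts must lie in [0, n_copies]")


@dataclass(frozen=True)
class DensityProfile:
    """Slab-binned mass density along one axis, averaged over frames.

    ``density`` is the physical slab density (Da/Å³: window mass divided
    by slab thickness x box cross-section); ``linear_density`` (Da/Å) is
    the same histogram divided by thickness only.
    """

    edges: np.ndarray
    density: np.ndarray
    linear_density: np.ndarray
    axis: int
    n_frames: int
    excluded_atoms: float  # mean per-frame count of atoms outside the range

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class MSDCurve:
    lag_times: np.ndarray  # ns, starting at 0
    values: np.ndarray  # Å²
    scheme: str


@dataclass(frozen=True)
class DiffusionEstimate:
    """Einstein-relation diffusion coefficient, MSD(τ) ≈ 6 D τ."""

    d_A2_per_ns: float
    d_cm2_per_s: float
    slope: float
    intercept: float
    fit_window: tuple[float, float]


@dataclass(frozen=True)
class MetricSeries:
    times: np.ndarray
    values: np.ndarray
    name: str


@dataclass(frozen=True)
class InteractionCount:
    times: np.ndarray
    hb_counts: np.ndarray
    sb_counts: np.ndarray
    criteria: dict


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # (n_frames,) cluster ids 0..k-1
    representatives: np.ndarray  # (k,) one frame index per cluster
    n_clusters: int
    linkage: str
    seed: int | None


# ---------------------------------------------------------------------------
# Distances / capture
# ---------------------------------------------------------------------------

def _min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances between two coordinate sets."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def min_matrix_distance(
    lig: np.ndarray, mat: np.ndarray, box: np.ndarray, method: str = "kdtree"
) -> float:
    """Nearest ligand-atom to matrix-atom distance under the periodic box."""
    if method == "brute":
        return float(_min_image_dists(lig, mat, box).min())
    tree = cKDTree(np.mod(mat, box), boxsize=box)
    dists, _ = tree.query(np.mod(lig, box))
    return float(np.min(dists))


def capture_count(
    traj: Trajectory,
    ligand_groups: Sequence[str],
    matrix_group: str = "matrix",
    cutoff: float = 3.5,
    mode: str = "atom",
    method: str = "kdtree",
) -> CaptureSeries:
    """Count captured ligand copies per frame.

    A copy is captured when its minimum atom-to-matrix-atom distance is
    ``<= cutoff`` (inclusive), under the minimum-image convention; with
    ``mode='com'`` the copy's centre of mass replaces its atoms.
    """
    if not ligand_groups:
        raise ValueError("no ligand groups given")
    mat_idx = traj.group(matrix_group)
    if mat_idx.size == 0:
        raise ValueError(f"matrix group {matrix_group!r} is empty")
    lig_idx = []
    for g in ligand_groups:
        idx = traj.group(g)
        if idx.size == 0:
            raise ValueError(f"ligand group {g!r} is empty")
        if np.intersect1d(idx, mat_idx).size:
            raise ValueError(f"ligand group {g!r} overlaps the matrix group")
        lig_idx.append(idx)

    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        mat = traj.coords[f, mat_idx]
        tree = None
        if method == "kdtree":
            tree = cKDTree(np.mod(mat, traj.box), boxsize=traj.box)
        n = 0
        for idx, gname in zip(lig_idx, ligand_groups):
            pts = traj.coords[f, idx]
            if mode == "com":
                w = traj.masses[idx]
                pts = (w[:, None] * pts).sum(axis=0, keepdims=True) / w.sum()
            if tree is not None:
                dmin = float(tree.query(np.mod(pts, traj.box))[0].min())
            else:
                dmin = float(_min_image_dists(pts, mat, traj.box).min())
            if dmin <= cutoff:
                n += 1
        counts[f] = n
    return CaptureSeries(times=traj.times.copy(), counts=counts,
                         n_copies=len(ligand_groups), cutoff=cutoff)


def capture_halftime(series: CaptureSeries) -> float:
    """First time the count reaches half the copies, ceil(n/2).

    Linear interpolation between the bracketing frames; ``inf`` when the
    threshold is never reached.
    """
    if series.counts.size == 0:
        raise ValueError("empty capture series")
    threshold = math.ceil(series.n_copies / 2)
    hits = np.nonzero(series.counts >= threshold)[0]
    if hits.size == 0:
        return math.inf
    i = int(hits[0])
    if i == 0:
        return float(series.times[0])
    c0, c1 = series.counts[i - 1], series.counts[i]
    t0, t1 = series.times[i - 1], series.times[i]
    return float(t0 + (threshold - c0) / (c1 - c0) * (t1 - t0))


# ---------------------------------------------------------------------------
# Density profile
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def density_profile(
    traj: Trajectory,
    selection: str,
    axis: int | str = "z",
    n_windows: int = 240,
    coord_range: tuple[float, float] = (-120.0, 120.0),
) -> DensityProfile:
    """Mass density per axis window, averaged over frames.

    Windows are half-open ``[lo, hi)`` with the final upper edge closed.
    The slab density divides each window's mass by (thickness x box
    cross-sectional area); atoms outside the range are excluded and
    tallied.  Mass is conserved: sum(density x slab volume) equals the
    mean in-range selected mass.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    lo, hi = coord_range
    if not hi > lo:
        raise ValueError("coordinate range must be increasing")
    idx = traj.group(selection)
    w = traj.masses[idx]
    edges = np.linspace(lo, hi, n_windows + 1)
    cross_area = float(np.prod(np.delete(traj.box, ax)))
    thickness = (hi - lo) / n_windows

    hist = np.zeros(n_windows)
    excluded = 0
    for f in range(traj.n_frames):
        c = traj.coords[f, idx, ax]
        h, _ = np.histogram(c, bins=edges, weights=w)
        hist += h
        excluded += int(np.sum((c < lo) | (c > hi)))
    if excluded:
        logger.info("density_profile: %d atom observations outside [%g, %g) excluded",
                    excluded, lo, hi)
    mean_mass = hist / traj.n_frames
    return DensityProfile(
        edges=edges,
        density=mean_mass / (thickness * cross_area),
        linear_density=mean_mass / thickness,
        axis=ax,
        n_frames=traj.n_frames,
        excluded_atoms=excluded / traj.n_frames,
    )


# ---------------------------------------------------------------------------
# MSD / diffusion
# ---------------------------------------------------------------------------

def unwrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic jumps: any inter-frame step > box/2 is image-corrected."""
    steps = np.diff(coords, axis=0)
    steps -= box * np.round(steps / box)
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(steps, axis=0)
    return out


def msd(
    traj: Trajectory,
    selection: str,
    max_lag: int | None = None,
    origin_stride: int = 1,
    unwrap: bool = True,
) -> MSDCurve:
    """Mean square displacement over sliding time origins.

    MSD(τ) averages |r(t+τ) − r(t)|² over every selected atom (one atom
    per ligand copy in the bead fixtures) and every origin at the given
    stride.  Frame times must be uniformly spaced.
    """
    idx = traj.group(selection)
    n_frames = traj.n_frames
    if max_lag is None:
        max_lag = n_frames // 2
    if max_lag >= n_frames:
        raise ValueError(f"max_lag {max_lag} >= trajectory length {n_frames}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    dts = np.diff(traj.times)
    if dts.size and not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
        raise ValueError("MSD requires uniformly spaced frames")
    dt = float(dts[0]) if dts.size else 0.0

    x = traj.coords[:, idx, :]
    if unwrap:
        x = unwrap_coordinates(x, traj.box)
    values = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = x[origins + lag] - x[origins]
        values[lag] = float(np.mean(np.sum(disp * disp, axis=-1)))
    return MSDCurve(
        lag_times=np.arange(max_lag + 1) * dt,
        values=values,
        scheme=f"all-copies, origin stride {origin_stride}",
    )


def diffusion_coefficient(
    curve: MSDCurve,
    fit_window: tuple[float, float] = (0.2, 0.8),
) -> DiffusionEstimate:
    """Least-squares Einstein fit D = slope/6 on a fractional lag window."""
    lo, hi = fit_window
    tmax = curve.lag_times[-1]
    mask = (curve.lag_times >= lo * tmax) & (curve.lag_times <= hi * tmax)
    t = curve.lag_times[mask]
    y = curve.values[mask]
    if t.size < 3:
        raise ValueError(f"fit window contains {t.size} < 3 lag points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate fit window: zero lag-time variance")
    slope, intercept = np.polyfit(t, y, 1)
    d = slope / 6.0
    return DiffusionEstimate(
        d_A2_per_ns=float(d),
        d_cm2_per_s=float(d) * 1e-7,
        slope=float(slope),
        intercept=float(intercept),
        fit_window=(float(t[0]), float(t[-1])),
    )


# ---------------------------------------------------------------------------
# RMSD / Rg / clustering
# ---------------------------------------------------------------------------

def _rmsd_pair(p: np.ndarray, q: np.ndarray, align: bool) -> float:
    if align:
        # Kabsch superposition; residuals computed directly (not from the
        # singular values, which loses precision to cancellation)
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        u, _, vt = np.linalg.svd(qc.T @ pc)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        diff = qc @ rot - pc
        return float(np.sqrt(np.mean(np.sum(diff * diff, axis=-1))))
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    selection: str,
    reference_frame: int = 0,
    align: bool = True,
) -> MetricSeries:
    """RMSD of each frame to a reference frame, optionally after Kabsch
    superposition (align=True, the standard drift-removing convention)."""
    idx = traj.group(selection)
    if align and idx.size < 3:
        raise ValueError("alignment needs at least 3 atoms")
    ref = traj.coords[reference_frame, idx]
    values = np.array(
        [_rmsd_pair(ref, traj.coords[f, idx], align) for f in range(traj.n_frames)]
    )
    return MetricSeries(times=traj.times.copy(), values=values,
                        name=f"rmsd_{'aligned' if align else 'raw'}")


def rg_series(traj: Trajectory, selection: str) -> MetricSeries:
    """Mass-weighted radius of gyration per frame."""
    idx = traj.group(selection)
    w = traj.masses[idx]
    total = w.sum()
    if total <= 0:
        raise ValueError("selection has zero total mass")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coords[f, idx]
        com = (w[:, None] * x).sum(axis=0) / total
        values[f] = math.sqrt(float((w * np.sum((x - com) ** 2, axis=-1)).sum() / total))
    return MetricSeries(times=traj.times.copy(), values=values, name="rg")


def rmsd_matrix(traj: Trajectory, selection: str, align: bool = True) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix (used as clustering input)."""
    idx = traj.group(selection)
    if align and idx.size < 3:
        raise ValueError("alignment needs at least 3 atoms")
    x = traj.coords[:, idx, :]
    n = traj.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _rmsd_pair(x[i], x[j], align)
    return m


def cluster_frames(
    distance_matrix: np.ndarray,
    n_clusters: int = 20,
    seed: int | None = None,
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of frames cut at exactly ``n_clusters``.

    The dendrogram (average linkage by default) is cut after
    ``n_frames − n_clusters`` merges, guaranteeing exactly k non-empty
    clusters; one representative frame is drawn uniformly per cluster
    with the given seed.
    """
    m = np.asarray(distance_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
        raise ValueError("need a symmetric nonnegative matrix with zero diagonal")
    n = m.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters {n_clusters} > n_frames {n}")
    if n_clusters == n:
        labels = np.arange(n)
    else:
        z = sch.linkage(squareform(m, checks=False), method=linkage)
        labels = sch.cut_tree(z, n_clusters=n_clusters).ravel()
    rng = np.random.default_rng(seed)
    reps = np.array(
        [rng.choice(np.nonzero(labels == k)[0]) for k in range(n_clusters)]
    )
    return ClusterResult(labels=labels, representatives=reps,
                         n_clusters=n_clusters, linkage=linkage, seed=seed)


# ---------------------------------------------------------------------------
# Hydrogen bonds / salt bridges
# ---------------------------------------------------------------------------

DEFAULT_HB_CRITERIA = {"ha_cutoff": 2.8, "dha_angle_min": 120.0}  # Å, degrees
DEFAULT_SB_CUTOFF = 4.0  # Å


def hbond_count(
    coords: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    ha_cutoff: float = DEFAULT_HB_CRITERIA["ha_cutoff"],
    dha_angle_min: float = DEFAULT_HB_CRITERIA["dha_angle_min"],
    max_dh_bond: float = 1.6,
) -> int:
    """Geometric hydrogen-bond count in one frame.

    A bond requires H...A <= ``ha_cutoff`` and a D-H...A angle (at the
    hydrogen) >= ``dha_angle_min``.  Each donor is a (heavy atom, bound
    hydrogen) index pair; a pair whose H sits farther than
    ``max_dh_bond`` from D is not a bound hydrogen and raises.
    """
    coords = np.asarray(coords, dtype=float)
    acceptors = np.asarray(acceptors, dtype=int)
    count = 0
    for d, h in donors:
        if d == h:
            raise ValueError(f"donor {d} lacks a distinct bound hydrogen")
        dh = np.linalg.norm(coords[h] - coords[d])
        if dh > max_dh_bond:
            raise ValueError(
                f"donor {d}: atom {h} at {dh:.2f} Å is not a bound hydrogen"
            )
        for a in acceptors:
            if a in (d, h):
                continue
            ha = coords[a] - coords[h]
            r = np.linalg.norm(ha)
            if r > ha_cutoff:
                continue
            hd = coords[d] - coords[h]
            cosang = float(np.dot(hd, ha) / (np.linalg.norm(hd) * r))
            angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if angle >= dha_angle_min:
                count += 1
    return count


def saltbridge_count(
    coords: np.ndarray,
    cation_groups: Sequence[Sequence[int]],
    anion_groups: Sequence[Sequence[int]],
    cutoff: float = DEFAULT_SB_CUTOFF,
) -> int:
    """Salt bridges in one frame: one per charged-group pair whose closest
    cation-atom/anion-atom distance is <= ``cutoff``."""
    coords = np.asarray(coords, dtype=float)
    count = 0
    for cat in cation_groups:
        c = coords[np.asarray(cat, dtype=int)]
        for an in anion_groups:
            a = coords[np.asarray(an, dtype=int)]
            d = np.sqrt(((c[:, None, :] - a[None, :, :]) ** 2).sum(-1))
            if d.min() <= cutoff:
                count += 1
    return count


def interaction_series(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    cation_groups: Sequence[Sequence[int]],
    anion_groups: Sequence[Sequence[int]],
    hb_criteria: Mapping[str, float] | None = None,
    sb_cutoff: float = DEFAULT_SB_CUTOFF,
) -> InteractionCount:
    """Per-frame HB and SB counts with the criteria echoed in the result."""
    crit = dict(DEFAULT_HB_CRITERIA)
    if hb_criteria:
        crit.update(hb_criteria)
    hb = np.array(
        [hbond_count(traj.coords[f], donors, acceptors, **crit)
         for f in range(traj.n_frames)],
        dtype=int,
    )
    sb = np.array(
        [saltbridge_count(traj.coords[f], cation_groups, anion_groups, sb_cutoff)
         for f in range(traj.n_frames)],
        dtype=int,
    )
    return InteractionCount(
        times=traj.times.copy(),
        hb_counts=hb,
        sb_counts=sb,
        criteria={"hb": crit, "sb_cutoff": sb_cutoff},
    )


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

def compare_capture(
    replicates_a: Sequence[np.ndarray],
    replicates_b: Sequence[np.ndarray],
) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t on per-frame capture counts.

    Counts are pooled across replicates on each side (every frame is one
    observation); returns (t, two-sided p).  Zero pooled variance with
    equal means gives (0, 1) by convention.
    """
    a = np.concatenate([np.asarray(r, dtype=float).ravel() for r in replicates_a])
    b = np.concatenate([np.asarray(r, dtype=float).ravel() for r in replicates_b])
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per side")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return math.inf if a[0] > b[0] else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
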