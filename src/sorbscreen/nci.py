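"""Promolecular non-covalent interaction (NCI) analysis.

The molecular electron density is approximated as a promolecular sum of
spherically averaged free-atom densities, each fitted as a few
exponential terms rho_atom(r) = sum_j c_j exp(-r / zeta_j) in atomic
units.  From the density and its analytic derivatives the reduced
density gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))

is evaluated on a regular grid; regions with low rho and low s mark
non-covalent interactions and are classified by the sign of the middle
Hessian eigenvalue lambda_2: sign(lambda_2) * rho < 0 is attractive
(hydrogen bonding), near zero is van der Waals, > 0 is steric repulsion.
Fields are exported as Gaussian cube files for isosurface rendering in
standard NCI viewers.

All internal work is in atomic units (bohr); Å are accepted at the
interface and converted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

BOHR_PER_ANGSTROM = 1.8897259886
#: 2 (3 pi^2)^(1/3), the reduced-gradient normalisation constant
RDG_NORM = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)

#: Free-atom promolecular density fits: element -> ((c_j, zeta_j), ...) in a.u.
#: Multi-exponential fits of spherically averaged atomic densities as used
#: by promolecular NCI codes, covering H through Ar.
PROMOLECULAR_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((0.2815, 0.5288),),
    "He": ((2.437, 0.3379),),
    "Li": ((11.84, 0.1912), (0.06332, 0.9992)),
    "Be": ((31.34, 0.1390), (0.3694, 0.6945)),
    "B": ((67.82, 0.1059), (0.8527, 0.5300)),
    "C": ((120.2, 0.0884), (2.167, 0.4276)),
    "N": ((190.9, 0.0767), (3.843, 0.3481)),
    "O": ((289.5, 0.0669), (6.251, 0.3113)),
    "F": ((406.3, 0.0608), (9.613, 0.2784)),
    "Ne": ((561.3, 0.0549), (13.57, 0.2525)),
    "Na": ((760.8, 0.0496), (22.61, 0.2235), (0.06358, 0.5408)),
    "Mg": ((1016.0, 0.0449), (29.59, 0.2035), (0.3331, 0.4852)),
    "Al": ((1319.0, 0.0411), (38.60, 0.1871), (0.8878, 0.4479)),
    "Si": ((1658.0, 0.0382), (50.53, 0.1735), (0.7888, 0.4114)),
    "P": ((2042.0, 0.0358), (61.69, 0.1618), (1.465, 0.3836)),
    "S": ((2501.0, 0.0335), (77.44, 0.1515), (2.170, 0.3613)),
    "Cl": ((3024.0, 0.0315), (94.89, 0.1422), (3.369, 0.3408)),
    "Ar": ((3625.0, 0.0296), (115.2, 0.1341), (4.754, 0.3229)),
}

_ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

_NEAR_NUCLEUS_CLAMP = 1e-6  # bohr


class UnknownElementError(ValueError):
    pass


def atom_terms(element: str, table: dict | None = None) -> tuple[tuple[float, float], ...]:
    """Exponential terms for one element; heavy elements beyond the table
    fall back to the heaviest parameterised element scaled by electron
    count, with a warning."""
    tbl = PROMOLECULAR_TABLE if table is None else table
    if element in tbl:
        return tbl[element]
    if table is None and element in _ATOMIC_NUMBERS:
        z = _ATOMIC_NUMBERS[element]
        scale = z / _ATOMIC_NUMBERS["Ar"]
        warnings.warn(
            f"element {element} not parameterised; using Ar terms scaled "
            f"by electron count ({scale:.2f})",
            stacklevel=2,
        )
        return tuple((c * scale, zeta) for c, zeta in tbl["Ar"])
    raise UnknownElementError(f"no promolecular parameters for element {element!r}")


def promolecular_density(
    elements: Sequence[str],
    positions: np.ndarray,
    points: np.ndarray,
    table: dict | None = None,
    input_unit: str = "angstrom",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promolecular rho, grad rho and Hessian(rho) at arbitrary points.

    ``positions`` (n_atoms, 3) and ``points`` (n_points, 3) share
    ``input_unit`` ('angstrom' or 'bohr'); outputs are atomic units.
    The nuclear cusp is regularised by clamping r >= 1e-6 bohr.

    For one exponential term f(r) = c exp(-r/z):
        f'  = -f/z,  f'' = f/z^2
        grad = f' u                      (u = r_vec / r)
        Hess = f'' u u^T + (f'/r)(I - u u^T)
    """
    pos = np.asarray(positions, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if input_unit == "angstrom":
        pos = pos * BOHR_PER_ANGSTROM
        pts = pts * BOHR_PER_ANGSTROM
    elif input_unit != "bohr":
        raise ValueError(f"unknown input_unit {input_unit!r}")

    n_pts = pts.shape[0]
    rho = np.zeros(n_pts)
    grad = np.zeros((n_pts, 3))
    hess = np.zeros((n_pts, 3, 3))
    eye = np.eye(3)

    for el, p in zip(elements, pos):
        terms = atom_terms(el, table)
        dvec = pts - p  # (P, 3)
        r = np.linalg.norm(dvec, axis=1)
        r = np.maximum(r, _NEAR_NUCLEUS_CLAMP)
        u = dvec / r[:, None]
        uu = u[:, :, None] * u[:, None, :]  # (P, 3, 3)
        for c, zeta in terms:
            f = c * np.exp(-r / zeta)
            fp = -f / zeta
            fpp = f / zeta**2
            rho += f
            grad += fp[:, None] * u
            hess += fpp[:, None, None] * uu + (fp / r)[:, None, None] * (eye - uu)
    return rho, grad, hess


def reduced_density_gradient(rho: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)); zero where the
    gradient vanishes."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("reduced gradient requires rho > 0 everywhere")
    gnorm = np.linalg.norm(np.asarray(grad, dtype=float), axis=-1)
    return gnorm / (RDG_NORM * rho ** (4.0 / 3.0))


def signed_density(rho: np.ndarray, hess: np.ndarray) -> np.ndarray:
    """sign(lambda_2) * rho, with lambda_2 the middle Hessian eigenvalue."""
    h = np.asarray(hess, dtype=float)
    single = h.ndim == 2
    if single:
        h = h[None]
    eigvals = np.linalg.eigvalsh(h)  # ascending
    lam2 = eigvals[:, 1]
    out = np.sign(lam2) * np.atleast_1d(np.asarray(rho, dtype=float))
    return float(out[0]) if single else out


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin, per-axis spacing and point counts (bohr)."""

    origin: np.ndarray
    spacing: np.ndarray
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.counts):
            raise ValueError("grid needs at least 2 points per axis")

    @classmethod
    def around_atoms(
        cls,
        positions_ang: np.ndarray,
        spacing: float = 0.15,
        margin: float = 3.0,
    ) -> "GridSpec":
        """Grid enclosing the atoms with a margin (spacing/margin in bohr).

        Counts are made odd and the grid is centred on the atoms' bounding
        box, so a symmetric system samples its interaction midplane with a
        lattice plane instead of straddling it between points.
        """
        pos = np.asarray(positions_ang, dtype=float) * BOHR_PER_ANGSTROM
        lo = pos.min(axis=0) - margin
        hi = pos.max(axis=0) + margin
        center = (lo + hi) / 2
        counts = tuple(
            int(np.ceil((h - l) / spacing)) // 2 * 2 + 1 for l, h in zip(lo, hi)
        )
        origin = center - float(spacing) * (np.array(counts) - 1) / 2
        return cls(origin=origin, spacing=np.full(3, float(spacing)), counts=counts)

    def points(self) -> np.ndarray:
        """All grid points, x-outer / z-fastest ordering, shape (N, 3)."""
        axes = [self.origin[i] + self.spacing[i] * np.arange(self.counts[i])
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class NCIField:
    """rho, s and sign(lambda_2)*rho on a grid, with the NCI-region mask."""

    grid: GridSpec
    rho: np.ndarray
    s: np.ndarray
    signed_rho: np.ndarray
    nci_mask: np.ndarray
    classification: np.ndarray  # 0 none, 1 attractive, 2 vdW, 3 repulsive
    rho_cut: float
    s_iso: float
    bin_edges: tuple[float, float]

    def class_counts(self) -> dict[str, int]:
        return {
            "attractive": int(np.sum(self.classification == 1)),
            "vdw": int(np.sum(self.classification == 2)),
            "repulsive": int(np.sum(self.classification == 3)),
        }

    @property
    def nci_volume(self) -> float:
        """Flagged-region volume estimate (bohr^3)."""
        return float(self.nci_mask.sum()) * self.grid.voxel_volume


def nci_grid(
    elements: Sequence[str],
    positions_ang: np.ndarray,
    grid: GridSpec,
    rho_cut: float = 0.05,
    s_iso: float = 0.7,
    bin_edges: tuple[float, float] = (-0.01, 0.01),
    table: dict | None = None,
    chunk: int = 20000,
) -> NCIField:
    """Evaluate the NCI fields on a grid and classify flagged points.

    Points with rho < ``rho_cut`` and s < ``s_iso`` form the NCI region;
    within it, sign(lambda_2)*rho below ``bin_edges[0]`` is attractive,
    above ``bin_edges[1]`` repulsive, in between van der Waals.
    """
    pos = np.asarray(positions_ang, dtype=float)
    pos_bohr = pos * BOHR_PER_ANGSTROM
    lo = grid.origin
    hi = grid.origin + grid.spacing * (np.array(grid.counts) - 1)
    if np.any(pos_bohr < lo) or np.any(pos_bohr > hi):
        warnings.warn("some atoms lie outside the grid", stacklevel=2)

    pts = grid.points()
    shape = grid.counts
    rho = np.empty(pts.shape[0])
    s = np.empty(pts.shape[0])
    signed = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], chunk):
        sl = slice(start, min(start + chunk, pts.shape[0]))
        r, g, h = promolecular_density(elements, pos_bohr, pts[sl],
                                       table=table, input_unit="bohr")
        rho[sl] = r
        s[sl] = reduced_density_gradient(r, g)
        signed[sl] = signed_density(r, h)

    mask = (rho < rho_cut) & (s < s_iso)
    classification = np.zeros(pts.shape[0], dtype=np.int8)
    att, rep = bin_edges
    classification[mask & (signed < att)] = 1
    classification[mask & (signed >= att) & (signed <= rep)] = 2
    classification[mask & (signed > rep)] = 3
    return NCIField(
        grid=grid,
        rho=rho.reshape(shape),
        s=s.reshape(shape),
        signed_rho=signed.reshape(shape),
        nci_mask=mask.reshape(shape),
        classification=classification.reshape(shape),
        rho_cut=rho_cut,
        s_iso=s_iso,
        bin_edges=bin_edges,
    )


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------

def write_cube(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    elements: Sequence[str],
    positions_ang: np.ndarray,
    comment: str = "sorbscreen scalar field",
) -> None:
    """Write a scalar field as a Gaussian cube file (bohr, Z-fastest)."""
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.counts):
        raise ValueError(f"field shape {values.shape} != grid counts {grid.counts}")
    pos = np.asarray(positions_ang, dtype=float) * BOHR_PER_ANGSTROM
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{comment}\n")
        fh.write("scalar field on a regular grid\n")
        fh.write(f"{len(elements):5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}"
                 f"{grid.origin[2]:12.6f}\n")
        for i in range(3):
            vec = [0.0, 0.0, 0.0]
            vec[i] = grid.spacing[i]
            fh.write(f"{grid.counts[i]:5d}{vec[0]:12.6f}{vec[1]:12.6f}{vec[2]:12.6f}\n")
        for el, p in zip(elements, pos):
            z = _ATOMIC_NUMBERS.get(el)
            if z is None:
                raise UnknownElementError(f"no atomic number for element {el!r}")
            fh.write(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}\n")
        flat = values.ravel(order="C")  # (x, y, z) with z fastest
        for start in range(0, flat.size, 6):
            line = "".join(f"{v:15.6E}" for v in flat[start:start + 6])
            fh.write(line + "\n")


def read_cube(path: str | Path) -> tuple[np.ndarray, GridSpec, list[int], np.ndarray]:
    """Read a Gaussian cube file: (values, grid, atomic numbers, positions bohr)."""
    path = Path(path)
    with path.open() as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        n_atoms = int(parts[0])
        if n_atoms < 0:
            raise ValueError("cube files with orbital blocks are not supported")
        origin = np.array(parts[1:4], dtype=float)
        counts = []
        spacing = []
        for i in range(3):
            parts = fh.readline().split()
            counts.append(int(parts[0]))
            vec = np.array(parts[1:4], dtype=float)
            off_axis = np.delete(vec, i)
            if np.any(off_axis != 0):
                raise ValueError("non-axis-aligned cube grids are not supported")
            spacing.append(vec[i])
        numbers = []
        positions = []
        for _ in range(n_atoms):
            parts = fh.readline().split()
            numbers.append(int(parts[0]))
            positions.append([float(x) for x in parts[2:5]])
        data = np.array(fh.read().split(), dtype=float)
    grid = GridSpec(origin=origin, spacing=np.array(spacing), counts=tuple(counts))
    if data.size != np.prod(counts):
        raise ValueError(f"cube data size {data.size} != {np.prod(counts)}")
    return data.reshape(counts), grid, numbers, np.array(positions)
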