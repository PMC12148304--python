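"""Unit-cell math, symmetry-copy enumeration and steric-clash filtering.

This replaces the crystal-contacts step of interactive modelling tools:
starting from a single collagen triple helix placed in a (typically
triclinic, P1) unit cell, it enumerates every symmetry-related copy with
at least one atom within a user-chosen contact distance ``d_c`` of the
original, and removes whole copies that sterically clash.  Larger ``d_c``
pulls in lattice translations further from the origin and therefore
yields larger fibrils.

The fractional↔Cartesian mapping uses the upper-triangular crystal
orientation matrix

    C = | a   b·cosγ   c·cosβ                      |
        | 0   b·sinγ   c·(cosα − cosβ·cosγ)/sinγ   |
        | 0   0        sqrt(c² − cxz² − cyz²)      |

with cxz = c·cosβ and cyz the (2,3) entry; det(C) is the triclinic cell
volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .pdbio import PDBFormatError, Structure, parse_pdb

__all__ = [
    "UnitCell",
    "OrientationMatrix",
    "Transform",
    "parse_template",
    "orientation_matrix",
    "enumerate_symmetry_copies",
    "apply_transform",
    "remove_clashes",
    "ClashFilterResult",
    "has_clash",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # volume positivity is checked when the orientation matrix is built

    @property
    def volume(self) -> float:
        """Analytic triclinic cell volume in Å³."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            raise ValueError("degenerate cell")
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass(frozen=True)
class OrientationMatrix:
    """Upper-triangular fractional→Cartesian matrix ``C`` (Å per cell unit)."""

    C: np.ndarray
    cxz: float
    cyz: float

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.C)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.C.T

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inverse.T


@dataclass(frozen=True)
class Transform:
    """Rigid Euclidean transform q' = R·q + t (R dimensionless, t in Å)."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.R.T + self.t

    def inverse(self) -> "Transform":
        Rinv = self.R.T
        return Transform(Rinv, -Rinv @ self.t)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.R, np.eye(3), atol=1e-12) and np.allclose(self.t, 0, atol=1e-12)


def parse_template(pdb_text: str) -> tuple[list[Structure], UnitCell]:
    """Read a triple-helix template PDB: atoms grouped by chain + unit cell.

    The header must carry crystallographic information (CRYST1); residue
    numbering is preserved as-is.
    """
    if "CRYST1" not in pdb_text:
        raise PDBFormatError("no crystallographic information (CRYST1 record missing)")
    structure, cell = parse_pdb(pdb_text)
    if cell is None:  # pragma: no cover - guarded above
        raise PDBFormatError("no crystallographic information")
    return structure.chains(), cell


def orientation_matrix(cell: UnitCell) -> OrientationMatrix:
    """Build the upper-triangular orientation matrix of a cell."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    cxz = cell.c * cb
    cyz = cell.c * (ca - cb * cg) / sg
    arg = cell.c ** 2 - cxz ** 2 - cyz ** 2
    if arg <= 0:
        raise ValueError("degenerate cell")
    C = np.array([
        [cell.a, cell.b * cg, cxz],
        [0.0, cell.b * sg, cyz],
        [0.0, 0.0, math.sqrt(arg)],
    ])
    return OrientationMatrix(C=C, cxz=cxz, cyz=cyz)


def apply_transform(structure: Structure, T: Transform) -> Structure:
    """Apply q' = R·q + t to every atom; non-coordinate fields preserved."""
    out = structure.copy()
    out.coords = T(out.coords)
    return out


def _pure_translations(space_group: str) -> list[np.ndarray]:
    """Fractional translations of the group's pure-translation operators.

    Only the translational sub-lattice of non-P1 groups is applied; the
    target system (collagen) is P1, where this is exact.
    """
    symbol = (space_group or "P 1").strip()
    if symbol.upper() in ("P 1", "P1"):
        return [np.zeros(3)]
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ValueError(f"unknown space group: {symbol!r}")
    warnings.warn(
        f"space group {symbol!r}: applying translational sub-lattice only",
        stacklevel=3,
    )
    out = []
    for op in sg.operations():
        if np.array_equal(np.asarray(op.rot), np.eye(3) * op.DEN):
            out.append(np.asarray(op.tran, dtype=float) / op.DEN)
    return out


def enumerate_symmetry_copies(
    atoms: Structure | np.ndarray,
    cell: UnitCell,
    d_c: float,
) -> list[Transform]:
    """Symmetry copies with any atom within ``d_c`` Å of the original.

    Candidate lattice indices are bounded per dimension by the fractional
    extent of the molecule plus ``d_c`` divided by the perpendicular cell
    height in that direction, which guarantees no contacting copy is
    missed.  Output is ordered lexicographically in (nx, ny, nz), then
    operator index; the identity is always included.
    """
    if d_c < 0:
        raise ValueError("contact distance must be non-negative")
    coords = atoms.coords if isinstance(atoms, Structure) else np.asarray(atoms, float)
    om = orientation_matrix(cell)
    C = om.C
    trans_ops = _pure_translations(cell.space_group)

    frac = om.to_fractional(coords)
    extent = frac.max(axis=0) - frac.min(axis=0)
    # perpendicular height of the cell along each lattice direction
    axes = C.T  # rows: a, b, c in Cartesian
    vol = abs(np.linalg.det(C))
    heights = np.array([
        vol / np.linalg.norm(np.cross(axes[(i + 1) % 3], axes[(i + 2) % 3]))
        for i in range(3)
    ])
    nmax = np.ceil(extent + d_c / heights).astype(int) + 1

    tree = cKDTree(coords)
    transforms: list[Transform] = []
    for nx in range(-nmax[0], nmax[0] + 1):
        for ny in range(-nmax[1], nmax[1] + 1):
            for nz in range(-nmax[2], nmax[2] + 1):
                for op_idx, tau in enumerate(trans_ops):
                    n = np.array([nx, ny, nz], dtype=float) + tau
                    t = C @ n
                    if np.allclose(t, 0, atol=1e-12):
                        transforms.append(Transform(np.eye(3), np.zeros(3)))
                        continue
                    d, _ = tree.query(coords + t, k=1, distance_upper_bound=d_c * 1.0000001)
                    if np.min(d) <= d_c:
                        transforms.append(Transform(np.eye(3), t))
    return transforms


def has_clash(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    overlap_fraction: float = 0.6,
) -> bool:
    """True if any inter-set pair has d < overlap_fraction·(r_i + r_j)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return False
    rmax_b = float(np.max(radii_b))
    tree = cKDTree(coords_b)
    cut = overlap_fraction * (radii_a + rmax_b)
    hits = tree.query_ball_point(coords_a, cut)
    for i, js in enumerate(hits):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(coords_b[js] - coords_a[i], axis=1)
        if np.any(d < overlap_fraction * (radii_a[i] + radii_b[js])):
            return True
    return False


def _has_clash_bruteforce(coords_a, radii_a, coords_b, radii_b, overlap_fraction=0.6):
    # O(n·m) reference path used below small systems; identical contract
    if len(coords_a) == 0 or len(coords_b) == 0:
        return False
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    thr = overlap_fraction * (radii_a[:, None] + radii_b[None, :])
    return bool(np.any(d < thr))


@dataclass
class ClashFilterResult:
    kept: list
    kept_indices: list[int]
    removed_indices: list[int]


def remove_clashes(
    copies: list[Structure],
    overlap_fraction: float = 0.6,
    brute_force_threshold: int = 5000,
) -> ClashFilterResult:
    """Greedy whole-copy steric filter.

    Copies are visited in enumeration order; a copy is dropped when any
    of its atoms comes closer than ``overlap_fraction · (rw_i + rw_j)``
    to an atom of an already retained copy.  The first (identity) copy is
    never removed.
    """
    if not copies:
        raise ValueError("at least one copy required")
    kept = [copies[0]]
    kept_idx = [0]
    removed: list[int] = []
    kept_data = [(copies[0].coords, copies[0].vdw_radii)]
    for i, cp in enumerate(copies[1:], start=1):
        ca, ra = cp.coords, cp.vdw_radii
        small = len(ca) <= brute_force_threshold
        clash = False
        for cb, rb in kept_data:
            check = _has_clash_bruteforce if small and len(cb) <= brute_force_threshold else has_clash
            if check(ca, ra, cb, rb, overlap_fraction):
                clash = True
                break
        if clash:
            removed.append(i)
        else:
            kept.append(cp)
            kept_idx.append(i)
            kept_data.append((ca, ra))
    return ClashFilterResult(kept=kept, kept_indices=kept_idx, removed_indices=removed)
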