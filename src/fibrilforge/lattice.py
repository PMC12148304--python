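"""Bravais-lattice representation of a fibril and layer-by-layer optimization.

Each symmetry copy of the template triple helix corresponds to an
integer lattice point ``p = C⁻¹·t`` (with ``C`` the crystal orientation
matrix and ``t`` the copy's Cartesian translation), so the fibril is a
finite set of occupied points of the Bravais lattice.  Symmetry
expansion under a spherical contact-distance rule leaves the outermost
``nz`` layers depleted — boundary molecules lack crosslink partners.
The optimizer therefore revisits the ``δz`` top and bottom layers: for
each layer it spans the rectangle between the extreme occupied
(nx, ny) indices, visits the vacancies in random (seeded) order, and
adds a candidate molecule whenever its crosslink atoms come within the
contact cutoff (3 Å, typical for non-covalent protein contacts) of an
existing molecule's crosslink atoms without introducing steric clashes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crosslinks import CrosslinkSite, CrosslinkUnit
from .crystal import OrientationMatrix, Transform, UnitCell, has_clash
from .pdbio import Structure

__all__ = [
    "LatticeError",
    "SolutionSpace",
    "Molecule",
    "FibrilSystem",
    "map_to_lattice",
    "layer_candidates",
    "optimize_layers",
    "connectivity_stats",
    "density_profile",
]


class LatticeError(ValueError):
    pass


@dataclass(frozen=True)
class SolutionSpace:
    """Bounds of the optimization search space δ = (δx, δy, δz).

    ``δz`` selects the ``2·δz`` boundary nz-layers for optimization;
    ``δx``/``δy`` optionally pad the candidate rectangle (default 0).
    """

    dx: int = 0
    dy: int = 0
    dz: int = 0

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) < 0:
            raise ValueError("solution-space components must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "SolutionSpace":
        parts = [int(x) for x in text.split(",")]
        return cls(*parts)


@dataclass
class Molecule:
    """One triple-helix copy: structure, transform, lattice point, sites."""

    model_id: int
    structure: Structure
    transform: Transform
    lattice_point: np.ndarray
    sites: list[CrosslinkSite] = field(default_factory=list)
    crosslink_class: str | None = None

    def __post_init__(self) -> None:
        self.lattice_point = np.asarray(self.lattice_point, dtype=int).reshape(3)

    def site_coords(self, terminus: str | None = None) -> np.ndarray:
        coords = [s.positions(self.structure) for s in self.sites
                  if terminus is None or s.terminus == terminus]
        if not coords:
            return np.empty((0, 3))
        return np.concatenate(coords, axis=0)


@dataclass
class FibrilSystem:
    """Ensemble of molecules sharing one unit cell."""

    molecules: list[Molecule]
    cell: UnitCell
    orientation: OrientationMatrix
    crosslink_units: list[CrosslinkUnit] = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.molecules]
        if len(ids) != len(set(ids)):
            raise ValueError("molecule model ids must be unique")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def lattice_points(self) -> np.ndarray:
        if not self.molecules:
            return np.empty((0, 3), dtype=int)
        return np.stack([m.lattice_point for m in self.molecules])

    def occupied(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in m.lattice_point) for m in self.molecules}


def map_to_lattice(t: np.ndarray, C: OrientationMatrix, tol: float = 1e-3) -> np.ndarray:
    """Map a Cartesian translation to its Bravais lattice point p = C⁻¹·t."""
    p = C.inverse @ np.asarray(t, dtype=float).reshape(3)
    rounded = np.round(p)
    if np.max(np.abs(p - rounded)) > tol:
        raise LatticeError(
            f"translation off Bravais lattice: C^-1 t = {p} (tol {tol})")
    return rounded.astype(int)


def layer_candidates(system: FibrilSystem, lz: int,
                     delta: SolutionSpace) -> set[tuple[int, int, int]]:
    """Vacant points of layer ``lz``'s bounding rectangle: P_rec \\ P_occupied.

    The rectangle spans the extreme occupied (nx, ny) indices in the
    layer, optionally padded by (δx, δy).
    """
    occ = system.lattice_points()
    in_layer = occ[occ[:, 2] == lz] if len(occ) else occ
    if len(in_layer) == 0:
        return set()
    x0, x1 = in_layer[:, 0].min() - delta.dx, in_layer[:, 0].max() + delta.dx
    y0, y1 = in_layer[:, 1].min() - delta.dy, in_layer[:, 1].max() + delta.dy
    occupied = {(int(p[0]), int(p[1])) for p in in_layer}
    return {(x, y, lz) for x in range(x0, x1 + 1) for y in range(y0, y1 + 1)
            if (x, y) not in occupied}


def _selected_layers(system: FibrilSystem, dz: int) -> list[int]:
    """Boundary layers, outermost first, lower block before upper block."""
    occ = system.lattice_points()
    if len(occ) == 0 or dz == 0:
        return []
    nz_min, nz_max = int(occ[:, 2].min()), int(occ[:, 2].max())
    lower = [nz_min + i for i in range(dz)]
    upper = [nz_max - i for i in range(dz)]
    out = []
    for lz in lower + upper:
        if nz_min <= lz <= nz_max and lz not in out:
            out.append(lz)
    return out


@dataclass
class LayerReport:
    layer: int
    candidates: int
    accepted: int
    rejected_distance: int
    rejected_clash: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def optimize_layers(
    system: FibrilSystem,
    delta: SolutionSpace,
    contact_cutoff: float = 3.0,
    seed: int = 0,
    overlap_fraction: float = 0.6,
) -> list[LayerReport]:
    """Fill crosslinkable vacancies in the δz boundary layers (in place).

    Candidates are visited uniformly at random without replacement
    (seeded).  A trial molecule — the reference molecule translated by
    ``t' = C·(p' − p_ref)`` — is accepted iff at least one of its
    crosslink atoms lies within ``contact_cutoff`` of an existing
    molecule's crosslink atoms and it introduces no steric clash.
    Pre-existing molecules are never removed; zero additions is a valid
    outcome.
    """
    reports: list[LayerReport] = []
    if not system.molecules:
        return reports
    rng = np.random.default_rng(seed)
    C = system.orientation.C
    ref = system.molecules[0]
    if all(len(m.sites) == 0 for m in system.molecules):
        warnings.warn("no crosslink sites in system; nothing to optimize")
        return reports

    def all_site_coords() -> np.ndarray:
        arrs = [m.site_coords() for m in system.molecules]
        arrs = [a for a in arrs if len(a)]
        return np.concatenate(arrs, axis=0) if arrs else np.empty((0, 3))

    next_id = max(m.model_id for m in system.molecules) + 1
    for lz in _selected_layers(system, delta.dz):
        cands = sorted(layer_candidates(system, lz, delta))
        order = rng.permutation(len(cands))
        accepted = rej_d = rej_c = 0
        site_tree = cKDTree(all_site_coords()) if len(all_site_coords()) else None
        for k in order:
            p_new = np.array(cands[k], dtype=int)
            t_shift = C @ (p_new - ref.lattice_point)
            trial_sites = ref.site_coords() + t_shift
            if site_tree is None or len(trial_sites) == 0:
                rej_d += 1
                continue
            d, _ = site_tree.query(trial_sites, k=1,
                                   distance_upper_bound=contact_cutoff * 1.0000001)
            if np.min(d) >= contact_cutoff:
                rej_d += 1
                continue
            trial_coords = ref.structure.coords + t_shift
            trial_radii = ref.structure.vdw_radii
            clash = any(
                has_clash(trial_coords, trial_radii, m.structure.coords,
                          m.structure.vdw_radii, overlap_fraction)
                for m in system.molecules
            )
            if clash:
                rej_c += 1
                continue
            new_structure = ref.structure.translated(t_shift)
            new_sites = [
                CrosslinkSite(s.type_name, s.valence, s.terminus,
                              list(s.residues), s.atom_indices.copy())
                for s in ref.sites
            ]
            t_new = ref.transform.t + t_shift
            system.molecules.append(Molecule(
                model_id=next_id,
                structure=new_structure,
                transform=Transform(np.eye(3), t_new),
                lattice_point=p_new,
                sites=new_sites,
            ))
            next_id += 1
            accepted += 1
            site_tree = cKDTree(all_site_coords())
        reports.append(LayerReport(lz, len(cands), accepted, rej_d, rej_c))
    return reports


def write_report_jsonl(reports: list[LayerReport], path: str) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(r.to_json() + "\n")


def connectivity_stats(system: FibrilSystem,
                       contact_cutoff: float = 3.0) -> tuple[float, float, float]:
    """Fractions of molecules crosslinked at (both ends, one end, neither).

    An end counts as connected when any of its crosslink atoms lies
    within ``contact_cutoff`` of another molecule's crosslink atoms.
    """
    mols = system.molecules
    if not mols:
        raise ValueError("empty system")
    other_trees = []
    all_coords = []
    owner = []
    for i, m in enumerate(mols):
        c = m.site_coords()
        if len(c):
            all_coords.append(c)
            owner.extend([i] * len(c))
    if not all_coords:
        return (0.0, 0.0, 1.0)
    pool = np.concatenate(all_coords, axis=0)
    owner = np.asarray(owner)
    tree = cKDTree(pool)

    both = one = none = 0
    for i, m in enumerate(mols):
        ends = 0
        for terminus in ("N", "C"):
            c = m.site_coords(terminus)
            if len(c) == 0:
                continue
            hits = tree.query_ball_point(c, contact_cutoff)
            if any(owner[j] != i for js in hits for j in js):
                ends += 1
        if ends == 2:
            both += 1
        elif ends == 1:
            one += 1
        else:
            none += 1
    n = len(mols)
    return (both / n, one / n, none / n)


@dataclass
class DensityProfile:
    shell_edges: np.ndarray  # Å
    density: np.ndarray      # points per Å² of transverse shell area
    occupancy_std: float     # std of per-cell 0/1 occupancy over layer rectangles


def density_profile(system: FibrilSystem,
                    shells: np.ndarray | int = 8) -> DensityProfile:
    """Radial point density about the lattice origin and packing uniformity.

    Lattice points are mapped to Cartesian space, projected on the plane
    perpendicular to the fibril (z) axis, and counted per radial shell,
    normalized by shell area.  The packing-uniformity metric is the
    standard deviation of the 0/1 occupancy over each layer's bounding
    rectangle (lower is more uniform).
    """
    pts = system.lattice_points()
    if len(pts) == 0:
        raise ValueError("empty system")
    cart = pts @ system.orientation.C.T
    r = np.linalg.norm(cart[:, :2], axis=1)
    if isinstance(shells, int):
        edges = np.linspace(0.0, max(float(r.max()), 1e-9) * 1.0001, shells + 1)
    else:
        edges = np.asarray(shells, dtype=float)
    counts, _ = np.histogram(r, bins=edges)
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    density = counts / area

    occ_cells = []
    for lz in np.unique(pts[:, 2]):
        layer = pts[pts[:, 2] == lz]
        x0, x1 = layer[:, 0].min(), layer[:, 0].max()
        y0, y1 = layer[:, 1].min(), layer[:, 1].max()
        grid = np.zeros((x1 - x0 + 1, y1 - y0 + 1))
        grid[layer[:, 0] - x0, layer[:, 1] - y0] = 1.0
        occ_cells.append(grid.ravel())
    occ = np.concatenate(occ_cells)
    return DensityProfile(edges, density, float(occ.std()))
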