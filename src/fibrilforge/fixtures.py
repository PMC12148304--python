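"""Deterministic synthetic test inputs: ideal helices, templates, fibrils.

Everything here is generated programmatically — no downloads — and is
deliberately skeletal rather than biochemically realistic:

* :func:`make_triple_helix` builds an idealized Gly-Pro-Hyp triple helix
  with a canonical axial rise of 2.86 Å per residue (8.58 Å per
  triplet), full backbone and optional idealized side chains.  It is the
  fixture for the axial-rise and threading metrics.
* :func:`make_template` emits PDB text of a one-molecule unit cell whose
  c axis encodes a designed 67 nm axial period: crosslink-capable
  residues sit at z = 0 (N terminus) and z = overlap (C terminus), so
  the symmetry-expanded system shows bands spaced overlap/gap apart.
  The body is a Cα-only triple helix spanning nearly the whole cell so
  that axial neighbors fall within modest contact distances.  Crosslink
  reach is lateral: each site carries reactive atoms extended ±6.5 Å
  toward the four lateral neighbors, whose 15 Å pitch leaves 2 Å
  between reactive atoms of adjacent molecules (crosslinkable at the
  3 Å contact cutoff, yet clash-free).
* :func:`make_fibril` assembles a pre-staggered system with explicit
  crosslink units (pairs of molecules mutually linked at both termini),
  designed D-band positions 0, 27, 67, 94, … nm, and 1.5 nm lateral
  pitch — ready for crosslink and analysis tests without expansion.
* :func:`make_lattice_system` builds a filled (nx × ny × nz) lattice
  with chosen vacancies, the fixture for the layer optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crosslinks import CrosslinkSite, CrosslinkUnit, detect_sites
from .crystal import Transform, UnitCell, orientation_matrix
from .geometry import build_side_chain
from .lattice import FibrilSystem, Molecule
from .pdbio import Structure, concat, write_pdb

__all__ = [
    "HelixParams",
    "make_triple_helix",
    "make_template",
    "make_fibril",
    "make_lattice_system",
    "DEFAULT_CELL",
]

#: Collagen-like synthetic cell: 1.5 nm lateral pitch, 67 nm axial period.
DEFAULT_CELL = UnitCell(15.0, 15.0, 670.0, 90.0, 90.0, 90.0, "P 1")

LATERAL_REACH = 6.5  # Å; reactive-atom extension toward lateral neighbors


@dataclass(frozen=True)
class HelixParams:
    """Parameters of the idealized triple helix."""

    residues_per_chain: int = 30
    rise_per_residue: float = 2.86      # Å; canonical collagen value
    twist_per_residue: float = -102.86  # degrees (left-handed PPII-like)
    radius: float = 2.5                 # Å; chain distance from the axis
    phases: tuple[float, float, float] = (0.0, 120.0, 240.0)
    repeat: str = "GPO"                 # Gly-Pro-Hyp

    def __post_init__(self) -> None:
        if self.rise_per_residue <= 0:
            raise ValueError("rise must be positive")
        if self.repeat[0] != "G" or len(self.repeat) != 3:
            raise ValueError("repeat must be a Gly-led triplet")


_REPEAT_RESNAMES = {"G": "GLY", "P": "PRO", "O": "HYP", "A": "ALA", "S": "SER"}


def _helix_point(t: float, phase_deg: float, p: HelixParams) -> np.ndarray:
    theta = np.radians(t * p.twist_per_residue + phase_deg)
    return np.array([p.radius * np.cos(theta), p.radius * np.sin(theta),
                     t * p.rise_per_residue])


def make_triple_helix(params: HelixParams | None = None,
                      side_chains: bool = True) -> Structure:
    """Idealized three-chain Gly-X-Y helix; Gly Cα axial spacing = 3·rise.

    Deterministic: two calls with equal parameters are bit-identical.
    The three chains sit at 120° phase offsets around a common axis, so
    the principal axis of the Cα cloud is exactly the helix axis.
    """
    p = params or HelixParams()
    rows = {k: [] for k in ("serial", "name", "resname", "chain", "resseq",
                            "element", "coords")}

    def add(name, resname, chain, resseq, element, pos):
        rows["serial"].append(len(rows["serial"]) + 1)
        rows["name"].append(name)
        rows["resname"].append(resname)
        rows["chain"].append(chain)
        rows["resseq"].append(resseq)
        rows["element"].append(element)
        rows["coords"].append(pos)

    for chain, phase in zip("ABC", p.phases):
        for j in range(p.residues_per_chain):
            letter = p.repeat[j % 3]
            resname = _REPEAT_RESNAMES[letter]
            ca = _helix_point(j, phase, p)
            n = _helix_point(j - 0.35, phase, p)
            c = _helix_point(j + 0.35, phase, p)
            radial = np.array([*(c[:2] / np.linalg.norm(c[:2])), 0.0])
            o = c + 1.23 * radial
            add("N", resname, chain, j + 1, "N", n)
            add("CA", resname, chain, j + 1, "C", ca)
            add("C", resname, chain, j + 1, "C", c)
            add("O", resname, chain, j + 1, "O", o)
            if side_chains and resname != "GLY":
                names, coords, elems = build_side_chain(resname, n, ca, c)
                for nm, crd, el in zip(names, coords, elems):
                    add(nm, resname, chain, j + 1, el, crd)

    return Structure(
        serial=np.array(rows["serial"], dtype=np.int64),
        name=np.array(rows["name"], dtype="U4"),
        resname=np.array(rows["resname"], dtype="U4"),
        chain_id=np.array(rows["chain"], dtype="U2"),
        resseq=np.array(rows["resseq"], dtype=np.int64),
        element=np.array(rows["element"], dtype="U2"),
        coords=np.array(rows["coords"], dtype=np.float64),
    )


def _site_residue(resseq: int, z: float, reach: float, chain: str = "A") -> Structure:
    """Synthetic crosslink-site residue: on-axis CA + 4 lateral reactive atoms."""
    names = ["CA", "NZ1", "NZ2", "NZ3", "NZ4"]
    coords = np.array([
        [0.0, 0.0, z],
        [reach, 0.0, z],
        [-reach, 0.0, z],
        [0.0, reach, z],
        [0.0, -reach, z],
    ])
    m = len(names)
    return Structure(
        serial=np.arange(m, dtype=np.int64),
        name=np.array(names, dtype="U4"),
        resname=np.full(m, "XLS", dtype="U4"),
        chain_id=np.full(m, chain, dtype="U2"),
        resseq=np.full(m, resseq, dtype=np.int64),
        element=np.array(["C", "N", "N", "N", "N"], dtype="U2"),
        coords=coords,
        hetero=np.ones(m, dtype=bool),
    )


def _skeleton_molecule(body_residues: int, overlap_nm: float,
                       reach: float = LATERAL_REACH,
                       rise: float = 2.86) -> Structure:
    """Cα-only triple-helix body plus XLS crosslink sites at z = 0 and
    z = overlap (the designed gap/overlap transition positions)."""
    p = HelixParams(residues_per_chain=body_residues, rise_per_residue=rise)
    parts = [_site_residue(0, 0.0, reach)]
    body_rows = make_triple_helix(p, side_chains=False)
    body = body_rows.select(body_rows.name == "CA")
    parts.append(body)
    parts.append(_site_residue(body_residues + 1, overlap_nm * 10.0, reach))
    out = concat(parts)
    out.serial = np.arange(1, len(out) + 1)
    return out


def make_template(cell: UnitCell | None = None, overlap_nm: float = 27.0,
                  body_residues: int = 231,
                  reach: float = LATERAL_REACH) -> str:
    """PDB text of a synthetic one-molecule template with CRYST1 header.

    Defaults: 15 Å lateral pitch, 670 Å axial period, crosslink sites at
    z = 0 and z = 270 Å, body spanning ~658 Å so axial neighbors are
    within small contact distances.  Symmetry expansion then yields
    crosslink bands spaced 27 nm (overlap) and 40 nm (gap) apart, i.e. a
    designed 67 nm D-period.
    """
    cell = cell or DEFAULT_CELL
    if not 0.0 <= overlap_nm * 10.0 <= cell.c:
        raise ValueError("crosslink sites outside cell")
    body_span = (body_residues - 1) * 2.86
    if body_span >= cell.c:
        raise ValueError("molecule longer than the c axis")
    mol = _skeleton_molecule(body_residues, overlap_nm, reach)
    return write_pdb(mol, cell=cell)


def _molecule_from_skeleton(model_id: int, skeleton: Structure,
                            lattice_point, C: np.ndarray,
                            site_template: list[CrosslinkSite] | None = None) -> Molecule:
    p = np.asarray(lattice_point, dtype=int)
    t = C @ p.astype(float)
    st = skeleton.translated(t)
    if site_template is None:
        site_template = detect_sites(skeleton)
    sites = [CrosslinkSite(s.type_name, s.valence, s.terminus,
                           list(s.residues), s.atom_indices.copy())
             for s in site_template]
    return Molecule(model_id=model_id, structure=st,
                    transform=Transform(np.eye(3), t),
                    lattice_point=p, sites=sites)


def make_fibril(n_molecules: int, mix=None, seed: int = 0,
                overlap_nm: float = 27.0, n_periods: int = 5,
                body_residues: int = 24) -> FibrilSystem:
    """Pre-assembled staggered fibril with explicit crosslink units.

    Molecules are placed in lateral pairs (grid columns 0 and 1, one row
    per pair, 15 Å pitch); each pair is mutually crosslinked at both
    termini, so an even ``n_molecules`` gives full both-end
    connectivity.  Pair rows cycle through ``n_periods`` axial offsets
    of one 67 nm period, which reproduces the designed band positions
    0, 27, 67, 94, … nm.
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    cell = DEFAULT_CELL
    C = orientation_matrix(cell).C
    skeleton = _skeleton_molecule(body_residues, overlap_nm)
    site_template = detect_sites(skeleton)
    molecules = []
    units: list[CrosslinkUnit] = []
    for m in range(n_molecules):
        pair, col = divmod(m, 2)
        lp = (col, pair, pair % n_periods)
        molecules.append(_molecule_from_skeleton(m, skeleton, lp, C, site_template))
    for pair in range(n_molecules // 2):
        a, b = 2 * pair, 2 * pair + 1
        for terminus, resseq in (("N", 0), ("C", body_residues + 1)):
            units.append(CrosslinkUnit(
                type_name="SYNX", valence="divalent", terminus=terminus,
                members=[(a, "A", resseq), (b, "A", resseq)],
            ))
    system = FibrilSystem(molecules=molecules, cell=cell,
                          orientation=orientation_matrix(cell),
                          crosslink_units=units, rng_seed=seed)
    if mix is not None:
        from .crosslinks import assign_mix
        assign_mix(system, mix, seed)
    return system


def make_lattice_system(shape: tuple[int, int, int],
                        vacancies: list[tuple[int, int, int]] | None = None,
                        body_residues: int = 8,
                        overlap_nm: float = 2.0,
                        seed: int = 0) -> FibrilSystem:
    """Filled (nx × ny × nz) Bravais lattice with designed vacancies.

    Every molecule carries laterally reaching crosslink sites, so any
    vacancy is crosslinkable from its lateral neighbors — the fixture
    for the layer-by-layer optimizer.
    """
    vacancies = set(vacancies or [])
    cell = DEFAULT_CELL
    C = orientation_matrix(cell).C
    skeleton = _skeleton_molecule(body_residues, overlap_nm)
    site_template = detect_sites(skeleton)
    molecules = []
    mid = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if (x, y, z) in vacancies:
                    continue
                molecules.append(_molecule_from_skeleton(mid, skeleton, (x, y, z), C,
                                                         site_template))
                mid += 1
    return FibrilSystem(molecules=molecules, cell=cell,
                        orientation=orientation_matrix(cell),
                        rng_seed=seed)
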