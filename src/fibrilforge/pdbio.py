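"""Lightweight atomic-structure container and PDB input/output.

The in-memory representation is a :class:`Structure` of parallel numpy
arrays — one row per atom — which keeps the heavy geometry operations
(symmetry expansion, clash filtering, lattice optimization) vectorized.
Parsing goes through gemmi; writing is a fixed-width PDB v3.3 formatter
so that segment identifiers and the wide-serial (hybrid-36) dialect used
for assemblies beyond 99,999 atoms are under explicit control.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Structure",
    "parse_pdb",
    "write_pdb",
    "vdw_radius",
    "VDW_RADII",
    "PDBFormatError",
]


class PDBFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


#: van der Waals radii in Å (Bondi 1964 with common extensions).
#: Unknown elements fall back to 1.7 Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 2.05,
    "SE": 1.90,
}

DEFAULT_VDW = 1.7


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW)


@dataclass
class Structure:
    """Parallel-array atomic structure.

    All string arrays are fixed-width unicode; ``coords`` is an (N, 3)
    float64 array in Å.  ``segid`` carries the per-molecule segment
    identifier used when merging many molecules into one assembly.
    """

    serial: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    name: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U4"))
    resname: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U4"))
    chain_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U2"))
    resseq: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    element: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U2"))
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.float64))
    segid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U4"))
    hetero: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        n = len(self.serial)
        if len(self.segid) == 0 and n:
            self.segid = np.full(n, "", dtype="U4")
        if len(self.hetero) == 0 and n:
            self.hetero = np.zeros(n, dtype=bool)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(), self.name.copy(), self.resname.copy(),
            self.chain_id.copy(), self.resseq.copy(), self.element.copy(),
            self.coords.copy(), self.segid.copy(), self.hetero.copy(),
        )

    def select(self, mask: np.ndarray) -> "Structure":
        return Structure(
            self.serial[mask], self.name[mask], self.resname[mask],
            self.chain_id[mask], self.resseq[mask], self.element[mask],
            self.coords[mask], self.segid[mask], self.hetero[mask],
        )

    def translated(self, t: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = out.coords + np.asarray(t, dtype=float).reshape(1, 3)
        return out

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.element])

    # -- residue / chain helpers ----------------------------------------
    def chain_ids(self) -> list[str]:
        """Unique chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c, s in zip(self.chain_id, self.segid):
            seen.setdefault((c, s), None)  # type: ignore[arg-type]
        return [c for c, _ in seen]

    def chains(self) -> list["Structure"]:
        """Split into per-(segid, chain) structures, order preserved."""
        keys = list(zip(self.segid, self.chain_id))
        seen: dict[tuple, None] = {}
        for k in keys:
            seen.setdefault(k, None)
        out = []
        karr = np.array(["|".join(k) for k in keys])
        for k in seen:
            out.append(self.select(karr == "|".join(k)))
        return out

    def iter_residues(self):
        """Yield (chain_id, resseq, resname, index array) in file order."""
        if not len(self):
            return
        key = np.stack([self.segid, self.chain_id, self.resseq.astype("U8")], axis=1)
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or tuple(key[i]) != tuple(key[start]):
                idx = np.arange(start, i)
                yield self.chain_id[start], int(self.resseq[start]), self.resname[start], idx
                start = i

    def residue_atoms(self, chain_id: str, resseq: int) -> np.ndarray:
        return np.where((self.chain_id == chain_id) & (self.resseq == resseq))[0]

    def atom_index(self, chain_id: str, resseq: int, name: str) -> int:
        idx = np.where(
            (self.chain_id == chain_id) & (self.resseq == resseq) & (self.name == name)
        )[0]
        if len(idx) != 1:
            raise KeyError(f"atom {chain_id}/{resseq}/{name}: {len(idx)} matches")
        return int(idx[0])


def concat(structures: list[Structure]) -> Structure:
    if not structures:
        return Structure()
    return Structure(
        np.concatenate([s.serial for s in structures]),
        np.concatenate([s.name for s in structures]),
        np.concatenate([s.resname for s in structures]),
        np.concatenate([s.chain_id for s in structures]),
        np.concatenate([s.resseq for s in structures]),
        np.concatenate([s.element for s in structures]),
        np.concatenate([s.coords for s in structures], axis=0),
        np.concatenate([s.segid for s in structures]),
        np.concatenate([s.hetero for s in structures]),
    )


# ---------------------------------------------------------------------------
# parsing


def parse_pdb(text: str):
    """Parse PDB text into (Structure, UnitCell | None).

    Returns the unit cell (crystal symmetry) as a
    :class:`fibrilforge.crystal.UnitCell` when a CRYST1 record is
    present, else ``None``.
    """
    from .crystal import UnitCell  # deferred: avoids import cycle

    st = gemmi.read_pdb_string(text)
    cell = None
    if "CRYST1" in text:
        g = st.cell
        cell = UnitCell(g.a, g.b, g.c, g.alpha, g.beta, g.gamma,
                        st.spacegroup_hm or "P 1")

    serial, name, resname, chain, resseq, element, coords, segid, het = (
        [], [], [], [], [], [], [], [], [])
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    serial.append(atom.serial)
                    name.append(atom.name)
                    resname.append(res.name)
                    chain.append(ch.name)
                    resseq.append(res.seqid.num)
                    element.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    segid.append(res.segment)
                    het.append(res.het_flag == "H")
        break  # first model only

    if not serial:
        raise PDBFormatError("empty structure: no ATOM records")

    structure = Structure(
        np.array(serial, dtype=np.int64),
        np.array(name, dtype="U4"),
        np.array(resname, dtype="U4"),
        np.array(chain, dtype="U2"),
        np.array(resseq, dtype=np.int64),
        np.array(element, dtype="U2"),
        np.array(coords, dtype=np.float64),
        np.array(segid, dtype="U4"),
        np.array(het, dtype=bool),
    )
    return structure, cell


# ---------------------------------------------------------------------------
# writing

_H36_DIGITS = string.digits + string.ascii_uppercase
_H36_DIGITS_LOW = string.digits + string.ascii_lowercase


def _encode_serial(serial: int) -> str:
    """Atom serial for the 5-column field; hybrid-36 beyond 99999."""
    if serial < 100000:
        return f"{serial:5d}"
    # hybrid-36: upper-case block then lower-case block (cctbx convention)
    v = serial - 100000 + 10 * 36 ** 4
    if v < 36 ** 5:
        return _to_base(v, _H36_DIGITS)
    v = serial - 100000 - 26 * 36 ** 4 + 10 * 36 ** 4
    return _to_base(v, _H36_DIGITS_LOW)


def _to_base(v: int, digits: str) -> str:
    out = ""
    for _ in range(5):
        out = digits[v % 36] + out
        v //= 36
    return out


def format_cryst1(cell) -> str:
    return (
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} "
        f"{cell.space_group:<11s}{1:4d}"
    )


def write_pdb(structure: Structure, cell=None, renumber: bool = True) -> str:
    """Serialize to PDB v3.3 text (TER between chains, END terminator).

    Assemblies with more than 99,999 atoms switch the serial field to the
    hybrid-36 dialect with a warning.
    """
    lines: list[str] = []
    if cell is not None:
        lines.append(format_cryst1(cell))

    n = len(structure)
    if n > 99999:
        warnings.warn(
            "structure exceeds 99,999 atoms; writing hybrid-36 (wide) serials",
            stacklevel=2,
        )
    serials = np.arange(1, n + 1) if renumber else structure.serial

    prev_key = None
    for i in range(n):
        key = (structure.segid[i], structure.chain_id[i])
        if prev_key is not None and key != prev_key:
            lines.append("TER")
        prev_key = key
        name = structure.name[i]
        # atom-name column convention: 1/2-char element names start col 14
        if len(name) < 4 and len(structure.element[i].strip()) < 2:
            name_f = f" {name:<3s}"
        else:
            name_f = f"{name:<4s}"
        record = "HETATM" if structure.hetero[i] else "ATOM  "
        x, y, z = structure.coords[i]
        lines.append(
            f"{record}{_encode_serial(int(serials[i]))} {name_f} "
            f"{structure.resname[i]:<3s} {structure.chain_id[i]:>1s}"
            f"{int(structure.resseq[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
            f"{structure.segid[i]:<4s}{structure.element[i]:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
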