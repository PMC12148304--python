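"""Crosslink type registry, site bookkeeping, ratio mixing and removal.

Collagen fibrils are stabilized by lysine-derived covalent crosslinks in
the telopeptide regions: divalent types such as hydroxylysine-keto-
norleucine (HLKNL, two member residues) and trivalent types such as
hydroxylysyl-pyridinoline (PYD, three members).  This module provides

* a user-extensible YAML registry of crosslink types,
* per-molecule class assignment from a ratio specification (mixing
  divalent/trivalent chemistry across the fibril),
* random removal of crosslink units at a given rate, replacing every
  member residue with lysine rebuilt at idealized geometry, and
* geometric detection of crosslinked site pairs between molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .geometry import build_side_chain
from .pdbio import Structure, concat

__all__ = [
    "CrosslinkType",
    "CrosslinkSite",
    "CrosslinkUnit",
    "MixSpec",
    "load_registry",
    "assign_mix",
    "remove_crosslinks",
    "detect_links",
]

VALENCE_SIZE = {"divalent": 2, "trivalent": 3}


@dataclass(frozen=True)
class CrosslinkType:
    name: str
    valence: str  # "divalent" | "trivalent"
    residues: tuple[str, ...]  # member residue codes, one per participant
    reactive_atoms: dict  # residue code -> list of reactive atom names
    description: str = ""

    def __post_init__(self) -> None:
        if self.valence not in VALENCE_SIZE:
            raise ValueError(f"{self.name}: valence must be divalent or trivalent")
        if len(self.residues) != VALENCE_SIZE[self.valence]:
            raise ValueError(
                f"{self.name}: {self.valence} crosslink must join exactly "
                f"{VALENCE_SIZE[self.valence]} residues"
            )


def load_registry(extra_path: str | None = None) -> dict[str, CrosslinkType]:
    """Load the built-in crosslink library, optionally merging a user file."""
    global _BUILTIN_REGISTRY
    if extra_path is None:
        if _BUILTIN_REGISTRY is None:
            _BUILTIN_REGISTRY = _load_registry_uncached(None)
        return dict(_BUILTIN_REGISTRY)
    return _load_registry_uncached(extra_path)


_BUILTIN_REGISTRY: dict[str, CrosslinkType] | None = None


def _load_registry_uncached(extra_path: str | None) -> dict[str, CrosslinkType]:
    with resources.files("fibrilforge.data").joinpath("crosslinks.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if extra_path is not None:
        with open(extra_path) as fh:
            user = yaml.safe_load(fh)
        raw["types"].update(user.get("types", {}))
    out = {}
    for name, spec in raw["types"].items():
        out[name] = CrosslinkType(
            name=name,
            valence=spec["valence"],
            residues=tuple(spec["residues"]),
            reactive_atoms=dict(spec["reactive_atoms"]),
            description=spec.get("description", ""),
        )
    return out


@dataclass
class CrosslinkSite:
    """One molecule's half (or third) of a potential crosslink.

    ``atom_indices`` index the reactive side-chain atoms within the parent
    molecule's structure; positions are always read live from there.
    """

    type_name: str
    valence: str
    terminus: str  # "N" | "C"
    residues: list[tuple[str, int]]  # (chain_id, resseq) of member residues
    atom_indices: np.ndarray

    def positions(self, structure: Structure) -> np.ndarray:
        return structure.coords[self.atom_indices]


@dataclass
class CrosslinkUnit:
    """A realized crosslink joining 2 (divalent) or 3 (trivalent) residues."""

    type_name: str
    valence: str
    terminus: str
    members: list[tuple[int, str, int]]  # (model_id, chain_id, resseq)

    def __post_init__(self) -> None:
        if len(self.members) != VALENCE_SIZE[self.valence]:
            raise ValueError(
                f"{self.valence} unit must have {VALENCE_SIZE[self.valence]} members"
            )


@dataclass
class MixSpec:
    """Ratios of molecule crosslink classes.

    Keys are either a single registry type name (same chemistry at both
    telopeptides, e.g. ``"PYD"``) or ``"N_TYPE-C_TYPE"`` for distinct
    N-/C-terminal chemistry (the four divalent/trivalent combinations).
    Weights are normalized to sum to one.
    """

    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty mix specification")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("mix weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("mix weights sum to zero")
        self.weights = {k: w / total for k, w in self.weights.items()}

    def terminal_types(self, cls: str) -> tuple[str, str]:
        if "-" in cls:
            n_type, c_type = cls.split("-", 1)
        else:
            n_type = c_type = cls
        return n_type, c_type

    def validate(self, registry: dict[str, CrosslinkType]) -> None:
        for cls in self.weights:
            for t in self.terminal_types(cls):
                if t not in registry:
                    raise KeyError(f"class not in crosslink library: {t!r}")

    @classmethod
    def parse(cls, text: str) -> "MixSpec":
        """Parse ``"PYD=0.5,HLKNL=0.5"`` style strings."""
        weights = {}
        for part in text.split(","):
            name, _, val = part.partition("=")
            weights[name.strip()] = float(val)
        return cls(weights)


def assign_mix(system, mix: MixSpec, seed: int,
               registry: dict[str, CrosslinkType] | None = None) -> dict[str, int]:
    """Assign each molecule a crosslink class with the given probabilities.

    Sites are retyped in place (type name, valence, and member residue
    codes from the registry); geometry is untouched.  Returns realized
    class counts.
    """
    registry = registry or load_registry()
    mix.validate(registry)
    classes = sorted(mix.weights)
    probs = np.array([mix.weights[c] for c in classes])
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(classes), size=len(system.molecules), p=probs)
    counts = {c: 0 for c in classes}
    for mol, k in zip(system.molecules, drawn):
        cls = classes[int(k)]
        counts[cls] += 1
        mol.crosslink_class = cls
        n_type, c_type = mix.terminal_types(cls)
        for site in mol.sites:
            new_type = registry[n_type if site.terminus == "N" else c_type]
            site.type_name = new_type.name
            site.valence = new_type.valence
            code = new_type.residues[0]
            for chain_id, resseq in site.residues:
                idx = mol.structure.residue_atoms(chain_id, resseq)
                mol.structure.resname[idx] = code
                mol.structure.hetero[idx] = True
    return counts


@dataclass
class RemovalReport:
    total_units: int
    removed_units: int
    remaining_units: int
    remaining_fraction: float
    removed: list[CrosslinkUnit] = field(default_factory=list)


def _mutate_to_lysine(structure: Structure, chain_id: str, resseq: int) -> Structure:
    """Replace one residue by lysine: backbone kept verbatim, side chain
    rebuilt at idealized geometry.  Residues lacking a complete backbone
    (synthetic site residues) are renamed with reactive atoms stripped."""
    idx = structure.residue_atoms(chain_id, resseq)
    if len(idx) == 0:
        raise KeyError(f"residue {chain_id}/{resseq} not found")
    names = set(structure.name[idx])
    lo, hi = idx[0], idx[-1]
    before = structure.select(np.arange(len(structure)) < lo)
    after = structure.select(np.arange(len(structure)) > hi)

    if {"N", "CA", "C"} <= names:
        keep = structure.select(np.isin(np.arange(len(structure)), idx)
                                & np.isin(structure.name, ["N", "CA", "C", "O"]))
        n_i = int(np.where(keep.name == "N")[0][0])
        ca_i = int(np.where(keep.name == "CA")[0][0])
        c_i = int(np.where(keep.name == "C")[0][0])
        sc_names, sc_coords, sc_elems = build_side_chain(
            "LYS", keep.coords[n_i], keep.coords[ca_i], keep.coords[c_i])
        m = len(sc_names)
        side = Structure(
            serial=np.arange(m, dtype=np.int64),
            name=np.array(sc_names, dtype="U4"),
            resname=np.full(m, "LYS", dtype="U4"),
            chain_id=np.full(m, chain_id, dtype="U2"),
            resseq=np.full(m, resseq, dtype=np.int64),
            element=np.array(sc_elems, dtype="U2"),
            coords=np.asarray(sc_coords),
            segid=np.full(m, keep.segid[0] if len(keep) else "", dtype="U4"),
            hetero=np.zeros(m, dtype=bool),
        )
        keep.resname[:] = "LYS"
        keep.hetero[:] = False
        mid = concat([keep, side])
    else:
        mid = structure.select(np.isin(np.arange(len(structure)), idx)
                               & (structure.name == "CA"))
        if len(mid) == 0:  # no CA either: keep first atom as placeholder
            mid = structure.select(np.arange(len(structure)) == lo)
        mid.resname[:] = "LYS"
        mid.hetero[:] = False
    out = concat([before, mid, after])
    out.serial = np.arange(1, len(out) + 1)
    return out


def remove_crosslinks(system, rate: float, seed: int,
                      mode: str = "exact") -> RemovalReport:
    """Randomly remove crosslink units, replacing members with lysine.

    ``rate`` is the fraction of crosslink units removed.  In ``"exact"``
    mode exactly ``round(rate·K)`` units (banker's rounding) are drawn
    without replacement; ``"bernoulli"`` removes each unit independently
    with probability ``rate``.  All member residues of a selected unit
    are removed together.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("removal rate must lie in [0, 1]")
    units = list(system.crosslink_units)
    K = len(units)
    rng = np.random.default_rng(seed)
    if K == 0:
        return RemovalReport(0, 0, 0, 1.0)
    if mode == "exact":
        n_remove = round(rate * K)
        chosen = sorted(rng.choice(K, size=n_remove, replace=False).tolist())
    elif mode == "bernoulli":
        chosen = [i for i in range(K) if rng.random() < rate]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    chosen_set = set(chosen)
    by_model = {m.model_id: m for m in system.molecules}
    for i in chosen:
        for model_id, chain_id, resseq in units[i].members:
            mol = by_model[model_id]
            mol.structure = _mutate_to_lysine(mol.structure, chain_id, resseq)
            # drop sites that referenced this residue; reindex the rest
            mol.sites = [s for s in mol.sites
                         if (chain_id, resseq) not in s.residues]
            _reindex_sites(mol)
    system.crosslink_units = [u for i, u in enumerate(units) if i not in chosen_set]
    removed = [units[i] for i in chosen]
    return RemovalReport(
        total_units=K,
        removed_units=len(chosen),
        remaining_units=K - len(chosen),
        remaining_fraction=(K - len(chosen)) / K,
        removed=removed,
    )


def _reindex_sites(mol) -> None:
    """Recompute site atom indices after a structure mutation."""
    registry = load_registry()
    for site in mol.sites:
        idx = []
        atoms_by_res = registry.get(site.type_name)
        for chain_id, resseq in site.residues:
            ridx = mol.structure.residue_atoms(chain_id, resseq)
            if atoms_by_res is not None:
                code = mol.structure.resname[ridx[0]] if len(ridx) else ""
                wanted = atoms_by_res.reactive_atoms.get(code)
            else:
                wanted = None
            for i in ridx:
                if wanted is None or mol.structure.name[i] in wanted:
                    idx.append(i)
        site.atom_indices = np.array(idx, dtype=int)


def detect_sites(structure: Structure,
                 registry: dict[str, CrosslinkType] | None = None) -> list[CrosslinkSite]:
    """Find crosslink-capable residues of a molecule by residue code.

    Every residue whose name appears in the registry becomes one site;
    reactive atom indices come from the registry's atom lists.  The
    terminus annotation is positional: residues below the median residue
    number of their chain are N-terminal sites, the rest C-terminal.
    """
    registry = registry or load_registry()
    code_to_type: dict[str, CrosslinkType] = {}
    for t in registry.values():
        for code in t.residues:
            code_to_type.setdefault(code, t)

    medians = {}
    for c in np.unique(structure.chain_id):
        medians[c] = float(np.median(structure.resseq[structure.chain_id == c]))

    sites = []
    for chain_id, resseq, resname, idx in structure.iter_residues():
        t = code_to_type.get(resname)
        if t is None:
            continue
        wanted = t.reactive_atoms.get(resname, [])
        atom_idx = np.array([i for i in idx if structure.name[i] in wanted], dtype=int)
        if len(atom_idx) == 0:
            continue
        terminus = "N" if resseq < medians[chain_id] else "C"
        sites.append(CrosslinkSite(
            type_name=t.name, valence=t.valence, terminus=terminus,
            residues=[(str(chain_id), int(resseq))], atom_indices=atom_idx,
        ))
    return sites


def derive_units(system, cutoff: float = 3.0) -> list[CrosslinkUnit]:
    """Realized crosslink units from geometric site-site links.

    A reactive side chain forms exactly one crosslink, so sites are
    matched greedily by increasing link distance, each site used at most
    once.  Mutually linked trivalent-site triangles become trivalent
    units (extracted first); every other link yields a divalent unit.
    Trivalent sites whose only partners are other already-used sites
    stay unlinked.  The result is stored on the system and returned.
    """
    mols = system.molecules
    edges = []  # (dist, i, si, j, sj)
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            for sa, sb, d in detect_links(mols[i], mols[j], cutoff):
                edges.append((d, i, mols[i].sites.index(sa), j, mols[j].sites.index(sb)))
    edges.sort(key=lambda e: (e[0], e[1:]))

    tri_adj: dict[tuple[int, int], set] = {}
    for _, i, si, j, sj in edges:
        sa, sb = mols[i].sites[si], mols[j].sites[sj]
        if sa.valence == "trivalent" and sb.valence == "trivalent":
            tri_adj.setdefault((i, si), set()).add((j, sj))
            tri_adj.setdefault((j, sj), set()).add((i, si))

    units: list[CrosslinkUnit] = []
    used: set[tuple[int, int]] = set()

    def member(node):
        i, k = node
        return (mols[i].model_id, *mols[i].sites[k].residues[0])

    # trivalent units: greedy triangle extraction in the tri-tri link graph
    for node in sorted(tri_adj):
        if node in used:
            continue
        neigh = sorted(tri_adj[node] - used)
        done = False
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                if neigh[b] in tri_adj.get(neigh[a], set()):
                    triple = [node, neigh[a], neigh[b]]
                    site0 = mols[node[0]].sites[node[1]]
                    units.append(CrosslinkUnit(
                        type_name=site0.type_name, valence="trivalent",
                        terminus=site0.terminus,
                        members=[member(n) for n in triple],
                    ))
                    used.update(triple)
                    done = True
                    break
            if done:
                break

    # divalent units: greedy matching by link distance
    for _, i, si, j, sj in edges:
        a, b = (i, si), (j, sj)
        if a in used or b in used:
            continue
        sa, sb = mols[i].sites[si], mols[j].sites[sj]
        if sa.valence == "trivalent" and sb.valence == "trivalent":
            continue  # incomplete trivalent pair stays unlinked
        units.append(CrosslinkUnit(
            type_name=sa.type_name if sa.valence == "divalent" else sb.type_name,
            valence="divalent", terminus=sa.terminus,
            members=[member(a), member(b)],
        ))
        used.update((a, b))
    system.crosslink_units = units
    return units


def detect_links(mol_a, mol_b, cutoff: float = 3.0):
    """All (site_a, site_b, min distance) pairs closer than ``cutoff`` Å.

    Distances are evaluated between designated reactive atoms only.
    Symmetric in its arguments.
    """
    out = []
    for sa in mol_a.sites:
        pa = sa.positions(mol_a.structure)
        if len(pa) == 0:
            continue
        for sb in mol_b.sites:
            pb = sb.positions(mol_b.structure)
            if len(pb) == 0:
                continue
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2).min()
            if d < cutoff:
                out.append((sa, sb, float(d)))
    return out
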