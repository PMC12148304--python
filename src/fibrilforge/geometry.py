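"""Small-molecule geometry utilities.

Covers the three geometric primitives the builder needs:

* ``place_atom`` — internal-coordinate (NeRF) placement of one atom from
  a bond length, bond angle and dihedral relative to three reference
  atoms; used for terminal cap construction.
* ``build_side_chain`` — idealized side-chain coordinates for a residue,
  obtained by rigidly superposing the ideal-geometry residue from the
  chemical component dictionary (bundled with biotite) onto the target
  backbone N/CA/C; backbone atoms are never moved.
* ``principal_axis`` — dominant direction of a point cloud (first
  principal component), used as the helix/fibril axis.
"""

from __future__ import annotations

import functools

import numpy as np

try:
    import biotite.structure.info as _struc_info
except Exception:  # pragma: no cover
    _struc_info = None

__all__ = ["place_atom", "kabsch", "build_side_chain", "principal_axis"]

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom d with |d−c| = bond, ∠(b,c,d) = angle (deg) and
    dihedral(a,b,c,d) = dihedral (deg)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(dih),
        np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ‖R·P + t − Q‖ (proper rotation)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


@functools.lru_cache(maxsize=64)
def ideal_residue(resname: str):
    """Ideal-geometry residue (heavy atoms) from the component dictionary."""
    if _struc_info is None:  # pragma: no cover
        raise RuntimeError("biotite is required for ideal residue geometry")
    res = _struc_info.residue(resname)
    if res is None:
        raise KeyError(f"residue {resname!r} not in component dictionary")
    return res[res.element != "H"]


def build_side_chain(
    resname: str,
    n_pos: np.ndarray,
    ca_pos: np.ndarray,
    c_pos: np.ndarray,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Idealized heavy side-chain atoms anchored to a fixed backbone.

    Returns (atom names, coordinates, elements) for every heavy atom of
    ``resname`` that is not a backbone atom, positioned by superposing
    the ideal residue's N/CA/C onto the given backbone coordinates.
    Glycine yields an empty result.
    """
    res = ideal_residue(resname)
    names = list(res.atom_name)
    try:
        src = np.stack([res.coord[names.index(a)] for a in ("N", "CA", "C")])
    except ValueError as e:
        raise KeyError(f"{resname}: ideal residue lacks backbone atoms") from e
    R, t = kabsch(src, np.stack([n_pos, ca_pos, c_pos]))
    side_mask = ~np.isin(res.atom_name, BACKBONE_ATOMS)
    side = res[side_mask]
    coords = side.coord @ R.T + t
    return list(side.atom_name), coords, [e.capitalize() for e in side.element]


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit first principal component of a point cloud (sign: +z-ish)."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    # orient toward positive z (or x) for determinism
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
    if axis @ ref < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)
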