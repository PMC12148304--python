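"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: Cartesian
translations come from gemmi's cell orthogonalization, clash scans are
plain O(n²) loops, and 1-D clustering is an exact dynamic program.
"""

from __future__ import annotations

import math

import gemmi
import numpy as np


def triclinic_volume(a, b, c, alpha, beta, gamma) -> float:
    """Closed-form triclinic cell volume."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    return a * b * c * math.sqrt(
        1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)


def brute_force_copies(coords: np.ndarray, cell, d_c: float,
                       index_range: int = 3) -> list[tuple[int, int, int]]:
    """All lattice translations in [-r, r]³ whose copy has any atom within
    d_c of the original; translations via gemmi orthogonalization."""
    g = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    out = []
    r = index_range
    for nx in range(-r, r + 1):
        for ny in range(-r, r + 1):
            for nz in range(-r, r + 1):
                if (nx, ny, nz) == (0, 0, 0):
                    out.append((0, 0, 0))
                    continue
                pos = g.orthogonalize(gemmi.Fractional(nx, ny, nz))
                t = np.array([pos.x, pos.y, pos.z])
                shifted = coords + t
                d2 = ((shifted[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
                if np.sqrt(d2.min()) <= d_c:
                    out.append((nx, ny, nz))
    return sorted(out)


def count_clash_pairs(copies, overlap_fraction: float = 0.6) -> int:
    """O(n²) count of violating atom pairs between different copies."""
    n_bad = 0
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            ca, ra = copies[i].coords, copies[i].vdw_radii
            cb, rb = copies[j].coords, copies[j].vdw_radii
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            thr = overlap_fraction * (ra[:, None] + rb[None, :])
            n_bad += int((d < thr).sum())
    return n_bad


def exact_kmeans_1d(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Globally optimal 1-D k-means by dynamic programming.

    Returns (cluster centers sorted ascending, total within-cluster SSE).
    Clusters of an optimal 1-D k-means are contiguous in sorted order,
    so an O(k·n²) DP over split points is exact.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i, j):  # cost of cluster x[i:j]
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = cost[kk - 1, i] + sse(i, j)
                if c < cost[kk, j]:
                    cost[kk, j] = c
                    back[kk, j] = i
    # recover centers
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = back[kk, j]
        bounds.append(j)
    bounds = bounds[::-1]
    centers = np.array([x[bounds[i]:bounds[i + 1]].mean() for i in range(k)])
    return centers, float(cost[k, n])


def random_valid_cell(rng: np.random.Generator):
    """Random triclinic cell with moderate angles (always non-degenerate)."""
    from fibrilforge.crystal import UnitCell

    while True:
        a, b, c = rng.uniform(5.0, 40.0, size=3)
        al, be, ga = rng.uniform(70.0, 110.0, size=3)
        ca_, cb_, cg_ = (math.cos(math.radians(v)) for v in (al, be, ga))
        if 1 - ca_**2 - cb_**2 - cg_**2 + 2 * ca_ * cb_ * cg_ > 1e-3:
            return UnitCell(a, b, c, al, be, ga, "P 1")
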