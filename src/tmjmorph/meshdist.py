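"""Exact point-to-triangle-mesh distances.

``closest_on_mesh`` prunes candidate triangles with a centroid KD-tree but
returns exactly the brute-force nearest point: a candidate set is accepted
only once the best exact distance found is provably no worse than the
distance to any unexamined triangle (k-th centroid distance minus the
largest triangle circumradius-like bound).  ``closest_on_mesh_brute`` is the
straight all-pairs computation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh


def point_triangle_closest(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each paired query point.

    ``points`` (N, 3) and ``triangles`` (N, 3, 3) are matched elementwise;
    returns (N, 3) closest points.  Region-based algorithm on barycentric
    coordinates (Eberly), fully vectorized.
    """
    p = np.asarray(points, dtype=np.float64)
    tri = np.asarray(triangles, dtype=np.float64)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        fresh = mask & ~done
        result[fresh] = value[fresh]
        done[fresh] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    settle((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)

    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b + np.nan_to_num(w_bc)[:, None] * (c - b),
    )

    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.nan_to_num(vb / denom)
        w = np.nan_to_num(vc / denom)
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return result


def closest_on_mesh_brute(
    points: np.ndarray, mesh: SurfaceMesh, chunk: int = 2_000_000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs nearest point on the mesh surface for each query point.

    Returns (distances, closest_points, triangle_indices).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tri = mesh.triangles()
    if len(tri) == 0:
        raise ValueError("mesh has no faces")
    n, m = len(points), len(tri)
    best_d2 = np.full(n, np.inf)
    best_pt = np.zeros((n, 3))
    best_tri = np.zeros(n, dtype=np.int64)
    rows_per = max(1, chunk // m)
    for start in range(0, n, rows_per):
        sl = slice(start, min(start + rows_per, n))
        p_block = points[sl]
        k = len(p_block)
        pp = np.repeat(p_block, m, axis=0)
        tt = np.tile(tri, (k, 1, 1))
        cp = point_triangle_closest(pp, tt).reshape(k, m, 3)
        d2 = np.sum((p_block[:, None, :] - cp) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)
        best_d2[sl] = d2[np.arange(k), idx]
        best_pt[sl] = cp[np.arange(k), idx]
        best_tri[sl] = idx
    return np.sqrt(best_d2), best_pt, best_tri


def closest_on_mesh(
    points: np.ndarray, mesh: SurfaceMesh, k0: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KD-pruned exact nearest point on the mesh surface.

    Equivalent to :func:`closest_on_mesh_brute` (same minima) but examines
    only triangles that can possibly host the nearest point.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tri = mesh.triangles()
    if len(tri) == 0:
        raise ValueError("mesh has no faces")
    centroids = tri.mean(axis=1)
    radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    max_radius = float(radius.max())
    tree = cKDTree(centroids)

    n = len(points)
    dist = np.empty(n)
    closest = np.empty((n, 3))
    tri_idx = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    k = min(k0, len(tri))
    while len(pending):
        p = points[pending]
        d_cent, cand = tree.query(p, k=k)
        d_cent = np.atleast_2d(d_cent.reshape(len(p), -1))
        cand = np.atleast_2d(cand.reshape(len(p), -1))
        kk = cand.shape[1]
        pp = np.repeat(p, kk, axis=0)
        tt = tri[cand.ravel()]
        cp = point_triangle_closest(pp, tt).reshape(len(p), kk, 3)
        d2 = np.sum((p[:, None, :] - cp) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        best = np.sqrt(d2[rows, j])
        # verified if no unexamined triangle can beat the best found
        verified = (best <= d_cent[:, -1] - max_radius) | (k >= len(tri))
        sel = pending[verified]
        dist[sel] = best[verified]
        closest[sel] = cp[rows[verified], j[verified]]
        tri_idx[sel] = cand[rows[verified], j[verified]]
        pending = pending[~verified]
        k = min(len(tri), k * 4)
    return dist, closest, tri_idx
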