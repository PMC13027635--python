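"""Exact point-to-mesh closest-point queries with a KD-tree candidate filter.

Candidate faces come from a KD-tree over face centroids. A face can only
beat the current best distance ``d`` if its centroid lies within
``d + r_max`` of the query point (``r_max`` = largest centroid-to-vertex
face radius), so k is grown until the k-th centroid distance passes that
bound; the result then equals the brute-force answer.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


def _exact_best(tris: np.ndarray, points: np.ndarray, cand: np.ndarray):
    """Best (distance, face, closest point) per row over candidate faces."""
    n, k = cand.shape
    flat_pts = np.repeat(points, k, axis=0)
    cp = trimesh.triangles.closest_point(tris[cand.ravel()], flat_pts)
    d = np.linalg.norm(flat_pts - cp, axis=1).reshape(n, k)
    best = d.argmin(axis=1)
    rows = np.arange(n)
    return d[rows, best], cand[rows, best], cp.reshape(n, k, 3)[rows, best]


def closest_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray, with_normals: bool = False):
    """Closest surface point, distance (and face normal) for each query point."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tris = np.asarray(mesh.triangles, dtype=float)
    if len(tris) == 0:
        raise ValueError("mesh has no faces")
    centroids = tris.mean(axis=1)
    r_max = float(np.linalg.norm(tris - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)

    n = len(points)
    best_d = np.full(n, np.inf)
    best_face = np.zeros(n, dtype=int)
    best_cp = np.zeros((n, 3))
    unresolved = np.arange(n)
    k = min(16, len(tris))
    while len(unresolved):
        pts = points[unresolved]
        cd, cand = tree.query(pts, k=k)
        cd = np.atleast_2d(cd)
        cand = np.atleast_2d(cand)
        d, f, cp = _exact_best(tris, pts, cand)
        better = d < best_d[unresolved]
        idx = unresolved[better]
        best_d[idx] = d[better]
        best_face[idx] = f[better]
        best_cp[idx] = cp[better]
        if k >= len(tris):
            break
        # resolved once no face outside the k candidates can possibly be closer
        done = cd[:, -1] > best_d[unresolved] + r_max
        unresolved = unresolved[~done]
        k = min(k * 4, len(tris))
    if with_normals:
        return best_cp, best_d, mesh.face_normals[best_face]
    return best_cp, best_d
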