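"""Isosurface extraction, tolerance-driven decimation, repair, STL I/O.

The segmented volume becomes a triangle mesh via marching cubes at the
estimated iso-value, with vertices placed on cube edges by linear
interpolation of intensities and scaled by the voxel spacing so coordinates
are physical millimetres. Marching-cubes output routinely carries
structural defects — inverted normals, duplicated vertices and faces,
degenerate triangles — so a best-effort repair pass with a defect report
precedes any downstream use.

Decimation is an iterative edge collapse that accepts a collapse only while
two export tolerances hold: the chordal deviation (every original vertex
stays within ``chordal_dev_mm`` of the simplified surface, default
0.005 mm) and the angular deviation (no face normal rotates more than
``angular_dev_deg``, default 5 degrees). Flat regions therefore collapse
aggressively while curvature is preserved.

STL is read and written directly in both ASCII and binary (little-endian,
80-byte header, uint32 facet count, 50-byte facets) so that malformed files
fail loudly with byte offsets.
"""

from __future__ import annotations

import dataclasses
import heapq
import struct
import warnings
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .volume import VoxelVolume

__all__ = [
    "DecimationSpec",
    "RepairReport",
    "marching_cubes",
    "decimate_to_tolerance",
    "repair_mesh",
    "read_stl",
    "write_stl",
]

WELD_TOL_MM = 1e-6


@dataclasses.dataclass
class DecimationSpec:
    chordal_dev_mm: float = 0.005
    angular_dev_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.chordal_dev_mm <= 0 or self.angular_dev_deg <= 0:
            raise ValueError("decimation tolerances must be positive")


@dataclasses.dataclass
class RepairReport:
    flipped_faces: int = 0
    welded_vertices: int = 0
    removed_duplicate_faces: int = 0
    removed_degenerate_faces: int = 0

    @property
    def clean(self) -> bool:
        return (
            self.flipped_faces
            == self.welded_vertices
            == self.removed_duplicate_faces
            == self.removed_degenerate_faces
            == 0
        )


def marching_cubes(vol: VoxelVolume, iso_value: float) -> trimesh.Trimesh:
    """Extract the iso-value surface as a mesh in physical mm coordinates."""
    data = np.asarray(vol.data, dtype=float)
    if not (data.min() < iso_value < data.max()):
        warnings.warn(
            f"iso-value {iso_value} outside intensity range "
            f"[{data.min()}, {data.max()}]: returning empty mesh",
            stacklevel=2,
        )
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    verts, faces, _, _ = measure.marching_cubes(data, level=iso_value, spacing=vol.spacing_mm)
    verts = verts + np.asarray(vol.origin_mm)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


# ---------------------------------------------------------------------------
# decimation


def _point_tri_dist(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Min distance of each point to a set of triangles (brute force)."""
    if len(tris) == 0:
        return np.full(len(points), np.inf)
    n, m = len(points), len(tris)
    p = np.repeat(points, m, axis=0)
    t = np.tile(tris, (n, 1, 1))
    closest = trimesh.triangles.closest_point(t, p)
    d = np.linalg.norm(p - closest, axis=1).reshape(n, m)
    return d.min(axis=1)


def _face_normal(vs: np.ndarray, f) -> np.ndarray:
    n = np.cross(vs[f[1]] - vs[f[0]], vs[f[2]] - vs[f[0]])
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else n


def decimate_to_tolerance(mesh: trimesh.Trimesh, spec: DecimationSpec | None = None) -> trimesh.Trimesh:
    """Collapse edges while chordal and angular tolerances both hold.

    Edges are visited shortest-first; a collapse moves both endpoints to the
    edge midpoint and is accepted only if (a) every original vertex tracked
    in the affected region stays within ``chordal_dev_mm`` of the new local
    surface, and (b) no affected face normal rotates by more than
    ``angular_dev_deg``. Requires a repaired mesh.
    """
    spec = spec or DecimationSpec()
    _, report = repair_mesh(mesh)
    if not report.clean:
        raise ValueError(f"decimation requires a repaired mesh; defects found: {report}")
    if len(mesh.faces) == 0:
        return mesh.copy()

    vs = np.array(mesh.vertices, dtype=float)
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set[int]] = {i: set() for i in range(len(vs))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)
    carried: dict[int, list[np.ndarray]] = {i: [vs[i].copy()] for i in range(len(vs))}
    alive = np.ones(len(vs), dtype=bool)
    cos_tol = np.cos(np.radians(spec.angular_dev_deg))

    def neighbors(v: int) -> set[int]:
        out = set()
        for fi in vert_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def fresh_heap() -> list[tuple[float, int, int]]:
        h: list[tuple[float, int, int]] = []
        for f in faces.values():
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                if a < b:
                    h.append((float(np.linalg.norm(vs[a] - vs[b])), a, b))
        heapq.heapify(h)
        return h

    # greedy shortest-edge passes until a fixpoint: committed collapses can
    # unlock neighbours that previously failed the link condition. Carried
    # original vertices persist across passes, so the chordal bound is
    # always measured against the true input vertices.
    heap = fresh_heap()
    collapsed_this_pass = 0
    while True:
        if not heap:
            if collapsed_this_pass == 0:
                break
            heap = fresh_heap()
            collapsed_this_pass = 0
            continue
        d, u, v = heapq.heappop(heap)
        if not (alive[u] and alive[v]):
            continue
        shared = vert_faces[u] & vert_faces[v]
        if not shared:
            continue
        if abs(np.linalg.norm(vs[u] - vs[v]) - d) > 1e-12:
            continue  # stale entry
        # link condition: vertices shared between the two one-rings must be
        # exactly the faces' opposite vertices, else the collapse pinches
        shared_nbrs = neighbors(u) & neighbors(v)
        opposite = {w for fi in shared for w in faces[fi] if w not in (u, v)}
        if shared_nbrs != opposite:
            continue

        region_faces = vert_faces[u] | vert_faces[v]
        new_faces = {}
        degenerate = False
        for fi in region_faces - shared:
            f = tuple(u if w == v else w for w in faces[fi])
            if len(set(f)) < 3:
                degenerate = True
                break
            new_faces[fi] = f
        if degenerate:
            continue

        # candidate placements: midpoint first, then either endpoint.
        # The chordal bound re-verifies every carried original vertex whose
        # neighbourhood changes, against the 2-ring face set (changed faces
        # plus the untouched faces around the affected neighbours).
        old_u = vs[u].copy()
        nbrs_all = neighbors(u) | neighbors(v)
        pts = carried[u] + carried[v]
        check_fids: set[int] = set(new_faces)
        for w in nbrs_all:
            pts = pts + carried[w]
            check_fids |= vert_faces[w]
        check_fids -= shared
        face_idx = np.array(
            [new_faces.get(fi, faces[fi]) for fi in check_fids], dtype=int
        )
        pts = np.asarray(pts)
        ok = False
        for placement in ((vs[u] + vs[v]) / 2.0, vs[u].copy(), vs[v].copy()):
            vs[u] = placement
            ok = True
            for fi, f in new_faces.items():
                n_new = _face_normal(vs, f)
                vs[u] = old_u  # old normal uses pre-collapse positions
                n_old = _face_normal(vs, faces[fi])
                vs[u] = placement
                if np.linalg.norm(n_new) == 0 or float(n_new @ n_old) < cos_tol:
                    ok = False
                    break
            if ok:
                dmin = _point_tri_dist(pts, vs[face_idx])
                ok = bool(np.all(dmin <= spec.chordal_dev_mm + 1e-12))
            if ok:
                break
            vs[u] = old_u
        if not ok:
            continue

        # commit: v merges into u at the accepted placement
        alive[v] = False
        carried[u] = carried[u] + carried[v]
        carried[v] = []
        for fi in shared:
            for w in faces[fi]:
                vert_faces[w].discard(fi)
            del faces[fi]
        for fi, f in new_faces.items():
            faces[fi] = f
            for w in f:
                vert_faces[w].add(fi)
        vert_faces[v] = set()
        collapsed_this_pass += 1
        for w in neighbors(u):
            heapq.heappush(heap, (float(np.linalg.norm(vs[u] - vs[w])), *sorted((u, w))))

    keep = np.nonzero(alive)[0]
    remap = {int(old): i for i, old in enumerate(keep)}
    out_faces = np.array([[remap[w] for w in f] for f in faces.values()], dtype=int)
    return trimesh.Trimesh(vertices=vs[keep], faces=out_faces, process=False)


# ---------------------------------------------------------------------------
# repair


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def repair_mesh(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, RepairReport]:
    """Weld near-duplicate vertices, drop duplicate/degenerate faces, fix winding.

    Always best-effort: returns the repaired mesh plus a report of what was
    changed. Vertex positions are unchanged except for welds (tolerance
    1e-6 mm, welded to the first occurrence).
    """
    from scipy.spatial import cKDTree

    report = RepairReport()
    verts = np.array(mesh.vertices, dtype=float)
    faces = np.array(mesh.faces, dtype=int)
    if len(verts) == 0:
        return mesh.copy(), report

    # weld vertices within tolerance (union-find over close pairs)
    tree = cKDTree(verts)
    pairs = tree.query_pairs(WELD_TOL_MM, output_type="ndarray")
    uf = _UnionFind(len(verts))
    for a, b in pairs:
        uf.union(int(a), int(b))
    root = np.array([uf.find(i) for i in range(len(verts))])
    report.welded_vertices = int(len(verts) - len(np.unique(root)))
    faces = root[faces]

    # degenerate faces: repeated indices or (numerically) zero area
    repeated = (
        (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
    )
    areas = 0.5 * np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]),
        axis=1,
    )
    degenerate = repeated | (areas < 1e-14)
    report.removed_degenerate_faces = int(degenerate.sum())
    faces = faces[~degenerate]

    # duplicate faces: same vertex set regardless of winding, keep first
    key = np.sort(faces, axis=1)
    _, first_idx = np.unique(key, axis=0, return_index=True)
    report.removed_duplicate_faces = int(len(faces) - len(first_idx))
    faces = faces[np.sort(first_idx)]

    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    out = trimesh.Trimesh(vertices=verts[used], faces=remap[faces], process=False)

    before = np.array(out.faces)
    trimesh.repair.fix_normals(out)
    after = np.array(out.faces)
    report.flipped_faces = int(np.sum(np.any(before != after, axis=1)))
    return out, report


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: trimesh.Trimesh, path: str | Path, mode: str = "binary") -> None:
    """Write STL: 'binary' (80-byte header, uint32 count, 50-byte facets) or 'ascii'."""
    path = Path(path)
    tris = np.asarray(mesh.triangles, dtype=np.float64)
    normals = np.asarray(mesh.face_normals, dtype=np.float64) if len(tris) else np.zeros((0, 3))
    if mode == "binary":
        with open(path, "wb") as fh:
            fh.write(b"orbifab binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", len(tris)))
            facet = np.zeros(len(tris), dtype=_BIN_FACET_DTYPE)
            facet["normal"] = normals.astype(np.float32)
            facet["verts"] = tris.astype(np.float32)
            fh.write(facet.tobytes())
    elif mode == "ascii":
        lines = ["solid orbifab"]
        for n, t in zip(normals, tris):
            lines.append(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid orbifab")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")


_BIN_FACET_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
)


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Read an ASCII or binary STL file, welding shared facet vertices."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) >= 5 and raw[:5] == b"solid" and b"facet" in raw[:500]:
        tris = _parse_ascii_stl(raw.decode("utf-8", errors="replace"), path)
    else:
        if len(raw) < 84:
            raise ValueError(
                f"{path}: truncated binary STL, {len(raw)} bytes < 84-byte minimum"
            )
        (count,) = struct.unpack_from("<I", raw, 80)
        expected = 84 + 50 * count
        if len(raw) < expected:
            raise ValueError(
                f"{path}: truncated binary STL at byte {len(raw)}, "
                f"header declares {count} facets ({expected} bytes)"
            )
        if len(raw) > expected:
            raise ValueError(
                f"{path}: facet-count mismatch: header declares {count} facets "
                f"({expected} bytes) but file has {len(raw)} bytes"
            )
        facet = np.frombuffer(raw, dtype=_BIN_FACET_DTYPE, count=count, offset=84)
        tris = facet["verts"].astype(np.float64)
    if len(tris) == 0:
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    verts = tris.reshape(-1, 3)
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return trimesh.Trimesh(vertices=uniq, faces=faces, process=False)


def _parse_ascii_stl(text: str, path: Path) -> np.ndarray:
    verts: list[list[float]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if tokens[:1] == ["vertex"]:
            if len(tokens) != 4:
                raise ValueError(f"{path}:{ln}: malformed vertex line")
            verts.append([float(v) for v in tokens[1:]])
    if len(verts) % 3 != 0:
        raise ValueError(
            f"{path}: ASCII STL vertex count {len(verts)} is not a multiple of 3 (truncated?)"
        )
    return np.asarray(verts, dtype=np.float64).reshape(-1, 3, 3)
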