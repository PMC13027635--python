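"""Layer planning for extrusion printing: constant and variable layer height.

Layer height is the central fidelity/throughput compromise of material
extrusion: the stair-step cusp on an inclined surface is ``h * cos(theta)``
(theta = angle between the local surface normal and the build axis), so
thinner layers smooth curved anatomy but multiply print time. Variable
layer height (VLH) keeps a fine height (default 0.07 mm) inside explicit
z-zones covering the critical geometry and a coarse height (default
0.3 mm) elsewhere, with a geometric ramp smoothing each transition.

Admissible heights are tied to the nozzle: h in [0.175 d, 0.75 d], the
working range of common 0.4 mm-nozzle extrusion profiles (0.07-0.3 mm).
Plans are contiguous; zone starts land exactly on a layer boundary and the
plan tops out exactly at the mesh extent, absorbing the residual into the
trailing layers at no more than 25% of each layer's nominal height.

Time/material estimates model perimeters (2 contours) and grid infill
(80%) at the stated speeds only — no travel, heating or acceleration — so
they are comparative, not absolute.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

__all__ = [
    "LayerPlan",
    "SliceStack",
    "PrintParams",
    "PrintEstimate",
    "make_layer_plan",
    "slice_mesh",
    "stair_step_error",
    "estimate_print",
    "adaptive_fine_zones",
]

NOZZLE_H_MIN_FRAC = 0.175
NOZZLE_H_MAX_FRAC = 0.75


@dataclasses.dataclass
class LayerPlan:
    """Ordered contiguous layers as (z_bottom_mm, height_mm) pairs."""

    layers: list[tuple[float, float]]
    nozzle_diameter_mm: float = 0.4

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("layer plan is empty")
        for (z0, h0), (z1, _) in zip(self.layers, self.layers[1:]):
            if abs(z0 + h0 - z1) > 1e-9:
                raise ValueError(f"plan not contiguous at z={z0 + h0:.4f} vs {z1:.4f}")
        if any(h <= 0 for _, h in self.layers):
            raise ValueError("layer heights must be positive")

    @property
    def z_bottom(self) -> float:
        return self.layers[0][0]

    @property
    def z_top(self) -> float:
        z, h = self.layers[-1]
        return z + h

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, h in self.layers])

    def mid_heights(self) -> np.ndarray:
        return np.array([z + h / 2 for z, h in self.layers])

    def to_csv(self, path: str | Path) -> None:
        lines = ["z_bottom_mm,height_mm"] + [f"{z:.6f},{h:.6f}" for z, h in self.layers]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, nozzle_diameter_mm: float = 0.4) -> "LayerPlan":
        rows = [
            tuple(float(t) for t in line.split(","))
            for line in Path(path).read_text().splitlines()
            if line and not line[0].isalpha()
        ]
        return cls([(z, h) for z, h in rows], nozzle_diameter_mm)


@dataclasses.dataclass
class SliceStack:
    """Per-layer closed cross-section polygons (shapely, holes included)."""

    polygons: list[list]  # one list of shapely Polygons per layer
    plan: LayerPlan

    def layer_area(self, i: int) -> float:
        return float(sum(p.area for p in self.polygons[i]))

    def layer_perimeter(self, i: int) -> float:
        total = 0.0
        for p in self.polygons[i]:
            total += p.exterior.length + sum(r.length for r in p.interiors)
        return float(total)


@dataclasses.dataclass
class PrintParams:
    """Extrusion parameters; defaults follow a 0.4 mm-nozzle PLA profile."""

    contour_speed_mm_s: float = 70.0
    infill_speed_mm_s: float = 200.0
    infill_density: float = 0.8
    n_contours: int = 2
    extrusion_width_mm: float = 0.4
    filament_price_per_cm3: float = 0.05

    def __post_init__(self) -> None:
        if self.contour_speed_mm_s <= 0 or self.infill_speed_mm_s <= 0:
            raise ValueError("speeds must be positive")


@dataclasses.dataclass
class PrintEstimate:
    time_s: float
    filament_volume_mm3: float
    cost_currency: float


def _nozzle_limits(nozzle: float) -> tuple[float, float]:
    return NOZZLE_H_MIN_FRAC * nozzle, NOZZLE_H_MAX_FRAC * nozzle


def _land_exactly(heights: list[float], target: float, max_frac: float = 0.25) -> list[float]:
    """Adjust trailing layers (each <= max_frac of nominal) so sums match target."""
    residual = target - sum(heights)
    out = list(heights)
    for i in range(len(out) - 1, -1, -1):
        if abs(residual) < 1e-12:
            break
        cap = max_frac * out[i]
        step = float(np.clip(residual, -cap, cap))
        out[i] += step
        residual -= step
    if abs(residual) > 1e-9:
        raise ValueError(
            f"cannot land plan on target within 25% trailing-layer adjustments "
            f"(residual {residual:.4f} mm)"
        )
    return out


def _geometric_ramp(h_from: float, h_to: float, n: int) -> list[float]:
    """n intermediate heights stepping geometrically from h_from toward h_to."""
    if n <= 0:
        return []
    r = (h_to / h_from) ** (1.0 / (n + 1))
    return [h_from * r ** (k + 1) for k in range(n)]


def make_layer_plan(
    z_range: tuple[float, float],
    base_h: float = 0.3,
    fine_h: float = 0.07,
    fine_zones: Sequence[tuple[float, float]] = (),
    ramp_layers: int = 3,
    nozzle: float = 0.4,
) -> LayerPlan:
    """Build a contiguous layer plan with fine z-zones and ramped transitions.

    Fine zones use ``fine_h`` exactly; base regions use ``base_h`` with a
    geometric ramp of ``ramp_layers`` layers on the coarse side of every
    transition. Base regions before a zone land exactly on the zone start;
    the plan as a whole lands exactly on ``z_range[1]``.
    """
    z0, z1 = float(z_range[0]), float(z_range[1])
    if z1 <= z0:
        raise ValueError("z_range must be increasing")
    h_lo, h_hi = _nozzle_limits(nozzle)
    for name, h in (("base_h", base_h), ("fine_h", fine_h)):
        if not (h_lo - 1e-12 <= h <= h_hi + 1e-12):
            raise ValueError(
                f"{name}={h} outside nozzle limits [{h_lo:.3f}, {h_hi:.3f}] mm "
                f"({NOZZLE_H_MIN_FRAC}d to {NOZZLE_H_MAX_FRAC}d for d={nozzle} mm)"
            )
    if fine_h > base_h:
        raise ValueError("fine_h must not exceed base_h")
    zones = sorted((max(a, z0), min(b, z1)) for a, b in fine_zones)
    for a, b in zones:
        if not (z0 <= a < b <= z1):
            raise ValueError(f"fine zone ({a}, {b}) outside z_range")
    for (_, b0), (a1, _) in zip(zones, zones[1:]):
        if a1 < b0:
            raise ValueError("fine zones overlap")

    heights: list[float] = []
    z = z0
    eps = 1e-9

    def fill_base(span: float, ramp_in: bool, ramp_out: bool, exact: bool) -> list[float]:
        # entry ramp ascends from fine toward base; exit ramp descends back
        entry = _geometric_ramp(fine_h, base_h, ramp_layers) if ramp_in else []
        exit_ = _geometric_ramp(base_h, fine_h, ramp_layers) if ramp_out else []
        fixed = sum(entry) + sum(exit_)
        m = max(int(round((span - fixed) / base_h)), 0)
        hs = entry + [base_h] * m + exit_
        if not hs:
            hs = [min(max(span, h_lo), h_hi)]
        if exact:
            hs = _land_exactly(hs, span)
        return hs

    prev_fine = False
    for i, (a, b) in enumerate(zones + [(z1, z1)]):
        is_last = i == len(zones)
        if a - z > eps:  # base region from z to a
            heights += fill_base(a - z, ramp_in=prev_fine, ramp_out=not is_last, exact=True)
            z = z0 + sum(heights)
        if is_last:
            break
        while z < b - eps:  # fine zone: exact fine_h, may overshoot the zone end
            heights.append(fine_h)
            z += fine_h
        prev_fine = True

    if abs((z0 + sum(heights)) - z1) > 1e-9:
        heights = _land_exactly(heights, z1 - z0)

    layers = []
    z = z0
    for h in heights:
        layers.append((z, h))
        z += h
    return LayerPlan(layers, nozzle_diameter_mm=nozzle)


def slice_mesh(mesh: trimesh.Trimesh, plan: LayerPlan) -> SliceStack:
    """Intersect the mesh with the mid-height plane of every layer.

    Cross sections are chained into closed polygons (with holes); empty
    layers are allowed. Requires a watertight mesh and a plan covering the
    mesh's z-extent.
    """
    if not mesh.is_watertight:
        counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)[1]
        n_open = int((counts == 1).sum())
        raise ValueError(f"mesh is not watertight: {n_open} open edges")
    zmin, zmax = mesh.bounds[:, 2]
    slack = 0.25 * float(plan.heights.min())
    if plan.z_bottom > zmin + slack or plan.z_top < zmax - slack:
        raise ValueError(
            f"plan [{plan.z_bottom:.3f}, {plan.z_top:.3f}] does not cover the mesh "
            f"z-extent [{zmin:.3f}, {zmax:.3f}]"
        )
    mids = plan.mid_heights()
    lines, _, _ = trimesh.intersections.mesh_multiplane(
        mesh, plane_origin=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0]), heights=mids
    )
    polys = [_close_section(seg) for seg in lines]
    return SliceStack(polygons=polys, plan=plan)


def _close_section(segments: np.ndarray) -> list:
    """Chain unordered 2D section segments into nested closed polygons.

    Polygonizes the noded segment arrangement, then applies even-odd
    nesting: even-depth faces are solids, their immediate children holes.
    """
    import shapely
    from shapely.geometry import MultiLineString, Polygon
    from shapely.ops import polygonize, unary_union

    if segments is None or len(segments) == 0:
        return []
    ml = shapely.set_precision(MultiLineString([s.tolist() for s in segments]), 1e-9)
    faces = [p for p in polygonize(unary_union(ml)) if p.area > 0]
    if not faces:
        return []
    # work on the exterior shells: every boundary ring of the arrangement is
    # exactly one face's exterior, so even-odd depth over shells nests holes
    shells = [Polygon(p.exterior.coords) for p in faces]
    reps = [p.representative_point() for p in shells]
    depth = [
        sum(1 for j, q in enumerate(shells) if j != i and q.contains(reps[i]))
        for i in range(len(shells))
    ]
    out = []
    for i, p in enumerate(shells):
        if depth[i] % 2 == 0:
            holes = [
                q.exterior.coords
                for j, q in enumerate(shells)
                if depth[j] == depth[i] + 1 and p.contains(reps[j])
            ]
            out.append(Polygon(p.exterior.coords, holes))
    return out


def stair_step_error(mesh: trimesh.Trimesh, plan: LayerPlan) -> np.ndarray:
    """Per-layer maximum cusp height h * |cos(theta)|.

    theta is the angle between the local face normal and the build (z)
    axis; vertical walls contribute zero, horizontal facets the full layer
    height. Each layer takes the maximum over faces crossing its z-band.
    """
    tri_z = mesh.triangles[:, :, 2]
    fmin, fmax = tri_z.min(axis=1), tri_z.max(axis=1)
    nz = np.abs(mesh.face_normals[:, 2])
    out = np.zeros(len(plan.layers))
    for i, (zb, h) in enumerate(plan.layers):
        in_band = (fmax >= zb) & (fmin <= zb + h)
        out[i] = h * float(nz[in_band].max()) if in_band.any() else 0.0
    return out


def estimate_print(stack: SliceStack, params: PrintParams | None = None) -> PrintEstimate:
    """Time/material estimate from perimeters and grid infill.

    Per layer: ``n_contours`` perimeter passes at the contour speed plus an
    infill path of length ``area * density / extrusion_width`` at the infill
    speed. Deposited volume counts contour beads plus infill at the stated
    density. Travel/heating/acceleration are ignored.
    """
    params = params or PrintParams()
    time_s = 0.0
    volume = 0.0
    for i, (_, h) in enumerate(stack.plan.layers):
        area = stack.layer_area(i)
        perim = stack.layer_perimeter(i)
        if area == 0 and perim == 0:
            continue
        contour_len = perim * params.n_contours
        infill_len = area * params.infill_density / params.extrusion_width_mm
        time_s += contour_len / params.contour_speed_mm_s + infill_len / params.infill_speed_mm_s
        volume += (
            contour_len * params.extrusion_width_mm * h
            + area * params.infill_density * h
        )
    cost = volume / 1000.0 * params.filament_price_per_cm3
    return PrintEstimate(time_s=float(time_s), filament_volume_mm3=float(volume), cost_currency=float(cost))


def adaptive_fine_zones(
    mesh: trimesh.Trimesh,
    base_h: float = 0.3,
    cusp_threshold_mm: float = 0.1,
) -> list[tuple[float, float]]:
    """z-intervals where the base-height cusp would exceed the threshold.

    Optional curvature-adaptive alternative to hand-picked fine zones:
    bands whose maximum stair-step cusp at ``base_h`` exceeds the threshold
    are merged into zones.
    """
    zmin, zmax = mesh.bounds[:, 2]
    n = max(int(np.ceil((zmax - zmin) / base_h)), 1)
    plan = LayerPlan([(zmin + i * base_h, base_h) for i in range(n)])
    cusp = stair_step_error(mesh, plan)
    zones: list[tuple[float, float]] = []
    for i, c in enumerate(cusp):
        if c > cusp_threshold_mm:
            zb, h = plan.layers[i]
            if zones and abs(zones[-1][1] - zb) < 1e-9:
                zones[-1] = (zones[-1][0], zb + h)
            else:
                zones.append((zb, zb + h))
    return zones
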