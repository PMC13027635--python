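"""Synthetic phantoms: CT-like shell volumes, stair-step surfaces, test meshes.

The orbital floor is a thin curved bony shell (0.74-1.5 mm) embedded in soft
tissue; on CT it suffers partial-volume blending because the slice spacing
(0.7 mm) is comparable to the bone thickness. The volume phantom emulates
exactly that situation with a spherical-cap shell whose geometry is known in
closed form: membership is evaluated on a supersampled grid and averaged
down, so edge voxels carry fractional bone occupancy, then Gaussian noise is
added. The exact voxel-centre mask at grid resolution is returned alongside
as ground truth.

The stair surface phantom emulates the layered texture of extrusion-printed
parts: parallel circular-arc bead ridges whose along-surface period is
``layer_height / sin(slope)`` and whose peak-to-valley height scales with
the layer height, plus measurement noise. It stands in for focus-variation
measurements of printed-template surface replicas.

All randomness flows through one named generator per operation, seeded from
the spec; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import trimesh

from .metrology import HeightMap
from .volume import LabelVolume, VoxelVolume

__all__ = [
    "PhantomSpec",
    "StairSurfaceSpec",
    "make_orbital_phantom",
    "make_stair_surface",
    "make_test_mesh",
]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the spherical-cap shell phantom.

    Intensities are HU-like: bone ~700, soft tissue ~40, noise SD ~20 give
    CT-grade contrast. ``supersample`` controls partial-volume fidelity:
    each voxel is subdivided ``supersample**3`` times and shell occupancy
    averaged, so edge voxels take intermediate intensities.
    ``defect_angle_deg`` removes an angular patch of the shell (0 = intact),
    emulating a blow-out defect.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    spacing_mm: tuple[float, float, float] = (0.4, 0.4, 0.7)
    shell_radius_mm: float = 10.0
    shell_thickness_mm: float = 0.9
    cap_angle_deg: float = 60.0
    bone_intensity: float = 700.0
    tissue_intensity: float = 40.0
    noise_sd: float = 20.0
    supersample: int = 4
    defect_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if not (0.5 <= self.shell_thickness_mm <= 2.0):
            raise ValueError(
                f"shell_thickness_mm must lie in [0.5, 2.0] mm, got {self.shell_thickness_mm}"
            )
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.bone_intensity <= self.tissue_intensity:
            raise ValueError("bone_intensity must exceed tissue_intensity")
        if not (0 < self.cap_angle_deg <= 90):
            raise ValueError("cap_angle_deg must lie in (0, 90]")


# Defect patch centred mid-cap, azimuth 0 (direction fixed; extent is the knob).
_DEFECT_POLAR_DEG = 30.0


def _shell_center(spec: PhantomSpec) -> np.ndarray:
    """Sphere centre placing the cap's z-midspan at the grid z-midspan."""
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    extent = (shape - 1) * spacing
    r_out = spec.shell_radius_mm
    z_lo = (r_out - spec.shell_thickness_mm) * math.cos(math.radians(spec.cap_angle_deg))
    z_hi = r_out
    cz = extent[2] / 2 - (z_lo + z_hi) / 2
    return np.array([extent[0] / 2, extent[1] / 2, cz])


def _shell_membership(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Boolean shell membership for an (n, 3) array of physical points."""
    d = pts - _shell_center(spec)
    r = np.linalg.norm(d, axis=-1)
    r_out = spec.shell_radius_mm
    inside = (r >= r_out - spec.shell_thickness_mm) & (r <= r_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.degrees(np.arccos(np.clip(d[..., 2] / np.maximum(r, 1e-12), -1, 1)))
    inside &= polar <= spec.cap_angle_deg
    if spec.defect_angle_deg > 0:
        t = math.radians(_DEFECT_POLAR_DEG)
        defect_dir = np.array([math.sin(t), 0.0, math.cos(t)])
        cosang = (d @ defect_dir) / np.maximum(r, 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        inside &= ang > spec.defect_angle_deg / 2
    return inside


def _check_fit(spec: PhantomSpec) -> None:
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    extent = (shape - 1) * spacing
    c = _shell_center(spec)
    r_out = spec.shell_radius_mm
    sin_cap = math.sin(math.radians(spec.cap_angle_deg))
    lo = c - np.array([r_out * sin_cap, r_out * sin_cap, 0.0])
    hi = c + np.array([r_out * sin_cap, r_out * sin_cap, r_out])
    names = "xyz"
    for a in range(3):
        if lo[a] < 0 or hi[a] > extent[a]:
            raise ValueError(
                f"shell does not fit inside the grid along axis {names[a]}: "
                f"needs [{lo[a]:.2f}, {hi[a]:.2f}] mm, grid spans [0, {extent[a]:.2f}] mm"
            )


def make_orbital_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, LabelVolume]:
    """Generate the CT-like shell volume and its ground-truth bone mask.

    Returns
    -------
    volume
        Intensities = tissue + occupancy * (bone - tissue) + Gaussian noise,
        occupancy averaged over ``supersample**3`` sub-voxel samples.
    mask
        Exact voxel-centre shell membership at grid resolution.
    """
    _check_fit(spec)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    s = spec.supersample

    # supersampled voxel-centre coordinates per axis: s points centred in each voxel
    axes = []
    for a in range(3):
        base = np.arange(shape[a]) * spacing[a]
        sub = (np.arange(s) + 0.5) / s - 0.5
        axes.append((base[:, None] + sub[None, :] * spacing[a]).ravel())
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    pts = np.stack(np.broadcast_arrays(xx, yy, zz), axis=-1)
    member = _shell_membership(spec, pts)
    occ = member.reshape(shape[0], s, shape[1], s, shape[2], s).mean(axis=(1, 3, 5))

    intensity = spec.tissue_intensity + occ * (spec.bone_intensity - spec.tissue_intensity)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    centers = np.stack(
        np.meshgrid(
            *(np.arange(shape[a]) * spacing[a] for a in range(3)), indexing="ij", sparse=False
        ),
        axis=-1,
    )
    mask = _shell_membership(spec, centers)

    vol = VoxelVolume(intensity, spacing_mm=spec.spacing_mm)
    lab = LabelVolume(mask.astype(np.uint8), spacing_mm=spec.spacing_mm)
    return vol, lab


@dataclasses.dataclass
class StairSurfaceSpec:
    """Parameters of the extruded-layer ('stair-step') surface phantom.

    The patch defaults to the 4 mm x 5.3 mm fields measured on template
    replicas. Ridges run along y; the x-period on the inclined surface is
    ``layer_height / sin(slope)``. ``bead_amplitude_coeff`` sets the
    peak-to-valley ridge height as a fraction of the layer height.
    """

    layer_height_mm: float = 0.2
    patch_size_mm: tuple[float, float] = (4.0, 5.3)
    lateral_spacing_mm: float = 0.0078
    bead_amplitude_coeff: float = 0.5
    slope_deg: float = 45.0
    noise_sd_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.05 <= self.layer_height_mm <= 0.35):
            raise ValueError(
                f"layer_height_mm must lie in [0.05, 0.35] mm, got {self.layer_height_mm}"
            )
        if any(p <= 0 for p in self.patch_size_mm) or self.lateral_spacing_mm <= 0:
            raise ValueError("patch dimensions and lateral spacing must be positive")
        if not (0 < self.slope_deg <= 90):
            raise ValueError("slope_deg must lie in (0, 90]")


def make_stair_surface(spec: StairSurfaceSpec) -> HeightMap:
    """Generate a stair-step height map (µm) of parallel bead ridges.

    Each period carries a circular-arc bead cross-section of peak-to-valley
    ``bead_amplitude_coeff * layer_height``; Gaussian measurement noise is
    added and the mean plane removed, so the returned map has ~zero mean.
    """
    period = spec.layer_height_mm / math.sin(math.radians(spec.slope_deg))
    if period < 2 * spec.lateral_spacing_mm:
        raise ValueError(
            f"ridge period {period:.4f} mm is below 2 x lateral spacing "
            f"({2 * spec.lateral_spacing_mm:.4f} mm): ridges unresolvable"
        )
    nx = int(round(spec.patch_size_mm[0] / spec.lateral_spacing_mm)) + 1
    ny = int(round(spec.patch_size_mm[1] / spec.lateral_spacing_mm)) + 1
    x = np.arange(nx) * spec.lateral_spacing_mm

    # circular arc through peak A above the valley line, zero at period edges
    amp_mm = spec.bead_amplitude_coeff * spec.layer_height_mm
    half = period / 2
    arc_r = (half**2 + amp_mm**2) / (2 * amp_mm)
    u = (x % period) - half
    profile_um = (np.sqrt(arc_r**2 - u**2) - (arc_r - amp_mm)) * 1000.0

    heights = np.tile(profile_um[:, None], (1, ny))
    if spec.noise_sd_um > 0:
        rng = np.random.default_rng(spec.seed)
        heights = heights + rng.normal(0.0, spec.noise_sd_um, size=heights.shape)
    heights = heights - heights.mean()
    return HeightMap(
        heights_um=heights,
        lateral_spacing_mm=spec.lateral_spacing_mm,
    )


def _cap_mesh(radius: float, cap_angle_deg: float, rings: int) -> trimesh.Trimesh:
    """Closed UV spherical cap: curved cap surface plus a flat base disk."""
    seg = max(3 * rings, 12)
    polar = np.linspace(0.0, math.radians(cap_angle_deg), rings + 1)[1:]
    az = np.linspace(0.0, 2 * math.pi, seg, endpoint=False)
    verts = [np.array([0.0, 0.0, radius])]  # apex
    for t in polar:
        ring = np.stack(
            [
                radius * math.sin(t) * np.cos(az),
                radius * math.sin(t) * np.sin(az),
                np.full(seg, radius * math.cos(t)),
            ],
            axis=1,
        )
        verts.append(ring)
    base_z = radius * math.cos(math.radians(cap_angle_deg))
    verts.append(np.array([0.0, 0.0, base_z]))  # base centre
    vertices = np.vstack([np.atleast_2d(v) for v in verts])

    faces = []
    first = 1
    for j in range(seg):  # apex fan, outward (CCW seen from outside)
        faces.append([0, first + j, first + (j + 1) % seg])
    for i in range(rings - 1):
        a0 = 1 + i * seg
        b0 = a0 + seg
        for j in range(seg):
            j1 = (j + 1) % seg
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    base_c = len(vertices) - 1
    last = 1 + (rings - 1) * seg
    for j in range(seg):  # base disk, outward is -z
        faces.append([base_c, last + (j + 1) % seg, last + j])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


def make_test_mesh(kind: str, size_mm: float = 10.0, resolution: int = 3) -> trimesh.Trimesh:
    """Watertight, consistently wound primitive: 'sphere', 'cap', or 'plate'.

    ``size_mm`` is the radius for sphere/cap and the edge length for the
    plate (thickness = size/10). ``resolution`` is icosphere subdivision
    depth (sphere) or polar ring count (cap).
    """
    if kind == "sphere":
        return trimesh.creation.icosphere(subdivisions=resolution, radius=float(size_mm))
    if kind == "cap":
        return _cap_mesh(float(size_mm), cap_angle_deg=60.0, rings=max(int(resolution) * 4, 4))
    if kind == "plate":
        s = float(size_mm)
        return trimesh.creation.box(extents=(s, s, s / 10))
    raise ValueError(f"unknown test-mesh kind {kind!r}; expected sphere|cap|plate")
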