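"""Volume containers and I/O.

All image-stage operations act on :class:`VoxelVolume`: a 3D scalar grid
with per-axis physical spacing (mm) and an origin. Axis order is fixed as
(x, y, z) with z the slice axis; voxel centres sit at
``origin + index * spacing`` (voxel-centre convention). Intensities are
HU-like and never rescaled implicitly.

The native interchange format is a NumPy ``.npz`` archive holding the grid
plus spacing and origin. A deliberately narrow DICOM-series reader handles
single-frame CT slices sorted by slice position; DICOM writing and modality
metadata beyond spacing/position are out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelVolume",
    "LabelVolume",
    "AnnotationSet",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "anisotropy_ratio",
]


def _check_spacing(spacing_mm: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing_mm}")
    return spacing  # type: ignore[return-value]


@dataclasses.dataclass
class VoxelVolume:
    """3D intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data
        Scalar array indexed ``[i, j, k]`` for axes (x, y, z).
    spacing_mm
        Physical voxel size per axis, mm.
    origin_mm
        Physical position of voxel (0, 0, 0), mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_center(self, index: Sequence[float]) -> np.ndarray:
        """Physical coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing_mm
        )

    def index_of(self, point_mm: Sequence[float]) -> np.ndarray:
        """Fractional voxel index of a physical point (inverse of voxel_center)."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.spacing_mm
        )

    def extent_mm(self) -> np.ndarray:
        """Physical span from first to last voxel centre per axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm)


@dataclasses.dataclass
class LabelVolume:
    """Binary mask on the same grid as its source volume: 1 = bone, 0 = non-bone."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got shape {self.data.shape}")
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"labels must be binary 0/1, found values {uniq[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclasses.dataclass
class AnnotationSet:
    """Sparse two-class seed annotations: (voxel index triple, class in {0, 1})."""

    points: list[tuple[tuple[int, int, int], int]]

    def __post_init__(self) -> None:
        classes = {c for _, c in self.points}
        if not classes <= {0, 1}:
            raise ValueError(f"annotation classes must be 0/1, got {classes}")
        if classes != {0, 1}:
            raise ValueError("annotations must contain at least one point of each class")

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        for idx, _ in self.points:
            if any(not (0 <= idx[a] < shape[a]) for a in range(3)):
                raise IndexError(f"annotation index {idx} out of bounds for shape {shape}")

    def indices(self) -> np.ndarray:
        return np.array([idx for idx, _ in self.points], dtype=int)

    def labels(self) -> np.ndarray:
        return np.array([c for _, c in self.points], dtype=int)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        """Read annotations from CSV rows ``i,j,k,class`` (header optional)."""
        pts = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line[0].isalpha():
                continue
            i, j, k, c = (int(float(tok)) for tok in line.split(","))
            pts.append(((i, j, k), c))
        return cls(pts)

    def to_csv(self, path: str | Path) -> None:
        lines = ["i,j,k,class"]
        lines += [f"{i},{j},{k},{c}" for (i, j, k), c in self.points]
        Path(path).write_text("\n".join(lines) + "\n")


def write_volume(vol: VoxelVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume to the native ``.npz`` container (lossless round trip)."""
    np.savez(
        Path(path),
        data=vol.data,
        spacing_mm=np.asarray(vol.spacing_mm, dtype=float),
        origin_mm=np.asarray(vol.origin_mm, dtype=float),
        is_label=np.array(isinstance(vol, LabelVolume)),
    )


def read_volume(path: str | Path) -> VoxelVolume | LabelVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        cls = LabelVolume if bool(npz["is_label"]) else VoxelVolume
        return cls(
            data=npz["data"],
            spacing_mm=tuple(npz["spacing_mm"]),
            origin_mm=tuple(npz["origin_mm"]),
        )


def read_dicom_series(directory: str | Path, spacing_tol: float = 1e-3) -> VoxelVolume:
    """Read a directory of single-frame CT DICOM slices into a volume.

    Slices are sorted by ``ImagePositionPatient`` z; the series must have a
    uniform slice step. Raises on inconsistent spacing, listing the offending
    slice indices.
    """
    import pydicom

    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(directory)
    slices = []
    for p in sorted(directory.iterdir()):
        if p.is_file():
            try:
                ds = pydicom.dcmread(p)
            except Exception:
                continue
            if hasattr(ds, "PixelData"):
                slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    steps = np.diff(zs)
    if len(steps):
        bad = np.nonzero(np.abs(steps - np.median(steps)) > spacing_tol)[0]
        if bad.size:
            raise ValueError(
                "inconsistent slice spacing between slice indices "
                f"{[(int(b), int(b) + 1) for b in bad]}"
            )
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    dz = float(np.median(steps)) if len(steps) else float(getattr(first, "SliceThickness", 1.0))
    # DICOM stores rows x cols (y, x); transpose to (x, y) then stack along z
    data = np.stack([np.asarray(ds.pixel_array).T for ds in slices], axis=-1).astype(np.float64)
    ox, oy = (float(v) for v in first.ImagePositionPatient[:2])
    return VoxelVolume(data, spacing_mm=(dx, dy, dz), origin_mm=(ox, oy, float(zs[0])))


def anisotropy_ratio(vol: VoxelVolume) -> float:
    """Slice-to-pixel spacing ratio dz/dx; 1.0 for isotropic volumes."""
    dx, _, dz = vol.spacing_mm
    return dz / dx
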