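"""Macro- and micro-scale metrological validation.

Two scales, mirroring how printed surgical templates are verified:

* **Macro**: signed point-to-surface deviations between a measured point
  cloud (or scanned mesh) and the nominal CAD mesh, summarised as
  max/min/range/mean/SD with the fraction inside a tolerance band
  (default +-0.2 mm).

* **Micro**: areal surface-texture parameters on height-map patches.
  Form and waviness are removed with a least-squares plane plus an areal
  Gaussian high-pass filter (50% transmission at the cutoff wavelength,
  default 1 mm). Sa is the arithmetical mean absolute height. The Sk
  family (Spk, Sk, Svk) comes from the material-ratio (Abbott-Firestone)
  curve via the standard 40% least-slope secant construction. Rsm is the
  mean width of profile elements on profiles taken perpendicular to the
  printed-layer ridges, with height and spacing discrimination.

Correlation statistics (Pearson r, Fisher-z 95% CI, t-test p) connect layer
height to the texture parameters, including a grouped form that works from
per-group mean/SD/n summaries and is algebraically identical to expanding
each group of three as {m-s, m, m+s}.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "HeightMap",
    "TextureParams",
    "DeviationResult",
    "CorrelationResult",
    "deviation_map",
    "highpass_surface",
    "compute_sa",
    "compute_sk_family",
    "compute_rsm",
    "texture_params",
    "pearson_r",
    "grouped_pearson_r",
    "fisher_ci",
    "read_heightmap",
    "write_heightmap",
]

# Gaussian filter constant: 50% amplitude transmission at the cutoff wavelength
# for a kernel exp(-x^2 / 2 sigma^2) with sigma = _GAUSS_SIGMA_FACTOR * cutoff.
_GAUSS_SIGMA_FACTOR = math.sqrt(math.log(2.0)) / (math.pi * math.sqrt(2.0))


@dataclasses.dataclass
class HeightMap:
    """Regular 2D grid of surface heights in µm with lateral spacing in mm."""

    heights_um: np.ndarray
    lateral_spacing_mm: float

    def __post_init__(self) -> None:
        self.heights_um = np.asarray(self.heights_um, dtype=float)
        if self.heights_um.ndim != 2:
            raise ValueError("height map must be 2D")
        if not np.all(np.isfinite(self.heights_um)):
            raise ValueError("height map contains non-finite values")
        if self.lateral_spacing_mm <= 0:
            raise ValueError("lateral spacing must be positive")

    @property
    def patch_size_mm(self) -> tuple[float, float]:
        nx, ny = self.heights_um.shape
        return ((nx - 1) * self.lateral_spacing_mm, (ny - 1) * self.lateral_spacing_mm)


@dataclasses.dataclass
class TextureParams:
    """Areal texture parameters of one filtered surface patch (all µm)."""

    Sa_um: float
    Spk_um: float
    Sk_um: float
    Svk_um: float
    Rsm_um: float


@dataclasses.dataclass
class DeviationResult:
    """Signed-deviation statistics between measured and nominal geometry."""

    n_points: int
    max_mm: float
    min_mm: float
    range_mm: float
    mean_mm: float
    sd_mm: float
    deviations_mm: np.ndarray
    tolerance_band_mm: float
    fraction_in_tolerance: float


@dataclasses.dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def deviation_map(
    measured,
    nominal,
    prealign: bool = False,
    tol: float = 0.2,
    align_tol_mm: float = 0.005,
    seed: int = 0,
) -> DeviationResult:
    """Signed point-to-surface deviations of measured data from a nominal mesh.

    ``measured`` is an (n, 3) point array or a mesh (its vertices are used).
    Positive deviations lie outside the nominal surface along its normal.
    With ``prealign``, a rigid best-fit registration (convergence tolerance
    ``align_tol_mm``) is applied to the measured data first.
    """
    import trimesh

    from ._proximity import closest_on_mesh

    if hasattr(measured, "vertices"):
        points = np.asarray(measured.vertices, dtype=float)
    else:
        points = np.asarray(measured, dtype=float)
    if points.size == 0:
        raise ValueError("measured point set is empty")
    points = points.reshape(-1, 3)

    if prealign:
        from .template import best_fit_align

        src = trimesh.Trimesh(vertices=points, faces=np.zeros((0, 3), dtype=int), process=False)
        res = best_fit_align(src, nominal, tol_mm=align_tol_mm, seed=seed)
        points = points @ res.transform.rotation.T + res.transform.translation_mm

    closest, dist, normals = closest_on_mesh(nominal, points, with_normals=True)
    sign = np.sign(np.einsum("ij,ij->i", points - closest, normals))
    sign[sign == 0] = 1.0
    dev = sign * dist

    return DeviationResult(
        n_points=len(dev),
        max_mm=float(dev.max()),
        min_mm=float(dev.min()),
        range_mm=float(dev.max() - dev.min()),
        mean_mm=float(dev.mean()),
        sd_mm=float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
        deviations_mm=dev,
        tolerance_band_mm=tol,
        fraction_in_tolerance=float(np.mean(np.abs(dev) <= tol)),
    )


def _remove_plane(z: np.ndarray, spacing: float) -> np.ndarray:
    nx, ny = z.shape
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    xx, yy = np.meshgrid(x, y, indexing="ij")
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(z.size)])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    return z - (A @ coef).reshape(z.shape)


def highpass_surface(hm: HeightMap, cutoff_mm: float = 1.0) -> HeightMap:
    """Remove form (LSQ plane) and waviness (Gaussian low-pass at the cutoff).

    The areal Gaussian filter transmits 50% of a sinusoid's amplitude at the
    cutoff wavelength; shorter wavelengths pass nearly untouched, longer ones
    are suppressed into the waviness surface that gets subtracted.
    """
    if min(hm.patch_size_mm) <= cutoff_mm:
        raise ValueError(
            f"patch {hm.patch_size_mm} mm is not larger than the cutoff {cutoff_mm} mm"
        )
    z = _remove_plane(hm.heights_um, hm.lateral_spacing_mm)
    sigma_samples = _GAUSS_SIGMA_FACTOR * cutoff_mm / hm.lateral_spacing_mm
    waviness = ndimage.gaussian_filter(z, sigma=sigma_samples, mode="nearest")
    out = z - waviness
    return HeightMap(out - out.mean(), hm.lateral_spacing_mm)


def compute_sa(hm: HeightMap) -> float:
    """Arithmetical mean height Sa (µm): mean absolute deviation from the mean plane."""
    z = hm.heights_um
    return float(np.abs(z - z.mean()).mean())


def _material_ratio_curve(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Abbott-Firestone curve: heights sorted descending vs material ratio in (0,1]."""
    heights = np.sort(z.ravel())[::-1]
    mr = (np.arange(heights.size) + 0.5) / heights.size
    return mr, heights


def compute_sk_family(hm: HeightMap) -> tuple[float, float, float]:
    """Reduced peak height Spk, core height Sk, reduced dale height Svk (µm).

    Construction on the areal material-ratio curve: slide a 40%-wide window
    to find the least-slope secant; the line through its endpoints, extended
    to 0% and 100%, is the equivalent core line. Sk is its height span.
    Smr1/Smr2 are the ratios where the curve crosses the line's end levels;
    Spk and Svk are the heights of area-equivalent triangles built on the
    excess material above Smr1 and missing material below Smr2.
    """
    mr, h = _material_ratio_curve(hm.heights_um - hm.heights_um.mean())
    n = h.size
    if h[0] - h[-1] <= 0:
        return 0.0, 0.0, 0.0
    w = max(int(round(0.4 * n)), 1)
    diffs = h[: n - w] - h[w:]
    # tie handling: all windows within a small tolerance of the least slope
    # contribute, and their secant lines are averaged. On generic surfaces a
    # single window wins; on exactly symmetric curves (where the flattest
    # windows tie at both ends) the averaged line restores the symmetry the
    # surface itself has.
    tol = 1e-3 * (h[0] - h[-1])
    ties = np.nonzero(diffs <= diffs.min() + tol)[0]
    slopes = (h[ties + w] - h[ties]) / (mr[ties + w] - mr[ties])
    h0 = float(np.mean(h[ties] + slopes * (0.0 - mr[ties])))
    h1 = float(np.mean(h[ties] + slopes * (1.0 - mr[ties])))
    sk = h0 - h1

    above = h > h0
    smr1 = float(above.mean())
    below = h < h1
    smr2 = 1.0 - float(below.mean())
    a1 = float(np.sum(h[above] - h0)) / n  # excess material area above the core
    a2 = float(np.sum(h1 - h[below])) / n  # missing material area below the core
    spk = 2.0 * a1 / smr1 if smr1 > 0 else 0.0
    svk = 2.0 * a2 / (1.0 - smr2) if smr2 < 1 else 0.0
    return float(spk), float(sk), float(svk)


def _profile_element_widths(
    profile: np.ndarray,
    spacing: float,
    height_discrim: float,
    spacing_discrim: float,
    discrim_floor: float,
) -> np.ndarray:
    """Widths of profile elements between accepted upward mean-line crossings."""
    z = profile - profile.mean()
    p2v = z.max() - z.min()
    c = max(height_discrim * p2v / 2.0, discrim_floor)
    min_spacing = spacing_discrim * spacing * len(z)

    up = np.nonzero((z[:-1] < 0) & (z[1:] >= 0))[0]
    accepted: list[float] = []
    last = None
    seg_start = 0
    for idx in up:
        # linear interpolation of the crossing position
        xc = idx + (0.0 - z[idx]) / (z[idx + 1] - z[idx])
        seg = z[seg_start : idx + 1]
        if seg.size and seg.max() >= c and seg.min() <= -c:
            if last is None or (xc - last) * spacing >= min_spacing:
                accepted.append(xc)
                last = xc
                seg_start = idx + 1
    if len(accepted) < 3:
        raise ValueError("insufficient profile elements above discrimination thresholds")
    return np.diff(accepted) * spacing


def compute_rsm(
    hm: HeightMap,
    n_profiles: int = 6,
    height_discrim: float = 0.1,
    spacing_discrim: float = 0.01,
    discrim_floor_um: float = 1.0,
    axis: int = 0,
) -> float:
    """Mean width Rsm (µm) of profile elements, averaged over profiles.

    Profiles run along ``axis`` (default 0, perpendicular to ridges that run
    along axis 1), ``n_profiles`` equally spaced across the patch. A profile
    element spans successive upward mean-line crossings; crossings count only
    if the profile rose above and fell below half the discrimination height
    (``height_discrim`` x peak-to-valley, floored at ``discrim_floor_um`` to
    ignore sub-resolution features) and elements narrower than
    ``spacing_discrim`` x profile length are merged.
    """
    z = hm.heights_um if axis == 0 else hm.heights_um.T
    n_across = z.shape[1]
    cols = np.linspace(0, n_across - 1, n_profiles + 2)[1:-1].round().astype(int)
    spacing_um = hm.lateral_spacing_mm * 1000.0
    widths = []
    for col in cols:
        widths.append(
            _profile_element_widths(
                z[:, col], spacing_um, height_discrim, spacing_discrim, discrim_floor_um
            ).mean()
        )
    return float(np.mean(widths))


def texture_params(hm: HeightMap, **rsm_kwargs) -> TextureParams:
    """All texture parameters of a filtered patch in one pass."""
    spk, sk, svk = compute_sk_family(hm)
    return TextureParams(
        Sa_um=compute_sa(hm),
        Spk_um=spk,
        Sk_um=sk,
        Svk_um=svk,
        Rsm_um=compute_rsm(hm, **rsm_kwargs),
    )


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if n < 4:
        raise ValueError("Fisher CI requires n >= 4")
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def pearson_r(x: Sequence[float], y: Sequence[float], conf: float = 0.95) -> CorrelationResult:
    """Sample Pearson r with t-test p-value (n-2 df) and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("Pearson r requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < 1:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * float(stats.t.sf(abs(t), n - 2))
        lo, hi = fisher_ci(r, n, conf) if n >= 4 else (-1.0, 1.0)
    else:
        p = 0.0
        lo = hi = r
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p_value=p, n=n)


def grouped_pearson_r(
    xs: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    ns: Sequence[int],
    conf: float = 0.95,
) -> CorrelationResult:
    """Pearson r of y against x from per-group summaries (mean, SD, n) of y.

    Every observation in group g shares x-value ``xs[g]``. The within-group
    scatter enters only the y sum of squares:

        r = sum n_g (x_g - xbar)(m_g - ybar)
            / sqrt( sum n_g (x_g - xbar)^2
                    * sum [ n_g (m_g - ybar)^2 + (n_g - 1) s_g^2 ] )

    For n_g = 3 this equals ``pearson_r`` on the expansion {m-s, m, m+s}.
    """
    xs = np.asarray(xs, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(xs) == len(means) == len(sds) == len(ns)):
        raise ValueError("xs, means, sds, ns must have equal length")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    n_tot = int(ns.sum())
    xbar = float(np.sum(ns * xs) / n_tot)
    ybar = float(np.sum(ns * means) / n_tot)
    sxy = float(np.sum(ns * (xs - xbar) * (means - ybar)))
    sxx = float(np.sum(ns * (xs - xbar) ** 2))
    syy = float(np.sum(ns * (means - ybar) ** 2 + (ns - 1) * sds**2))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in grouped data")
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) < 1:
        t = r * math.sqrt((n_tot - 2) / (1 - r * r))
        p = 2 * float(stats.t.sf(abs(t), n_tot - 2))
        lo, hi = fisher_ci(r, n_tot, conf)
    else:
        p = 0.0
        lo = hi = r
    return CorrelationResult(r=float(r), ci_low=lo, ci_high=hi, p_value=p, n=n_tot)


def write_heightmap(hm: HeightMap, path: str | Path) -> None:
    """Plain-text matrix grid with a 2-line header (spacing, units)."""
    header = f"lateral_spacing_mm {hm.lateral_spacing_mm}\nunits um"
    np.savetxt(Path(path), hm.heights_um, header=header, comments="# ")


def read_heightmap(path: str | Path, replica: bool = False) -> HeightMap:
    """Read a height map written by :func:`write_heightmap`.

    With ``replica=True`` heights are sign-flipped on load: replicas are
    negatives of the measured surface (Sa and Rsm are invariant; Spk and
    Svk swap).
    """
    path = Path(path)
    spacing = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line.lstrip("# ").split()
                if parts and parts[0] == "lateral_spacing_mm":
                    spacing = float(parts[1])
            else:
                break
    if spacing is None:
        raise ValueError(f"{path}: missing lateral_spacing_mm header line")
    z = np.loadtxt(path)
    if replica:
        z = -z
    return HeightMap(z, spacing)
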