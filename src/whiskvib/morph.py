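"""Cross-sectional morphometry of whisker CT volumes.

Reimplements the slice-wise shape analysis commonly run on micro-CT scans of
whisker shafts: per-slice cross-sectional area, maximum/minimum caliper
(Feret) width, theta (the angle of the principal cross-sectional axis from
the slide-plane horizontal), and eccentricity, plus crest/trough detection on
the caliper profile of undulated whiskers.

Conventions
-----------
* Volumes are ``(z, y, x)``; slices are taken along ``z`` (the shaft axis
  for phantoms scanned lying flat on a slide).
* Caliper widths sweep directions in 0.5 deg steps over [0, 180); each
  extent is the convex-hull projection of foreground *pixel centers* plus
  one pixel spacing, which is unbiased for digitized discs.
* Theta comes from the second central image moments,
  ``theta = 0.5 * atan2(2*mu11, mu20 - mu02)``, mapped to (-90, 90] degrees
  and measured from the x (slide-plane horizontal) axis.  Circular sections
  have no defined orientation: theta is reported as 0 with a flag.
* Eccentricity uses the caliper widths: ``e = sqrt(1 - (min/max)^2)``, 0 for
  a circle and < 1 for any ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "CrossSectionMask",
    "SliceMetrics",
    "ShaftProfile",
    "NoWhiskerError",
    "AmbiguousSliceError",
    "DegenerateGeometryError",
    "segment_slice",
    "caliper_widths",
    "principal_axis_theta",
    "eccentricity",
    "slice_metrics",
    "profile_along_shaft",
    "detect_crests_troughs",
    "area_consistency_stat",
]

CALIPER_STEP_DEG = 0.5
# a second component is "large" (ambiguous) above this fraction of the largest
_AMBIGUITY_FRACTION = 0.5
# relative moment anisotropy below which orientation is undefined
_CIRCULAR_TOL = 1e-2


class NoWhiskerError(ValueError):
    """No foreground found: no whisker in slice."""


class AmbiguousSliceError(ValueError):
    """More than one comparably-sized component after cleaning."""


class DegenerateGeometryError(ValueError):
    """Mask too small for the requested metric."""


@dataclass
class CrossSectionMask:
    mask: np.ndarray  # 2-D bool
    pixel_spacing: float  # um
    slice_index: int = 0
    arc_position: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class SliceMetrics:
    """Shape metrics of one cross-section.  Lengths in mm, area in mm^2."""

    area: float
    max_caliper: float
    min_caliper: float
    theta: float  # degrees in (-90, 90]
    eccentricity: float
    centroid: tuple[float, float]  # (x, y) mm
    slice_index: int = 0
    arc_position: float = 0.0  # mm
    orientation_undefined: bool = False


@dataclass
class ShaftProfile:
    """Ordered per-slice metrics from base (largest area) to tip."""

    slices: list[SliceMetrics]
    crest_indices: list[int] = field(default_factory=list)
    trough_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slices)

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.slices], dtype=float)

    @property
    def arc_mm(self) -> np.ndarray:
        return self.series("arc_position")


def segment_slice(
    volume: np.ndarray,
    slice_index: int,
    pixel_spacing: float,
    threshold: float | None = None,
    arc_position: float = 0.0,
) -> CrossSectionMask:
    """Segment the whisker cross-section in one slice of a ``(z, y, x)`` volume.

    Thresholds the slice (Otsu by default, or a fixed ``threshold``), keeps
    the largest connected component, and fills holes.
    """
    img = np.asarray(volume[slice_index], dtype=float)
    if threshold is None:
        if img.max() <= img.min():
            raise NoWhiskerError(f"no whisker in slice {slice_index}")
        threshold = threshold_otsu(img)
    fg = img > threshold
    if not fg.any():
        raise NoWhiskerError(f"no whisker in slice {slice_index}")
    labels, n = label(fg, return_num=True, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] >= _AMBIGUITY_FRACTION * sizes[order[0]]:
        raise AmbiguousSliceError(
            f"slice {slice_index}: {n} comparable components after cleaning"
        )
    mask = ndimage.binary_fill_holes(labels == order[0] + 1)
    return CrossSectionMask(
        mask=mask,
        pixel_spacing=pixel_spacing,
        slice_index=slice_index,
        arc_position=arc_position,
    )


def _hull_points(mask: CrossSectionMask) -> np.ndarray:
    """Convex-hull vertices of foreground pixel centers, in (x, y) pixels."""
    ys, xs = np.nonzero(mask.mask)
    if xs.size == 0:
        raise NoWhiskerError("empty mask")
    if xs.size == 1:
        raise DegenerateGeometryError("single-pixel mask has no caliper width")
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:  # collinear points: use them all
        return pts


def caliper_widths(mask: CrossSectionMask) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) width of the mask, in mm.

    Projects the convex hull of pixel centers onto directions swept in
    0.5 deg steps over [0, 180) and adds one pixel spacing to each extent.
    """
    verts = _hull_points(mask)
    ang = np.deg2rad(np.arange(0.0, 180.0, CALIPER_STEP_DEG))
    dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    proj = verts @ dirs.T  # (n_verts, n_dirs)
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0  # pixels
    spacing_mm = mask.pixel_spacing / 1000.0
    return float(extents.max() * spacing_mm), float(extents.min() * spacing_mm)


def _central_moments(mask: np.ndarray) -> tuple[float, float, float]:
    ys, xs = np.nonzero(mask)
    x0, y0 = xs.mean(), ys.mean()
    dx, dy = xs - x0, ys - y0
    return float((dx * dx).mean()), float((dy * dy).mean()), float((dx * dy).mean())


def principal_axis_theta(mask: CrossSectionMask) -> tuple[float, bool]:
    """Angle of the principal cross-sectional axis from horizontal, in degrees.

    Returns ``(theta, orientation_undefined)``; circular sections (isotropic
    second moments) get theta 0 with the flag set.
    """
    if not mask.mask.any():
        raise NoWhiskerError("empty mask")
    mu20, mu02, mu11 = _central_moments(mask.mask)
    aniso = math.hypot(mu20 - mu02, 2.0 * mu11)
    if aniso < _CIRCULAR_TOL * (mu20 + mu02):
        return 0.0, True
    theta = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    return theta, False


def eccentricity(max_caliper: float, min_caliper: float) -> float:
    """Eccentricity e = sqrt(1 - (min/max)^2): 0 for a circle, < 1 always."""
    if min_caliper <= 0:
        raise ValueError(f"min caliper must be positive, got {min_caliper}")
    if max_caliper < min_caliper:
        raise ValueError("max caliper smaller than min caliper")
    return math.sqrt(1.0 - (min_caliper / max_caliper) ** 2)


def slice_metrics(mask: CrossSectionMask) -> SliceMetrics:
    """All shape metrics of one segmented cross-section."""
    spacing_mm = mask.pixel_spacing / 1000.0
    area = float(mask.mask.sum()) * spacing_mm**2
    fmax, fmin = caliper_widths(mask)
    theta, undefined = principal_axis_theta(mask)
    ys, xs = np.nonzero(mask.mask)
    return SliceMetrics(
        area=area,
        max_caliper=fmax,
        min_caliper=fmin,
        theta=theta,
        eccentricity=eccentricity(fmax, fmin),
        centroid=(float(xs.mean()) * spacing_mm, float(ys.mean()) * spacing_mm),
        slice_index=mask.slice_index,
        arc_position=mask.arc_position,
        orientation_undefined=undefined,
    )


def profile_along_shaft(
    volume: np.ndarray,
    pixel_spacing: float,
    threshold: float | None = None,
    crest_prominence: float = 0.05,
) -> ShaftProfile:
    """Per-slice metrics along a whisker volume, ordered base -> tip.

    The base is the largest-area end.  Empty slices at either end are
    skipped; an empty slice in the interior raises with its index attached.
    """
    nz = volume.shape[0]
    occupied = [
        z for z in range(nz) if (np.asarray(volume[z]) > (threshold or 0)).any()
    ]
    if not occupied:
        raise NoWhiskerError("volume contains no whisker")
    z0, z1 = occupied[0], occupied[-1]
    metrics: list[SliceMetrics] = []
    for z in range(z0, z1 + 1):
        try:
            mask = segment_slice(
                volume,
                z,
                pixel_spacing,
                threshold=threshold,
                arc_position=z * pixel_spacing / 1000.0,
            )
            metrics.append(slice_metrics(mask))
        except (NoWhiskerError, AmbiguousSliceError, DegenerateGeometryError) as exc:
            raise type(exc)(f"slice {z}: {exc}") from exc
    if metrics[0].area < metrics[-1].area:  # base = largest-area end
        metrics = metrics[::-1]
        arc0 = metrics[0].arc_position
        for m in metrics:
            m.arc_position = arc0 - m.arc_position
    else:
        arc0 = metrics[0].arc_position
        for m in metrics:
            m.arc_position = m.arc_position - arc0
    profile = ShaftProfile(slices=metrics)
    if len(metrics) >= 5:
        crests, troughs = detect_crests_troughs(
            profile.series("max_caliper"), prominence_fraction=crest_prominence
        )
        profile.crest_indices = crests
        profile.trough_indices = troughs
    return profile


def detect_crests_troughs(
    max_caliper_series: np.ndarray, prominence_fraction: float = 0.05
) -> tuple[list[int], list[int]]:
    """Local maxima (crests) and minima (troughs) of a caliper-width series.

    Prominence threshold is ``prominence_fraction`` of the series median.
    Crest and trough indices are forced to interleave by keeping, between
    consecutive extrema of one kind, only the most extreme of the other kind.
    """
    x = np.asarray(max_caliper_series, dtype=float)
    if x.size < 5:
        raise ValueError("series too short for extremum detection")
    prom = prominence_fraction * float(np.median(x))
    crests, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    if len(crests) == 0 or len(troughs) == 0:
        return list(crests), list(troughs)
    # enforce strict alternation
    events = sorted([(i, "c") for i in crests] + [(i, "t") for i in troughs])
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx, _ = kept[-1]
            better = (
                x[idx] > x[prev_idx] if kind == "c" else x[idx] < x[prev_idx]
            )
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    return (
        [i for i, k in kept if k == "c"],
        [i for i, k in kept if k == "t"],
    )


def area_consistency_stat(profile: ShaftProfile) -> tuple[float, float] | None:
    """Detrended CVs of area and max caliper at the crest/trough slices.

    Quantifies the observation that cross-sectional area stays nearly
    constant across neighboring undulations while the caliper width swings.
    A local linear fit over arc position removes the taper before computing
    each coefficient of variation.  Returns ``None`` when fewer than 2 crests
    or 2 troughs are available (e.g. smooth whiskers).
    """
    if len(profile.crest_indices) < 2 or len(profile.trough_indices) < 2:
        return None
    idx = np.array(sorted(profile.crest_indices + profile.trough_indices))
    arc = profile.arc_mm[idx]

    def detrended_cv(values: np.ndarray) -> float:
        # local linear fit: each extremum against a window of its neighbors,
        # so the taper (including its curvature) is removed, not the undulation
        resid = np.empty_like(values)
        half = 2
        for i in range(values.size):
            lo, hi = max(0, i - half), min(values.size, i + half + 1)
            coef = np.polyfit(arc[lo:hi], values[lo:hi], 1)
            resid[i] = values[i] - np.polyval(coef, arc[i])
        return float(np.std(resid) / np.mean(values))

    return (
        detrended_cv(profile.series("area")[idx]),
        detrended_cv(profile.series("max_caliper")[idx]),
    )
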