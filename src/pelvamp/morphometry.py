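"""Lesion morphometry: plaque depth and severity, cyst axes and volume change.

Plaque depth follows the supporting-line construction used for reading
support: on each sagittal slice, the plaque contour points lying within a
predetermined distance of the uterus boundary form the contact set; the chord
through the two extreme contact points fixes a direction, and the depth is
the perpendicular distance between the two lines parallel to that chord that
enclose the plaque.  The per-lesion depth is the maximum over slices, and the
severity grade is none (0 mm), mild (< 5 mm) or severe (>= 5 mm).

Cyst (OEC) axes come from a direct least-squares ellipse fit of the subpixel
mask contour on every axial slice; the slice whose fitted ellipse has the
largest area is reported.  Volumes are voxel counts times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import LabelMask

__all__ = [
    "SEVERITY_THRESHOLD_MM",
    "PlaqueMeasurement",
    "EllipseAxes",
    "VolumeChange",
    "severity_from_depth",
    "plaque_depth_slice",
    "plaque_depth",
    "fit_ellipse_axes",
    "oec_axes",
    "mask_volume",
    "volume_change",
]

#: Severity cut: depths >= 5 mm grade as "severe" ("5 mm or more").
SEVERITY_THRESHOLD_MM = 5.0

#: Default contact-search distance: two in-plane voxels.
DEFAULT_CONTACT_DIST_MM = 1.2

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PlaqueMeasurement:
    depth_mm: float
    argmax_slice: int | None
    width_mm: float
    severity: str  # "none" | "mild" | "severe"


@dataclass(frozen=True)
class EllipseAxes:
    major_mm: float
    minor_mm: float
    slice_index: int
    center_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.major_mm >= self.minor_mm > 0:
            raise ValueError("ellipse axes must satisfy major >= minor > 0")


@dataclass(frozen=True)
class VolumeChange:
    pre_mm3: float
    post_mm3: float

    @property
    def delta_mm3(self) -> float:
        return self.post_mm3 - self.pre_mm3


def severity_from_depth(depth_mm: float) -> str:
    """Grade a plaque depth: none (0), mild (< 5 mm), severe (>= 5 mm)."""
    if depth_mm < 0:
        raise ValueError("depth must be >= 0")
    if depth_mm == 0:
        return "none"
    return "severe" if depth_mm >= SEVERITY_THRESHOLD_MM else "mild"


def _contour_pixels(mask2d: np.ndarray) -> np.ndarray:
    """8-connected boundary pixels of a 2D binary mask (as an index array)."""
    eroded = ndimage.binary_erosion(mask2d, structure=np.ones((3, 3), dtype=bool))
    return np.argwhere(mask2d & ~eroded)


def _contact_direction(points_mm: np.ndarray) -> np.ndarray | None:
    """Unit direction of the contact line: the principal axis of the contact set.

    The contact set is one to two pixels thick, so the chord through its two
    extreme points systematically tilts by one pixel across the set width;
    the total-least-squares (principal) direction is the stable estimate of a
    line parallel to the contact surface.  Returns ``None`` when the points
    are coincident.
    """
    centered = points_mm - points_mm.mean(axis=0)
    cov = centered.T @ centered
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        return None
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] <= 0:
        return None
    return vecs[:, -1]


def plaque_depth_slice(
    uterus2d: np.ndarray,
    plaque2d: np.ndarray,
    spacing2d: Sequence[float],
    contact_dist_mm: float = DEFAULT_CONTACT_DIST_MM,
) -> float | None:
    """Supporting-line plaque depth on one sagittal slice, in mm.

    Returns ``None`` when the plaque is empty or no usable contact set with
    the uterus boundary exists (fewer than two distinct contact points).

    The enclosing lines bound the plaque *pixels as areas*: the perpendicular
    span of the pixel centers is augmented by the support of one pixel
    footprint along the chord normal, so an axis-aligned slab k pixels thick
    measures exactly k pixel-widths.
    """
    if contact_dist_mm <= 0:
        raise ValueError("contact_dist_mm must be > 0")
    uterus2d = np.asarray(uterus2d, dtype=bool)
    plaque2d = np.asarray(plaque2d, dtype=bool)
    if uterus2d.shape != plaque2d.shape:
        raise ValueError("uterus and plaque slices must share a grid")
    if not plaque2d.any() or not uterus2d.any():
        return None
    s = np.asarray(spacing2d, dtype=float)

    # Distance (mm) from every pixel to the nearest uterus pixel.
    dist_to_uterus = ndimage.distance_transform_edt(~uterus2d, sampling=s)
    contour = _contour_pixels(plaque2d)
    contact = contour[dist_to_uterus[tuple(contour.T)] <= contact_dist_mm]
    if len(contact) < 2:
        return None
    u = _contact_direction(contact * s)
    if u is None:
        return None
    n = np.array([-u[1], u[0]])

    proj = (np.argwhere(plaque2d) * s) @ n
    # One in-plane pixel of support: the enclosing lines bound pixel areas,
    # not centers.  For an axis-aligned k-pixel slab this yields exactly
    # k pixel-widths; for oblique chords the full footprint projection
    # (|n0|s0 + |n1|s1) would systematically overshoot the underlying band.
    return float(proj.max() - proj.min() + min(s))


def plaque_depth(
    organ_mask: LabelMask,
    *,
    uterus_label: str | int = "uterus",
    plaque_label: str | int = "plaque",
    contact_dist_mm: float = DEFAULT_CONTACT_DIST_MM,
) -> PlaqueMeasurement:
    """Maximum supporting-line depth over all sagittal slices, with severity.

    The slice axis is the through-plane axis (axis 2).  ``width_mm`` is the
    plaque extent parallel to the bounding lines on the deepest slice.
    """
    uterus = organ_mask.binary(uterus_label)
    if not uterus.any():
        raise ValueError("organ mask contains no uterus label")
    plaque = organ_mask.binary(plaque_label)
    s2d = organ_mask.spacing_mm[:2]
    if not plaque.any():
        return PlaqueMeasurement(0.0, None, 0.0, "none")

    best_depth, best_slice = 0.0, None
    for k in range(organ_mask.shape[2]):
        d = plaque_depth_slice(uterus[:, :, k], plaque[:, :, k], s2d, contact_dist_mm)
        if d is not None and d > best_depth:
            best_depth, best_slice = d, k
    if best_slice is None:
        return PlaqueMeasurement(0.0, None, 0.0, "none")

    width = _plaque_width(uterus[:, :, best_slice], plaque[:, :, best_slice], s2d, contact_dist_mm)
    return PlaqueMeasurement(best_depth, best_slice, width, severity_from_depth(best_depth))


def _plaque_width(
    uterus2d: np.ndarray, plaque2d: np.ndarray, spacing2d: Sequence[float], contact_dist_mm: float
) -> float:
    """Extent of the plaque parallel to the bounding lines (perpendicular width)."""
    s = np.asarray(spacing2d, dtype=float)
    dist = ndimage.distance_transform_edt(~np.asarray(uterus2d, bool), sampling=s)
    contour = _contour_pixels(np.asarray(plaque2d, bool))
    contact = contour[dist[tuple(contour.T)] <= contact_dist_mm]
    if len(contact) < 2:
        return 0.0
    u = _contact_direction(contact * s)
    if u is None:
        return 0.0
    proj = (np.argwhere(plaque2d) * s) @ u
    return float(proj.max() - proj.min() + min(s))


def fit_ellipse_axes(
    mask2d: np.ndarray, spacing2d: Sequence[float], slice_index: int = 0
) -> EllipseAxes:
    """Direct least-squares ellipse fit of the subpixel contour of a 2D mask.

    Axis lengths are the full (diameter-like) major/minor axes in mm.
    Raises ``ValueError`` on degenerate input (fewer than 5 contour points or
    a collinear contour).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.sum() < 5:
        raise ValueError("need at least 5 foreground pixels for an ellipse fit")
    s = np.asarray(spacing2d, dtype=float)
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)
    if len(contour) < 5:
        raise ValueError("need at least 5 contour points for an ellipse fit")
    pts = contour * s  # (row, col) in mm
    model = measure.EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate contour: ellipse fit failed")
    a, b = model.axis_lengths
    if not np.isfinite([a, b]).all() or min(a, b) <= 0:
        raise ValueError("degenerate contour: ellipse fit returned invalid axes")
    major, minor = 2 * max(a, b), 2 * min(a, b)
    xc, yc = model.center
    return EllipseAxes(float(major), float(minor), slice_index, (float(xc), float(yc)))


def oec_axes(oec_mask: LabelMask, *, label: str | int | None = None) -> list[EllipseAxes]:
    """Largest-area-slice ellipse axes for each cyst in the mask.

    Lesions are separated as 26-connected 3D components, ordered by voxel
    count descending.  For each, an ellipse is fitted on every axial slice
    and the slice with the largest fitted-ellipse area is reported.
    """
    fg = oec_mask.binary(label) if label is not None else oec_mask.data > 0
    if not fg.any():
        raise ValueError("empty cyst mask")
    labeled, n = ndimage.label(fg, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1

    s2d = oec_mask.spacing_mm[:2]
    results: list[EllipseAxes] = []
    for comp in order:
        comp_mask = labeled == comp
        best: EllipseAxes | None = None
        best_area = -np.inf
        for k in range(oec_mask.shape[2]):
            sl = comp_mask[:, :, k]
            if sl.sum() < 5:
                continue
            try:
                axes = fit_ellipse_axes(sl, s2d, slice_index=k)
            except ValueError:
                continue
            area = np.pi * axes.major_mm * axes.minor_mm / 4
            if area > best_area:
                best, best_area = axes, area
        if best is not None:
            results.append(best)
    if not results:
        raise ValueError("no slice of any component supported an ellipse fit")
    return results


def mask_volume(mask: LabelMask, *, label: str | int | None = None) -> float:
    """Voxel-count volume in mm^3 (count times voxel volume)."""
    fg = mask.binary(label) if label is not None else mask.data > 0
    return float(fg.sum()) * mask.voxel_volume_mm3


def volume_change(
    pre_mask: LabelMask, post_mask: LabelMask, *, label: str | int | None = None
) -> VolumeChange:
    """Pre/post voxel volumes and their difference (post minus pre)."""
    return VolumeChange(mask_volume(pre_mask, label=label), mask_volume(post_mask, label=label))
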