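"""Volumes, label masks, NIfTI I/O and the preprocessing / inference contracts.

The imaging pipeline works on two sequences resampled to a common anisotropic
grid (0.6 x 0.6 mm in-plane, 6.0 mm through-plane): a sagittal T2-weighted
stack carrying the organs and the plaque, and an axial T1-weighted stack
carrying ovarian endometriotic cysts.  This module provides the in-memory
carrier (:class:`Volume` / :class:`LabelMask`), NIfTI round-tripping, z-score
normalization, physical-extent-preserving resampling, the training-time
augmentation chain and uniform-weight sliding-window inference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Volume",
    "LabelMask",
    "AugmentationParams",
    "DegenerateVolumeError",
    "load_nifti",
    "save_nifti",
    "znormalize",
    "resample",
    "augment",
    "sliding_window_predict",
    "DEFAULT_SPACING",
    "DEFAULT_PATCH_SHAPE",
]

#: Study grid: in-plane 0.6 mm (axes 0, 1), through-plane 6.0 mm (axis 2).
DEFAULT_SPACING: tuple[float, float, float] = (0.6, 0.6, 6.0)

#: Training patch size in voxels (in-plane rows, columns, slices).
DEFAULT_PATCH_SHAPE: tuple[int, int, int] = (384, 384, 24)


class DegenerateVolumeError(ValueError):
    """Raised for inputs that defeat an operation (e.g. constant intensity)."""


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Axis convention: axis 0 = in-plane rows, axis 1 = in-plane columns,
    axis 2 = slice (through-plane) axis.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "Volume":
        return dataclasses.replace(self, data=data)

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping 0-based voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMask(Volume):
    """Integer mask aligned with a :class:`Volume`; ``labels`` names the codes."""

    labels: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label mask data must be integer-valued")
            self.data = self.data.astype(np.int16)
        self.labels = dict(self.labels)

    def binary(self, label: str | int) -> np.ndarray:
        code = self.labels[label] if isinstance(label, str) else int(label)
        return self.data == code

    def aligned_with(self, other: Volume) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


def load_nifti(path, *, as_mask: bool = False, labels: Mapping[str, int] | None = None) -> Volume:
    """Read a NIfTI volume, taking spacing from the affine column norms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in aff[:3, 3])
    if as_mask:
        return LabelMask(np.rint(data).astype(np.int16), spacing, origin, labels or {})
    return Volume(data.astype(np.float32), spacing, origin)


def save_nifti(volume: Volume, path) -> None:
    dtype = np.int16 if isinstance(volume, LabelMask) else np.float32
    img = nib.Nifti1Image(volume.data.astype(dtype), volume.affine())
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def znormalize(v: Volume) -> Volume:
    """Zero-mean, unit-SD normalization of the whole input volume."""
    data = np.asarray(v.data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        raise DegenerateVolumeError("cannot z-normalize a constant volume")
    return v.copy_with(((data - data.mean()) / sd).astype(np.float32))


def resample(
    v: Volume,
    target_spacing: Sequence[float] = DEFAULT_SPACING,
    *,
    is_mask: bool | None = None,
) -> Volume:
    """Resample to ``target_spacing``, preserving the physical extent.

    Intensities are interpolated linearly, masks nearest-neighbour.  Voxels
    are treated as cells (``grid_mode``), so an N-voxel axis of spacing s maps
    to round(N*s/t) voxels of spacing t covering the same extent.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if is_mask is None:
        is_mask = isinstance(v, LabelMask)
    if np.allclose(v.spacing_mm, target, rtol=0, atol=1e-9):
        return dataclasses.replace(v, data=v.data.copy())
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(v.shape, v.spacing_mm, target)
    )
    zoom = [ns / n for ns, n in zip(new_shape, v.shape)]
    order = 0 if is_mask else 1
    out = ndimage.zoom(
        np.asarray(v.data, dtype=v.data.dtype if is_mask else np.float32),
        zoom,
        order=order,
        mode="grid-constant",
        grid_mode=True,
        prefilter=False,
    )
    if is_mask:
        return dataclasses.replace(v, data=out.astype(v.data.dtype), spacing_mm=target)
    return dataclasses.replace(v, data=out.astype(np.float32), spacing_mm=target)


@dataclass
class AugmentationParams:
    """Training-time augmentation chain parameters.

    Defaults mirror the training recipe: random zoom in (0.9, 1.2), a random
    monotone nonlinear warp of the intensity histogram, an additive offset
    drawn from (-0.1, 0.1) of the image SD, and Gaussian noise N(0, 0.1).
    """

    zoom_range: tuple[float, float] = (0.9, 1.2)
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    noise_sd: float = 0.1
    histogram_warp_strength: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom_range low must be <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.histogram_warp_strength < 0:
            raise ValueError("histogram_warp_strength must be >= 0")


def _center_crop_or_pad(data: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = data
    for ax, target in enumerate(shape):
        n = out.shape[ax]
        if n > target:
            lo = (n - target) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(lo, lo + target)
            out = out[tuple(sl)]
        elif n < target:
            pad = [(0, 0)] * out.ndim
            lo = (target - n) // 2
            pad[ax] = (lo, target - n - lo)
            out = np.pad(out, pad, mode="edge")
    return out


def _monotone_warp(rng: np.random.Generator, strength: float) -> Callable[[np.ndarray], np.ndarray]:
    """Random monotone piecewise-cubic map of [0, 1]; identity at strength 0."""
    n_knots = 6
    x = np.linspace(0.0, 1.0, n_knots)
    # Positive random increments pulled toward uniform as strength -> 0.
    incr = rng.gamma(shape=max(1e-3, 1.0 / max(strength, 1e-12)), scale=1.0, size=n_knots - 1)
    y = np.concatenate([[0.0], np.cumsum(incr)])
    y /= y[-1]
    interp = PchipInterpolator(x, y)

    def warp(values: np.ndarray) -> np.ndarray:
        return np.asarray(interp(values))

    return warp


def augment(v: Volume, p: AugmentationParams) -> Volume:
    """Apply zoom -> monotone intensity warp -> offset -> noise, reproducibly.

    The output keeps the input grid shape (zoom is about the volume center,
    cropped or edge-padded back).  With identity parameters (zoom (1,1),
    strength 0, shift (0,0), noise 0) the input is returned unchanged.
    """
    rng = np.random.default_rng(p.seed)
    data = np.asarray(v.data, dtype=np.float32)

    zoom = float(rng.uniform(*p.zoom_range))
    if abs(zoom - 1.0) > 1e-12:
        zoomed = ndimage.zoom(data, zoom, order=1, mode="nearest", prefilter=False)
        data = _center_crop_or_pad(zoomed, v.shape).astype(np.float32)

    if p.histogram_warp_strength > 0:
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            norm = (data - lo) / (hi - lo)
            data = (_monotone_warp(rng, p.histogram_warp_strength)(norm) * (hi - lo) + lo).astype(
                np.float32
            )

    shift = float(rng.uniform(*p.intensity_shift_range)) * float(np.asarray(v.data).std())
    if shift != 0.0:
        data = data + np.float32(shift)

    if p.noise_sd > 0:
        data = data + rng.normal(0.0, p.noise_sd, size=data.shape).astype(np.float32)

    return v.copy_with(data)


def _window_starts(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, stride))
    starts.append(size - patch)  # flush to the far edge so every voxel is covered
    return sorted(set(starts))


def sliding_window_predict(
    v: Volume,
    predictor: Callable[[np.ndarray], np.ndarray],
    patch_shape: Sequence[int] = DEFAULT_PATCH_SHAPE,
    overlap: float = 0.5,
) -> np.ndarray:
    """Tile ``v`` into patches, predict each, and uniformly average overlaps.

    ``predictor`` maps a patch array of shape ``patch_shape`` to per-class
    probabilities of shape ``(C, *patch_shape)``.  Volumes smaller than the
    patch are edge-padded, predicted once, and cropped back.  Returns a
    ``(C, *v.shape)`` array whose per-voxel class probabilities sum to 1.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    patch = tuple(int(x) for x in patch_shape)
    data = np.asarray(v.data, dtype=np.float32)
    pad = [(0, max(0, p - n)) for p, n in zip(patch, data.shape)]
    padded = np.pad(data, pad, mode="edge") if any(hi for _, hi in pad) else data

    strides = tuple(max(1, int(round(p * (1 - overlap)))) for p in patch)
    starts = [_window_starts(n, p, s) for n, p, s in zip(padded.shape, patch, strides)]

    accum: np.ndarray | None = None
    counts = np.zeros(padded.shape, dtype=np.float32)
    for i0 in starts[0]:
        for i1 in starts[1]:
            for i2 in starts[2]:
                sl = (slice(i0, i0 + patch[0]), slice(i1, i1 + patch[1]), slice(i2, i2 + patch[2]))
                probs = np.asarray(predictor(padded[sl]), dtype=np.float32)
                if probs.ndim != 4 or probs.shape[1:] != patch:
                    raise ValueError(
                        f"predictor returned shape {probs.shape}, expected (C, {patch})"
                    )
                if accum is None:
                    accum = np.zeros((probs.shape[0],) + padded.shape, dtype=np.float32)
                accum[(slice(None),) + sl] += probs
                counts[sl] += 1.0
    assert accum is not None
    out = accum / counts[None]
    crop = tuple(slice(0, n) for n in data.shape)
    out = out[(slice(None),) + crop]
    # Uniform averaging of normalized predictions keeps per-voxel sums at 1;
    # renormalize to absorb float accumulation error.
    out /= np.clip(out.sum(axis=0, keepdims=True), 1e-12, None)
    return out
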