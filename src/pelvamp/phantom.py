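"""Synthetic pelvic phantoms with analytically known ground truth.

Each phantom emulates the two MR grids the pipeline consumes: a sagittal
T2-weighted stack with uterus, bladder, rectum, two ovaries and a posterior
uterine plaque, and an axial T1-weighted stack with an ovarian endometriotic
cyst (OEC).  All geometry is built from ellipsoids in physical coordinates,
so plaque depth, cyst axes and volumes are known exactly and every
downstream measurement can be validated without patient data.

Key constructions:

* The posterior uterine surface is locally flattened (a truncated
  ellipsoid), and the plaque is a constant-thickness band grown outward from
  that face.  A flat contact face makes the supporting-line depth of the
  rasterized plaque equal to the requested depth up to half an in-plane
  voxel, which is what makes the ground truth analytic.
* Adhesions at the seven pelvic locations deform the two named organs:
  each is stretched toward its partner (a direction-coded shape change) and
  the inter-organ gap is bridged by growing both organs into the connecting
  corridor (gap -> 0, local flattening, sphericity drop).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .morphometry import severity_from_depth
from .volume_io import DEFAULT_SPACING, LabelMask, Volume, save_nifti

__all__ = [
    "ORGAN_LABELS",
    "OEC_LABELS",
    "ADHESION_LOCATIONS",
    "TISSUE_INTENSITY",
    "PhantomSpec",
    "GroundTruth",
    "PhantomSample",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]

ORGAN_LABELS = {
    "uterus": 1,
    "bladder": 2,
    "rectum": 3,
    "ovary_left": 4,
    "ovary_right": 5,
    "plaque": 6,
}

OEC_LABELS = {"oec": 1}

#: The seven adhesion locations, fixed order.
ADHESION_LOCATIONS: tuple[str, ...] = (
    "left_ovary_rectum",
    "right_ovary_rectum",
    "left_right_ovary",
    "uterus_left_ovary",
    "uterus_right_ovary",
    "uterus_rectum",
    "uterus_bladder",
)

_LOCATION_PAIRS: dict[str, tuple[str, str]] = {
    "left_ovary_rectum": ("ovary_left", "rectum"),
    "right_ovary_rectum": ("ovary_right", "rectum"),
    "left_right_ovary": ("ovary_left", "ovary_right"),
    "uterus_left_ovary": ("uterus", "ovary_left"),
    "uterus_right_ovary": ("uterus", "ovary_right"),
    "uterus_rectum": ("uterus", "rectum"),
    "uterus_bladder": ("uterus", "bladder"),
}

#: Per-tissue mean intensity on a 0-1 scale (T2 grid unless noted).  The
#: source protocols publish no tissue contrast, so these are fixed package
#: conventions: fluid-filled bladder bright on T2, fibrotic plaque dark,
#: blood-filled cyst bright on T1.
TISSUE_INTENSITY = {
    "background": 0.12,
    "uterus": 0.60,
    "bladder": 0.90,
    "rectum": 0.45,
    "ovary_left": 0.70,
    "ovary_right": 0.70,
    "plaque": 0.35,
    "t1_background": 0.15,
    "oec": 0.85,
}

#: Stretch factor applied to each organ of a flagged pair (along the
#: pair axis) and the half-width (mm) of the gap-bridging corridor.
ADHESION_STRETCH = 0.18
ADHESION_BRIDGE_PAD_MM = 3.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class PhantomGeometryError(ValueError):
    """Raised when a spec would produce overlapping or clipped organs."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom; geometry is derived from the grid extent."""

    image_shape: tuple[int, int, int] = (128, 128, 16)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    plaque_depth_mm: float = 0.0
    oec_axes_mm: tuple[float, float] | None = None
    adhesion_flags: tuple[bool, ...] = (False,) * 7
    noise_sd: float = 0.05
    seed: int = 0
    t1_shape: tuple[int, int, int] = (96, 96, 12)
    jitter: float = 1.0  # scale of random size/position perturbation

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.plaque_depth_mm < 0:
            raise ValueError("plaque_depth_mm must be >= 0")
        if len(self.adhesion_flags) != len(ADHESION_LOCATIONS):
            raise ValueError(f"adhesion_flags must have {len(ADHESION_LOCATIONS)} entries")
        if self.oec_axes_mm is not None:
            major, minor = self.oec_axes_mm
            if not major >= minor > 0:
                raise ValueError("oec axes must satisfy major >= minor > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    plaque_depth_mm: float
    severity: str
    oec_axes_mm: tuple[float, float] | None
    oec_volume_mm3: float
    adhesions: dict[str, bool]


@dataclass(frozen=True)
class PhantomSample:
    t2_volume: Volume
    t1_volume: Volume
    organ_mask: LabelMask
    oec_mask: LabelMask
    truth: GroundTruth
    patient_id: str = "P0000"


@dataclass
class _Organ:
    name: str
    center: np.ndarray  # mm
    semi_axes: np.ndarray  # mm
    truncate_x0: float | None = None  # keep x0 <= this plane (mm)
    stretches: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def radius2(self, coords: np.ndarray) -> np.ndarray:
        """Squared normalized ellipsoid coordinate of (..., 3) physical points."""
        x = coords - self.center
        for u, delta in self.stretches:
            # Inverse of I + delta*u*u^T applied to the offset.
            x = x - (delta / (1.0 + delta)) * (x @ u)[..., None] * u
        return ((x / self.semi_axes) ** 2).sum(axis=-1)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Membership test for an (..., 3) array of physical points."""
        inside = self.radius2(coords) <= 1.0
        if self.truncate_x0 is not None:
            inside &= coords[..., 0] <= self.truncate_x0
        return inside


def _voxel_centers(shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def _layout(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, _Organ]:
    """Organ geometry as fractions of the grid extent, with mm caps and jitter."""
    H = np.array([n * s for n, s in zip(spec.image_shape, spec.spacing_mm)])
    j = spec.jitter

    def jpos(scale: float = 1.0) -> np.ndarray:
        return rng.uniform(-1, 1, size=3) * np.array([0.6, 1.5, 1.5]) * scale * j

    def jsize() -> np.ndarray:
        return 1.0 + rng.uniform(-0.05, 0.05, size=3) * j

    uterus_sa = np.array([0.09 * H[0], 0.15 * H[1], min(0.15 * H[2], 16.0)]) * jsize()
    uterus_c = np.array([0.34 * H[0], 0.50 * H[1], 0.50 * H[2]]) + jpos()
    uterus = _Organ("uterus", uterus_c, uterus_sa, truncate_x0=uterus_c[0] + 0.75 * uterus_sa[0])

    bladder = _Organ(
        "bladder",
        np.array([0.15 * H[0], 0.50 * H[1], 0.50 * H[2]]) + jpos(),
        np.array([0.055 * H[0], 0.12 * H[1], min(0.12 * H[2], 13.0)]) * jsize(),
    )
    rectum = _Organ(
        "rectum",
        np.array([0.68 * H[0], 0.50 * H[1], 0.50 * H[2]]) + jpos(),
        np.array([0.05 * H[0], 0.30 * H[1], max(6.5, 0.05 * H[0])]) * jsize(),
    )
    ovary_sa = np.array([0.05 * H[0], 0.07 * H[1], min(0.11 * H[2], 8.0)])
    dz = 0.17 * H[2]
    ovaries = {
        side: _Organ(
            f"ovary_{side}",
            np.array([0.45 * H[0], 0.50 * H[1] + sy * 0.19 * H[1], 0.50 * H[2] + sz * dz])
            + jpos(0.5),
            ovary_sa * jsize(),
        )
        for side, sy, sz in (("left", -1, -1), ("right", 1, 1))
    }
    return {
        "uterus": uterus,
        "bladder": bladder,
        "rectum": rectum,
        "ovary_left": ovaries["left"],
        "ovary_right": ovaries["right"],
    }


def _grow_plaque(
    uterus3d: np.ndarray, organs: dict[str, _Organ], spec: PhantomSpec
) -> np.ndarray:
    """Constant-thickness band outward from the flat posterior uterine face.

    Pixels whose center lies within the band (nearest-uterus distance up to
    depth + half an in-plane voxel) are included, so the rasterized band is
    the best voxel approximation of the analytic slab; any nonzero depth
    keeps at least the first pixel ring.
    """
    t = spec.plaque_depth_mm
    plaque = np.zeros_like(uterus3d)
    if t <= 0:
        return plaque
    s0, s1 = spec.spacing_mm[:2]
    uterus = organs["uterus"]
    i_face = int(np.floor(uterus.truncate_x0 / s0))
    thresh = max(t + s0 / 2, s0 * 1.01)
    for k in range(uterus3d.shape[2]):
        sl = uterus3d[:, :, k]
        if not sl.any():
            continue
        rows = np.argwhere(sl)
        if rows[:, 0].max() != i_face:  # slice does not reach the flat face
            continue
        face_cols = rows[rows[:, 0] == i_face][:, 1]
        half_width = 0.55 * (face_cols.max() - face_cols.min()) / 2 * s1
        if half_width < 3 * s1:
            continue
        c1 = (face_cols.max() + face_cols.min()) / 2 * s1
        dist = ndimage.distance_transform_edt(~sl, sampling=(s0, s1))
        ii, jj = np.meshgrid(
            np.arange(sl.shape[0]) * s0, np.arange(sl.shape[1]) * s1, indexing="ij"
        )
        band = (~sl) & (dist <= thresh) & (ii > uterus.truncate_x0) & (np.abs(jj - c1) <= half_width)
        plaque[:, :, k] = band
    if t > 0 and not plaque.any():
        raise PhantomGeometryError("plaque band could not be placed on any slice")
    return plaque


def _bridge_pair(
    masks: dict[str, np.ndarray], name_a: str, name_b: str, spacing: Sequence[float]
) -> None:
    """Grow both organs into the corridor between them until they meet.

    The corridor keeps a margin around the plaque band so the plaque-uterus
    contact surface (the depth measurement's anchor) stays untouched.
    """
    a, b = masks[name_a], masks[name_b]
    occupied = np.zeros_like(a)
    for name, m in masks.items():
        if name == "plaque" and m.any():
            guard = ndimage.binary_dilation(m, structure=np.ones((7, 7, 1), dtype=bool))
            occupied |= guard
        else:
            occupied |= m
    da = ndimage.distance_transform_edt(~a, sampling=spacing)
    db = ndimage.distance_transform_edt(~b, sampling=spacing)
    free = ~occupied
    if not free.any():
        return
    gap = float((da + db)[free].min())
    lens = free & (da + db <= gap + ADHESION_BRIDGE_PAD_MM)
    masks[name_a] = a | (lens & (da <= db))
    masks[name_b] = b | (lens & (da > db))


def _render_intensity(
    label_data: np.ndarray,
    label_names: dict[str, int],
    background: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(label_data.shape, background, dtype=np.float32)
    for name, code in label_names.items():
        img[label_data == code] = TISSUE_INTENSITY[name]
    img = ndimage.gaussian_filter(img, sigma=(0.4, 0.4, 0.0))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return img.astype(np.float32)


def _rasterize_oec(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    data = np.zeros(spec.t1_shape, dtype=bool)
    if spec.oec_axes_mm is None:
        return data
    major, minor = spec.oec_axes_mm
    s = spec.spacing_mm
    H = np.array([n * c for n, c in zip(spec.t1_shape, s)])
    k_mid = spec.t1_shape[2] // 2
    center = np.array([0.5 * H[0], 0.5 * H[1], k_mid * s[2]])
    # Through-plane semi-axis tracks the minor axis (roughly prolate cysts),
    # so scaling all axes by f^(1/3) scales the volume by f.
    semi = np.array([major / 2, minor / 2, min(minor / 2, 0.45 * H[2])])
    if semi[0] * 2 > 0.9 * H[0] or semi[1] * 2 > 0.9 * H[1]:
        raise PhantomGeometryError("cyst axes do not fit the T1 grid")
    theta = rng.uniform(0, np.pi)
    c, si = np.cos(theta), np.sin(theta)
    coords = _voxel_centers(spec.t1_shape, s) - center
    x0 = c * coords[..., 0] + si * coords[..., 1]
    x1 = -si * coords[..., 0] + c * coords[..., 1]
    return (x0 / semi[0]) ** 2 + (x1 / semi[1]) ** 2 + (coords[..., 2] / semi[2]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, patient_id: str = "P0000") -> PhantomSample:
    """Build one phantom sample with self-consistent ground truth.

    Raises :class:`PhantomGeometryError` if the requested geometry would
    clip the grid or make organs overlap.
    """
    rng = np.random.default_rng(spec.seed)
    organs = _layout(spec, rng)

    # Adhesion stretch: elongate each organ of a flagged pair toward its partner.
    for loc, flagged in zip(ADHESION_LOCATIONS, spec.adhesion_flags):
        if not flagged:
            continue
        na, nb = _LOCATION_PAIRS[loc]
        u = organs[nb].center - organs[na].center
        u = u / np.linalg.norm(u)
        organs[na].stretches.append((u, ADHESION_STRETCH))
        organs[nb].stretches.append((u, ADHESION_STRETCH))

    coords = _voxel_centers(spec.image_shape, spec.spacing_mm)
    masks = {name: org.contains(coords) for name, org in organs.items()}

    # A flagged pair stretched into contact may overlap; contested voxels go
    # to the organ whose normalized ellipsoid coordinate is smaller, which
    # flattens the contact interface (the deformation adhesions produce).
    flagged_pairs = [
        _LOCATION_PAIRS[loc]
        for loc, on in zip(ADHESION_LOCATIONS, spec.adhesion_flags)
        if on
    ]
    for na, nb in flagged_pairs:
        overlap = masks[na] & masks[nb]
        if overlap.any():
            closer_a = organs[na].radius2(coords) <= organs[nb].radius2(coords)
            masks[na] &= ~overlap | closer_a
            masks[nb] &= ~overlap | ~closer_a

    # Geometry validation: organs must not clip the grid nor overlap.
    for name, m in masks.items():
        if m.sum() < 20:
            raise PhantomGeometryError(f"{name} is too small on this grid ({int(m.sum())} voxels)")
        if m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any():
            raise PhantomGeometryError(f"{name} clips the in-plane grid boundary")
    names = list(masks)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            if (masks[na] & masks[nb]).any():
                raise PhantomGeometryError(f"organs {na} and {nb} overlap; reduce sizes or jitter")

    plaque = _grow_plaque(masks["uterus"], organs, spec)
    # The band grows into free space only; organs deformed toward the
    # posterior compartment may shave its lateral margins.
    for m in masks.values():
        plaque &= ~m
    if spec.plaque_depth_mm > 0 and not plaque.any():
        raise PhantomGeometryError("no free space left for the plaque band")

    # Gap bridging for flagged pairs, in fixed location order.
    masks["plaque"] = plaque
    for loc, flagged in zip(ADHESION_LOCATIONS, spec.adhesion_flags):
        if flagged:
            _bridge_pair(masks, *_LOCATION_PAIRS[loc], spec.spacing_mm)
    plaque = masks.pop("plaque")

    label_data = np.zeros(spec.image_shape, dtype=np.int16)
    for name, code in ORGAN_LABELS.items():
        if name == "plaque":
            label_data[plaque] = code
        else:
            label_data[masks[name]] = code
    organ_mask = LabelMask(label_data, spec.spacing_mm, labels=ORGAN_LABELS)

    oec = _rasterize_oec(spec, rng)
    oec_mask = LabelMask(oec.astype(np.int16), spec.spacing_mm, labels=OEC_LABELS)

    t2 = Volume(
        _render_intensity(label_data, {k: v for k, v in ORGAN_LABELS.items()},
                          TISSUE_INTENSITY["background"], spec.noise_sd, rng),
        spec.spacing_mm,
    )
    t1 = Volume(
        _render_intensity(oec_mask.data, OEC_LABELS, TISSUE_INTENSITY["t1_background"],
                          spec.noise_sd, rng),
        spec.spacing_mm,
    )

    truth = GroundTruth(
        plaque_depth_mm=float(spec.plaque_depth_mm),
        severity=severity_from_depth(spec.plaque_depth_mm),
        oec_axes_mm=spec.oec_axes_mm,
        oec_volume_mm3=float(oec.sum()) * float(np.prod(spec.spacing_mm)),
        adhesions=dict(zip(ADHESION_LOCATIONS, map(bool, spec.adhesion_flags))),
    )
    return PhantomSample(t2, t1, organ_mask, oec_mask, truth, patient_id)


#: Per-location adhesion prevalence for cohort sampling, matching the
#: positive-sample fractions reported for the clinical cohort (38%, 37%,
#: 16%, 73%, 66%, 62%, 6% in the fixed location order).
DEFAULT_PREVALENCE: tuple[float, ...] = (0.38, 0.37, 0.16, 0.73, 0.66, 0.62, 0.06)


def generate_cohort(
    n: int,
    seed: int = 0,
    prevalence: Sequence[float] = DEFAULT_PREVALENCE,
    *,
    image_shape: tuple[int, int, int] = (128, 128, 16),
    t1_shape: tuple[int, int, int] = (96, 96, 12),
    depth_range_mm: tuple[float, float] = (0.6, 12.0),
    plaque_prob: float = 0.7,
    oec_prob: float = 0.8,
    pair_fraction: float = 0.2,
    noise_sd: float = 0.05,
) -> list[PhantomSample]:
    """Sample ``n`` phantoms; some patients contribute pre/post pairs.

    Adhesion labels are Bernoulli(prevalence) per location, drawn per
    patient.  A ``pair_fraction`` of patients with a cyst contribute two
    samples (the post-surgery cyst volume is shrunk by a random factor in
    [0.1, 0.9]).  Fully reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prevalence = tuple(float(p) for p in prevalence)
    if len(prevalence) != len(ADHESION_LOCATIONS) or any(not 0 <= p <= 1 for p in prevalence):
        raise ValueError("prevalence must be 7 floats in [0, 1]")
    rng = np.random.default_rng(seed)
    max_depth = _max_feasible_depth(image_shape, DEFAULT_SPACING)
    depth_range = (depth_range_mm[0], min(depth_range_mm[1], max_depth))

    samples: list[PhantomSample] = []
    patient = 0
    while len(samples) < n:
        patient += 1
        pid = f"P{patient:04d}"
        flags = tuple(bool(rng.random() < p) for p in prevalence)
        depth = float(rng.uniform(*depth_range)) if rng.random() < plaque_prob else 0.0
        if rng.random() < oec_prob:
            # Clinically typical cysts are ~2.5-4.5 cm; cap to the T1 grid.
            hi = min(44.0, 0.8 * min(t1_shape[0] * DEFAULT_SPACING[0],
                                     t1_shape[1] * DEFAULT_SPACING[1]))
            lo = min(24.0, 0.6 * hi)
            major = float(rng.uniform(lo, hi))
            minor = float(rng.uniform(max(12.0, 0.5 * major), 0.92 * major))
            oec: tuple[float, float] | None = (major, minor)
        else:
            oec = None
        spec = PhantomSpec(
            image_shape=image_shape,
            plaque_depth_mm=depth,
            oec_axes_mm=oec,
            adhesion_flags=flags,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            t1_shape=t1_shape,
        )
        samples.append(generate_phantom(spec, patient_id=pid))
        paired = oec is not None and rng.random() < pair_fraction
        if paired and len(samples) < n:
            shrink = float(rng.uniform(0.1, 0.9))  # volume factor
            scale = shrink ** (1 / 3)
            post_spec = dataclasses.replace(
                spec,
                oec_axes_mm=(oec[0] * scale, oec[1] * scale),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            samples.append(generate_phantom(post_spec, patient_id=pid))
    return samples


def _max_feasible_depth(shape: Sequence[int], spacing: Sequence[float]) -> float:
    """Largest plaque depth that keeps clear of the rectum on this grid."""
    H0 = shape[0] * spacing[0]
    face = 0.34 * H0 + 0.75 * 0.09 * H0
    rectum_anterior = 0.68 * H0 - 0.05 * H0
    return max(0.0, rectum_anterior - face - 3.0)  # 3 mm clearance incl. jitter


def write_cohort(samples: Sequence[PhantomSample], out_dir) -> None:
    """Write NIfTI volume/mask pairs and a ground-truth CSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        stem = f"{s.patient_id}_{i:04d}"
        save_nifti(s.t2_volume, out / f"{stem}_t2.nii.gz")
        save_nifti(s.t1_volume, out / f"{stem}_t1.nii.gz")
        save_nifti(s.organ_mask, out / f"{stem}_organs.nii.gz")
        save_nifti(s.oec_mask, out / f"{stem}_oec.nii.gz")
        row = {
            "sample": stem,
            "patient_id": s.patient_id,
            "plaque_depth_mm": s.truth.plaque_depth_mm,
            "severity": s.truth.severity,
            "oec_major_mm": s.truth.oec_axes_mm[0] if s.truth.oec_axes_mm else "",
            "oec_minor_mm": s.truth.oec_axes_mm[1] if s.truth.oec_axes_mm else "",
            "oec_volume_mm3": s.truth.oec_volume_mm3,
        }
        row.update({f"adhesion_{k}": int(v) for k, v in s.truth.adhesions.items()})
        rows.append(row)
    with open(out / "truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
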