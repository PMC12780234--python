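import numpy as np
import pytest
from scipy import ndimage

from pelvamp.shape_radiomics import (
    FEATURE_NAMES,
    DegenerateMaskError,
    FeatureVector56,
    feature_vector,
    mesh_surface,
    principal_axes,
    shape_features,
)
from pelvamp.volume_io import LabelMask

from conftest import digitized_ball, digitized_ellipsoid, rotation_matrix


def random_blob(seed: int, spacing=(0.6, 0.6, 2.0)) -> LabelMask:
    """A smooth random single-component blob: thresholded filtered noise + ellipsoid."""
    rng = np.random.default_rng(seed)
    shape = (48, 48, 24)
    base = digitized_ellipsoid(rng.uniform(6, 12, size=3), spacing=spacing, margin=4).data
    base = np.pad(base, [(0, max(0, s - b)) for s, b in zip(shape, base.shape)])[
        : shape[0], : shape[1], : shape[2]
    ].astype(bool)
    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=(4, 4, 2))
    blob = base | (noise > np.quantile(noise, 0.93))
    labeled, n = ndimage.label(blob, structure=np.ones((3, 3, 3), bool))
    sizes = ndimage.sum_labels(np.ones(shape), labeled, index=range(1, n + 1))
    keep = labeled == (1 + np.argmax(sizes))
    return LabelMask(keep.astype(np.int16), spacing, labels={"fg": 1})


def oracle_features(mask: LabelMask) -> dict:
    """Independent brute-force recomputation of all 14 descriptors.

    Mesh measures go through trimesh (independent area/volume code on the
    same half-level isosurface); diameters are direct O(n^2) pairwise scans
    without convex-hull acceleration; eigenvalues come from the explicit
    scatter matrix rather than np.cov.
    """
    import trimesh
    from skimage import measure as skmeasure

    fg = mask.data > 0
    spacing = np.asarray(mask.spacing_mm)

    padded = np.pad(fg, 1).astype(np.float32)
    sigma = [0.8 / s for s in spacing]
    smoothed = ndimage.gaussian_filter(padded, sigma, mode="constant")
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = skmeasure.marching_cubes(smoothed, 0.5, spacing=tuple(spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    area, volume = float(mesh.area), float(abs(mesh.volume))

    coords = np.argwhere(fg).astype(float) * spacing
    centered = coords - coords.mean(axis=0)
    scatter = centered.T @ centered / (len(coords) - 1)
    vals = np.sort(np.linalg.eigvalsh(scatter))[::-1]

    eroded = ndimage.binary_erosion(fg, structure=np.ones((3, 3, 3), bool))
    bidx = np.argwhere(fg & ~eroded)
    bpts = bidx * spacing

    def brute_max(points):
        best = 0.0
        for i in range(len(points)):
            d = np.linalg.norm(points[i + 1 :] - points[i], axis=1)
            if len(d):
                best = max(best, float(d.max()))
        return best

    def brute_max_2d(axis):
        keep = [a for a in range(3) if a != axis]
        best = 0.0
        for idx in np.unique(bidx[:, axis]):
            best = max(best, brute_max(bpts[bidx[:, axis] == idx][:, keep]))
        return best

    return {
        "elongation": np.sqrt(vals[1] / vals[0]),
        "flatness": np.sqrt(vals[2] / vals[0]),
        "sphericity": (36 * np.pi * volume**2) ** (1 / 3) / area,
        "major_axis_mm": 4 * np.sqrt(vals[0]),
        "minor_axis_mm": 4 * np.sqrt(vals[1]),
        "least_axis_mm": 4 * np.sqrt(vals[2]),
        "max2d_row_mm": brute_max_2d(0),
        "max2d_col_mm": brute_max_2d(1),
        "max2d_slice_mm": brute_max_2d(2),
        "max3d_mm": brute_max(bpts),
        "mesh_volume_mm3": volume,
        "voxel_volume_mm3": float(fg.sum()) * float(np.prod(spacing)),
        "surface_area_mm2": area,
        "surface_volume_ratio": area / volume,
    }


class TestPrincipalAxes:
    def test_ball_is_isotropic(self):
        vals, _ = principal_axes(digitized_ball(12.0))
        assert np.sqrt(vals[1] / vals[0]) == pytest.approx(1.0, abs=0.02)
        assert np.sqrt(vals[2] / vals[0]) == pytest.approx(1.0, abs=0.02)

    def test_ellipsoid_axis_ratios(self):
        vals, _ = principal_axes(digitized_ellipsoid((30.0, 15.0, 7.5), margin=3))
        lengths = 4 * np.sqrt(vals)
        assert lengths[0] / lengths[1] == pytest.approx(2.0, rel=0.03)
        assert lengths[0] / lengths[2] == pytest.approx(4.0, rel=0.03)

    def test_rotation_leaves_eigenvalues_unchanged(self):
        plain = digitized_ellipsoid((18.0, 9.0, 6.0), margin=4)
        rot = digitized_ellipsoid((18.0, 9.0, 6.0), margin=4,
                                  rotation=rotation_matrix(2, np.pi / 5))
        v1, _ = principal_axes(plain)
        v2, _ = principal_axes(rot)
        assert np.allclose(v1, v2, rtol=0.01)

    def test_degenerate_mask_rejected(self):
        flat = np.zeros((8, 8, 3), dtype=np.int16)
        flat[2:6, 2:6, 1] = 1  # coplanar
        with pytest.raises(DegenerateMaskError):
            principal_axes(LabelMask(flat, (0.6, 0.6, 6.0)))


class TestMeshSurface:
    def test_ball_area_and_volume_analytic(self):
        area, volume = mesh_surface(digitized_ball(12.0))
        assert area == pytest.approx(4 * np.pi * 144, rel=0.03)
        assert volume == pytest.approx(4 / 3 * np.pi * 1728, rel=0.03)

    def test_single_voxel_meshes_to_face_midpoint_octahedron(self):
        data = np.zeros((5, 5, 5), dtype=np.int16)
        data[2, 2, 2] = 1
        m = LabelMask(data, (1.0, 1.0, 1.0))
        area, volume = mesh_surface(m, smoothing_mm=0.0)
        # Octahedron through the voxel face midpoints: V = 4abc/3 with
        # a=b=c=1/2, A = 8 * (sqrt(3)/4) * (sqrt(2)/2)^2.
        assert volume == pytest.approx(4 / 3 * 0.125, rel=1e-6)
        assert area == pytest.approx(np.sqrt(3), rel=1e-6)

    def test_translation_invariance(self):
        data = np.zeros((30, 30, 10), dtype=np.int16)
        data[4:12, 5:14, 2:6] = 1
        shifted = np.roll(data, (6, 5, 2), axis=(0, 1, 2))
        m1 = LabelMask(data, (0.6, 0.6, 2.0))
        m2 = LabelMask(shifted, (0.6, 0.6, 2.0))
        assert mesh_surface(m1) == pytest.approx(mesh_surface(m2), rel=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateMaskError):
            mesh_surface(LabelMask(np.zeros((4, 4, 4), dtype=np.int16)))


class TestShapeFeatures:
    def test_ball_maximizes_sphericity(self):
        f = shape_features(digitized_ball(12.0))
        assert f.sphericity >= 0.98
        assert f.sphericity <= 1.02

    def test_slice_axis_rod_is_extreme(self):
        """A thin slice-axis rod: tiny axis ratios, max3d ~ its length.

        Elongation and flatness shrink toward 0 for a rod (the standard
        ratio convention: smaller means more rod-like); a strictly
        single-voxel cross-section is degenerate and rejected instead.
        """
        data = np.zeros((8, 8, 16), dtype=np.int16)
        data[3:5, 3:5, 2:14] = 1  # 12 slices tall, 2x2 voxels wide
        f = shape_features(LabelMask(data, (0.6, 0.6, 6.0)))
        assert f.flatness <= f.elongation < 0.05
        expected = np.sqrt((11 * 6.0) ** 2 + 2 * 0.6**2)
        assert f.max3d_mm == pytest.approx(expected, rel=0.01)

        line = np.zeros((7, 7, 16), dtype=np.int16)
        line[3, 3, 2:14] = 1
        with pytest.raises(DegenerateMaskError):
            shape_features(LabelMask(line, (0.6, 0.6, 6.0)))

    def test_invariants_on_random_blobs(self):
        for seed in range(5):
            f = shape_features(random_blob(seed))
            assert 0 < f.flatness <= f.elongation <= 1
            assert 0 < f.sphericity <= 1.02
            assert f.major_axis_mm >= f.minor_axis_mm >= f.least_axis_mm
            assert f.max3d_mm >= max(f.max2d_row_mm, f.max2d_col_mm, f.max2d_slice_mm)
            assert f.mesh_volume_mm3 > 0 and f.surface_area_mm2 > 0
            assert f.surface_volume_ratio == pytest.approx(
                f.surface_area_mm2 / f.mesh_volume_mm3
            )

    def test_mesh_and_voxel_volume_agree_for_smooth_blobs(self):
        f = shape_features(digitized_ball(12.0))
        assert f.mesh_volume_mm3 == pytest.approx(f.voxel_volume_mm3, rel=0.05)

    def test_matches_brute_force_oracle_on_random_blobs(self):
        """Dual-route check of all 14 descriptors on 20 random blobs."""
        for seed in range(20):
            mask = random_blob(seed)
            f = shape_features(mask)
            expected = oracle_features(mask)
            for name in FEATURE_NAMES:
                assert getattr(f, name) == pytest.approx(expected[name], rel=0.01), (
                    f"{name} mismatch on blob {seed}"
                )

    def test_rotation_invariance_within_digitization_tolerance(self):
        plain = shape_features(digitized_ellipsoid((15.0, 10.0, 8.0), margin=4))
        rotated = shape_features(
            digitized_ellipsoid((15.0, 10.0, 8.0), margin=4,
                                rotation=rotation_matrix(2, np.pi / 2))
        )
        for name in ("sphericity", "surface_area_mm2", "mesh_volume_mm3",
                     "major_axis_mm", "minor_axis_mm", "least_axis_mm", "max3d_mm"):
            assert getattr(plain, name) == pytest.approx(getattr(rotated, name), rel=0.02)


class TestFeatureVector:
    def test_phantom_gives_56_finite_values(self, small_phantom):
        fv = feature_vector(small_phantom.organ_mask)
        assert fv.values.shape == (56,)
        assert np.isfinite(fv.values).all()
        assert fv.missing == ()

    def test_deterministic(self, small_phantom):
        a = feature_vector(small_phantom.organ_mask)
        b = feature_vector(small_phantom.organ_mask)
        assert np.array_equal(a.values, b.values)

    def test_isotropic_scaling_laws(self):
        small = shape_features(digitized_ball(8.0))
        big = shape_features(digitized_ball(16.0))
        assert big.mesh_volume_mm3 / small.mesh_volume_mm3 == pytest.approx(8.0, rel=0.05)
        assert big.surface_area_mm2 / small.surface_area_mm2 == pytest.approx(4.0, rel=0.05)
        assert big.sphericity == pytest.approx(small.sphericity, rel=0.02)

    def test_missing_organ_flagged_with_nans(self, small_phantom):
        data = small_phantom.organ_mask.data.copy()
        data[data == small_phantom.organ_mask.labels["bladder"]] = 0
        mask = LabelMask(data, small_phantom.organ_mask.spacing_mm,
                         labels=small_phantom.organ_mask.labels)
        fv = feature_vector(mask)
        assert "bladder" in fv.missing
        cols = FeatureVector56.column_names()
        bladder_idx = [i for i, c in enumerate(cols) if c.startswith("bladder__")]
        assert np.isnan(fv.values[bladder_idx]).all()
        other_idx = [i for i, c in enumerate(cols) if not c.startswith("bladder__")]
        assert np.isfinite(fv.values[other_idx]).all()
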