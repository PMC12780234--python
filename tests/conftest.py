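import numpy as np
import pytest

from pelvamp.phantom import PhantomSpec, generate_phantom
from pelvamp.volume_io import LabelMask


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64x12 phantom with a 4 mm plaque and a 30x20 mm cyst."""
    spec = PhantomSpec(
        image_shape=(64, 64, 12), t1_shape=(64, 64, 12),
        plaque_depth_mm=4.0, oec_axes_mm=(30.0, 20.0), seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-grid phantom with a severe (7.2 mm) plaque."""
    spec = PhantomSpec(plaque_depth_mm=7.2, oec_axes_mm=(40.0, 25.0), seed=11)
    return generate_phantom(spec)


def digitized_ball(radius_mm: float, spacing=(0.6, 0.6, 0.6), margin: int = 5) -> LabelMask:
    """Rasterized ball centered on the grid, as a binary LabelMask."""
    shape = tuple(int(2 * radius_mm / s) + 2 * margin for s in spacing)
    center = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])
    grid = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    )
    fg = ((grid - center) ** 2).sum(-1) <= radius_mm**2
    return LabelMask(fg.astype(np.int16), spacing, labels={"fg": 1})


def digitized_ellipsoid(semi_axes_mm, spacing=(0.6, 0.6, 0.6), margin: int = 5,
                        rotation=None) -> LabelMask:
    """Rasterized (optionally rotated) ellipsoid as a binary LabelMask."""
    semi = np.asarray(semi_axes_mm, float)
    extent = semi.max() if rotation is not None else semi
    shape = tuple(int(2 * e / s) + 2 * margin
                  for e, s in zip(np.broadcast_to(extent, (3,)), spacing))
    center = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])
    grid = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    ) - center
    if rotation is not None:
        grid = grid @ np.asarray(rotation).T
    fg = ((grid / semi) ** 2).sum(-1) <= 1.0
    return LabelMask(fg.astype(np.int16), spacing, labels={"fg": 1})


def rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == 2:
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    if axis == 1:
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
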