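import numpy as np
import pytest
from skimage.measure import label as cc_label

import lcnpipe as lp


@pytest.fixture(scope="session")
def micro_phantom():
    """Default micro-scale phantom (64³ @ 2 µm, ~170 lacunae, 2 canals)."""
    return lp.generate_phantom(lp.microct_spec(seed=11))


@pytest.fixture(scope="session")
def nano_phantom():
    """Default nano-scale phantom (120³ @ 0.3 µm, 5 lacunae + canaliculi)."""
    return lp.generate_phantom(lp.txm_spec(seed=7))


@pytest.fixture(scope="session")
def nano_split(nano_phantom):
    """Segmented + split LCN of the nano phantom with labelled lacunae."""
    gray, truth = nano_phantom
    mask = lp.segment_lcn(gray, threshold=125, polarity="dark")
    lacunae, canaliculi = lp.split_lcn(mask, open_radius=3)
    labelled = cc_label(lacunae, connectivity=3)
    return mask, lacunae, canaliculi, labelled


def make_tube(p0, p1, radius, shape):
    """Voxels within `radius` of the segment p0-p1 (voxel coordinates)."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    v = p1 - p0
    t = np.clip((pts - p0) @ v / (v @ v), 0.0, 1.0)
    nearest = p0 + t[..., None] * v
    return np.linalg.norm(pts - nearest, axis=-1) <= radius


def make_ellipsoid(semiaxes, shape=None, center=None, spacing=1.0):
    """Axis-aligned digitized ellipsoid; semiaxes in physical units."""
    semi = np.asarray(semiaxes, float)
    if shape is None:
        half = int(np.ceil(semi.max() / spacing)) + 2
        shape = (2 * half + 1,) * 3
        center = (half, half, half)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d = np.stack([(zz - center[0]), (yy - center[1]), (xx - center[2])], axis=-1) * spacing
    return (np.square(d / semi).sum(axis=-1)) <= 1.0
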