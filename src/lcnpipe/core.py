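"""Core voxel-volume containers and morphology primitives.

All volumes are dense numpy arrays in (z, y, x) axis order with isotropic
physical spacing in micrometres.  Lengths elsewhere in the package are in
micrometres unless a function documents otherwise (the Darcy solver works
in SI internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

# Canonical semantic labels used by the phantom generator and pipelines.
BACKGROUND = 0
BONE = 1
LACUNA = 2
CANALICULUS = 3
VASCULAR = 4
IMPLANT = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    BONE: "bone",
    LACUNA: "lacuna",
    CANALICULUS: "canaliculus",
    VASCULAR: "vascular",
    IMPLANT: "implant",
}


@dataclass
class Volume3D:
    """A 3D scalar voxel grid with isotropic spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values; grayscale (float) or binary (bool).
    spacing : float
        Edge length of a voxel in micrometres; must be > 0.
    """

    data: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        return float(self.spacing) ** 3

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size along (z, y, x) in µm."""
        return np.asarray(self.shape) * self.spacing

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume(Volume3D):
    """Integer-labelled :class:`Volume3D` with a label-semantics map."""

    semantics: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.data)]


def binned_spacing(native_spacing: float, factor: int) -> float:
    """Voxel size after binning: the native spacing times the binning factor."""
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    return native_spacing * factor


def bin_volume(volume: Volume3D, factor: int) -> Volume3D:
    """Downsample a grayscale volume by block averaging.

    Each output voxel is the mean of a ``factor³`` block; the spacing grows by
    the same factor (e.g. binning 22.8 nm data by two yields 45.6 nm voxels).
    Trailing voxels that do not fill a complete block are dropped.
    """
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return volume.copy()
    nz, ny, nx = (s - s % factor for s in volume.shape)
    d = volume.data[:nz, :ny, :nx].astype(float)
    d = d.reshape(nz // factor, factor, ny // factor, factor, nx // factor, factor)
    return Volume3D(d.mean(axis=(1, 3, 5)), binned_spacing(volume.spacing, factor))


# ---------------------------------------------------------------------------
# Euclidean-ball morphology via exact distance transforms.
#
# For the ball structuring element B(r) = {d : |d| <= r} (voxel-centre
# distances, identical to skimage.morphology.ball), dilation and erosion
# reduce to thresholded Euclidean distance transforms, which is exact and
# much faster than structuring-element convolution for large r.
# ---------------------------------------------------------------------------


def ball_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary dilation by a Euclidean ball of the given radius (voxels)."""
    mask = np.asarray(mask, bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    dist_to_fg = ndi.distance_transform_edt(~mask)
    return dist_to_fg <= radius


def ball_erosion(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary erosion by a Euclidean ball of the given radius (voxels).

    Voxels outside the array are treated as background, matching the usual
    padded-with-zeros convention.
    """
    mask = np.asarray(mask, bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    dist_to_bg = ndi.distance_transform_edt(padded)
    return (dist_to_bg > radius)[1:-1, 1:-1, 1:-1]


def ball_opening(mask: np.ndarray, radius: float) -> np.ndarray:
    return ball_dilation(ball_erosion(mask, radius), radius)


def ball_closing(mask: np.ndarray, radius: float) -> np.ndarray:
    """Closing with outside-the-array treated as background (no artificial
    filling against the volume border)."""
    mask = np.asarray(mask, bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    pad = int(np.ceil(radius)) + 1
    padded = np.pad(mask, pad, constant_values=False)
    closed = ball_erosion(ball_dilation(padded, radius), radius)
    sl = tuple(slice(pad, -pad) for _ in range(3))
    return closed[sl]


def require_binary(arr: np.ndarray, name: str = "mask") -> np.ndarray:
    """Coerce to bool, rejecting arrays that are not 0/1-valued."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary; found values {vals[:8]}")
    return arr.astype(bool)
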