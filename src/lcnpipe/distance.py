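"""Distance statistics of the bone matrix to lacunae / canaliculi.

For a target structure (lacunae or canaliculi) the exact Euclidean distance
from every bone-matrix voxel centre to the nearest target voxel centre is
computed; the normalized cumulative histogram of those distances yields the
Dist50 statistics (Lc.Dist50, Ca.Dist50): the distance within which 50% of
the bone matrix lies from the nearest target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import require_binary


@dataclass
class DistanceProfile:
    """Normalized cumulative distance histogram over bone-matrix voxels."""

    target_class: str  # "lacunae" | "canaliculi" | other
    bin_edges_um: np.ndarray
    cumulative: np.ndarray  # fraction of matrix voxels with distance <= edge
    spacing: float

    def __post_init__(self) -> None:
        if len(self.cumulative) and (np.diff(self.cumulative) < -1e-12).any():
            raise ValueError("cumulative fraction must be nondecreasing")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    @property
    def dist50_um(self) -> float:
        return dist_quantile(self, 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_um": self.bin_centers_um, "cumulative_fraction": self.cumulative}
        )


def distance_map(target: np.ndarray, spacing: float) -> np.ndarray:
    """Exact Euclidean distance (µm) of every voxel to the nearest target voxel."""
    target = require_binary(target, "target")
    if not target.any():
        raise ValueError("no reference structure: target mask is empty")
    return ndi.distance_transform_edt(~target, sampling=spacing)


def distance_profile(
    target: np.ndarray,
    matrix: np.ndarray,
    spacing: float,
    target_class: str = "target",
    bin_width: float | None = None,
) -> DistanceProfile:
    """Cumulative distance histogram of matrix voxels to the nearest target.

    Distances are voxel-centre to voxel-centre (a face-adjacent matrix voxel
    is at one spacing).  The histogram bin width defaults to the voxel size.
    """
    matrix = require_binary(matrix, "matrix")
    if not matrix.any():
        raise ValueError("matrix mask is empty")
    target = require_binary(target, "target")
    if (target & matrix).any():
        raise ValueError("target and matrix masks must be disjoint")
    dmap = distance_map(target, spacing)
    dists = dmap[matrix]
    bw = spacing if bin_width is None else float(bin_width)
    if bw <= 0:
        raise ValueError("bin width must be > 0")
    # centre the bins on multiples of the bin width: voxel-grid distances are
    # near-multiples of the spacing, and offset bins would bias Dist50 by
    # half a bin in degenerate (single-distance) cases
    dmax = float(dists.max())
    n_bins = max(1, int(np.floor(dmax / bw + 0.5)) + 1)
    edges = (np.arange(n_bins + 1) - 0.5) * bw
    counts, _ = np.histogram(dists, bins=edges)
    cum = np.cumsum(counts) / dists.size
    cum[-1] = 1.0  # guard against float round-off at the last edge
    return DistanceProfile(target_class, edges, cum, spacing)


def dist_quantile(profile: DistanceProfile, q: float) -> float:
    """Distance (µm) at which the cumulative fraction reaches q.

    Linear interpolation between consecutive bin centres; Dist50 is
    ``dist_quantile(profile, 0.5)``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if profile.cumulative.size == 0:
        raise ValueError("empty distance profile")
    if q == 0.0:
        return 0.0
    centers = profile.bin_centers_um
    cum = profile.cumulative
    idx = int(np.searchsorted(cum, q))
    if idx >= len(cum):
        return float(centers[-1])
    if idx == 0 or cum[idx] == cum[idx - 1]:
        return float(centers[idx])
    c0, c1 = cum[idx - 1], cum[idx]
    d0, d1 = centers[idx - 1], centers[idx]
    value = float(d0 + (q - c0) / (c1 - c0) * (d1 - d0))
    # never return a distance below the smallest one that carries mass
    # (keeps the all-mass-at-one-distance case at that distance)
    first_mass = int(np.argmax(cum > 0))
    return max(value, float(centers[first_mass]))
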