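"""Nano-scale (TXM-like) lacunar-canalicular network morphometry.

Segments the LCN from grayscale by thresholding, splits lacunae from
canaliculi with a morphological opening and a Boolean AND, and computes the
standard morphometric descriptors:

* per lacuna: volume Lc.V, surface area Lc.SA (triangulated isosurface),
  sphericity  pi^(1/3) (6 V)^(2/3) / SA  (1 for a perfect sphere) and
  smoothness  SA^3 / (36 pi V^2)  (its inverse cube, >= 1);
* per specimen: mean canalicular surface/volume per canaliculus (a
  canaliculus = one skeleton branch), canaliculi areal density N.Ca/Lc.SA,
  junction density Ca.nodes/BV, and the LCN porosity LCN/BV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import marching_cubes, mesh_surface_area

from .core import Volume3D, ball_opening, require_binary
from .skeleton import SkeletonGraph, skeleton_graph


@dataclass
class LacunaRecord:
    """Morphometrics of a single lacuna."""

    id: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float
    smoothness: float
    centroid: tuple[float, float, float]  # voxel coords (z, y, x)
    axis_lengths_um: tuple[float, float, float]  # principal semi-axis estimates
    axis_directions: np.ndarray  # rows = principal directions
    border_touching: bool


@dataclass
class LCNMetrics:
    """Per-specimen descriptors of the lacunar-canalicular network."""

    mean_ca_sa_um2: float  # mean canalicular surface area per canaliculus
    mean_ca_v_um3: float  # mean canalicular volume per canaliculus
    n_canaliculi: int
    n_ca_per_lc_sa_um2: float  # N.Ca/Lc.SA, canaliculi areal density
    ca_nodes_per_bv_um3: float  # Ca.nodes/BV, junction density
    lcn_bv_fraction: float  # LCN/BV porosity

    def to_dict(self) -> dict:
        return {
            "Ca.SA_um2": self.mean_ca_sa_um2,
            "Ca.V_um3": self.mean_ca_v_um3,
            "n_canaliculi": self.n_canaliculi,
            "N.Ca/Lc.SA_per_um2": self.n_ca_per_lc_sa_um2,
            "Ca.nodes/BV_per_um3": self.ca_nodes_per_bv_um3,
            "LCN/BV": self.lcn_bv_fraction,
        }


def segment_lcn(
    gray: Volume3D,
    threshold: Optional[float] = None,
    polarity: str = "dark",
    denoise: Optional[str] = None,
    denoise_size: float = 1.0,
) -> np.ndarray:
    """Threshold a grayscale volume into an LCN mask.

    ``polarity="dark"`` marks voxels with intensity <= threshold as LCN
    (pores darker than matrix, the absorption-contrast convention);
    ``"bright"`` marks intensity >= threshold.  With ``threshold=None`` the
    Otsu threshold is used.  Optional denoising (``"gaussian"``, ``"median"``)
    runs before thresholding.
    """
    img = np.asarray(gray.data, float)
    if denoise == "gaussian":
        img = ndi.gaussian_filter(img, denoise_size)
    elif denoise == "median":
        img = ndi.median_filter(img, size=max(1, int(round(denoise_size))))
    elif denoise is not None:
        raise ValueError(f"unknown denoiser {denoise!r}")
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(img))
    if polarity == "dark":
        return img <= threshold
    if polarity == "bright":
        return img >= threshold
    raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")


def split_lcn(
    lcn: np.ndarray, open_radius: float, expected_lacunae: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split an LCN mask into lacunae and canaliculi.

    The lacunae are what survives a morphological opening with a ball whose
    radius exceeds the canalicular radius but is below the smallest lacunar
    semiaxis; the canaliculi are the LCN voxels outside the lacunae (Boolean
    AND with the inverted lacunae), so the two masks are disjoint and their
    union is the input.

    If ``expected_lacunae`` is given and the opening leaves fewer connected
    components, a warning is issued (a lacuna vanished under the opening).
    """
    lcn = require_binary(lcn, "lcn")
    lacunae = ball_opening(lcn, open_radius)
    canaliculi = lcn & ~lacunae
    if expected_lacunae is not None:
        n = int(cc_label(lacunae, connectivity=3).max())
        if n < expected_lacunae:
            warnings.warn(
                f"opening with radius {open_radius} left {n} lacunae "
                f"(expected {expected_lacunae}); some lacunae vanished",
                stacklevel=2,
            )
    return lacunae, canaliculi


def mesh_area(mask: np.ndarray, spacing: float, smooth_sigma: float = 1.0) -> float:
    """Surface area (µm²) of a binary object via a triangulated isosurface.

    The binary field is lightly Gaussian-smoothed (``smooth_sigma`` voxels)
    before marching cubes: meshing the raw 0/1 field leaves a staircase
    surface ~8-9% too large, while the smoothed 0.5-level surface of a
    digitized sphere is within ~1% of the true area.  If smoothing erases a
    thin structure entirely the sigma is halved until a surface survives.
    """
    mask = require_binary(mask)
    pad = max(2, int(np.ceil(2 * smooth_sigma)) + 1)
    padded = np.pad(mask, pad).astype(np.float32)
    sigma = smooth_sigma
    while True:
        field = ndi.gaussian_filter(padded, sigma) if sigma > 0 else padded
        if field.max() > 0.5:
            break
        sigma /= 2.0
        if sigma < 0.05:
            field = padded
            break
    verts, faces, *_ = marching_cubes(field, level=0.5, spacing=(spacing,) * 3)
    return float(mesh_surface_area(verts, faces))


def sphericity_from_vs(volume: float, surface_area: float) -> float:
    """pi^(1/3) (6V)^(2/3) / SA; equals 1 for a perfect sphere."""
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area)


def smoothness_from_vs(volume: float, surface_area: float) -> float:
    """SA^3 / (36 pi V^2); >= 1, equal to 1 for a sphere (inverse cube of
    sphericity)."""
    return float(surface_area**3 / (36.0 * np.pi * volume**2))


def shape_descriptors(
    labelled: np.ndarray, spacing: float, min_voxels: int = 2
) -> list[LacunaRecord]:
    """Per-component shape descriptors.

    Volume is voxel count x spacing³; surface area comes from a marching-cubes
    isosurface of the component (voxel-face counting would inflate SA by
    ~50% and bias sphericity well below the anatomical range).  Principal
    axes come from the second moments of the voxel coordinates; semi-axis
    lengths are the ellipsoid-equivalent sqrt(5 lambda_i).  Components
    smaller than ``min_voxels`` are excluded with a warning.
    """
    labelled = np.asarray(labelled)
    if labelled.dtype == bool:
        labelled = cc_label(labelled, connectivity=3)
    records: list[LacunaRecord] = []
    shape = labelled.shape
    for lid in np.unique(labelled):
        if lid == 0:
            continue
        mask = labelled == lid
        n = int(mask.sum())
        if n < min_voxels:
            warnings.warn(f"component {lid} has {n} voxel(s); excluded", stacklevel=2)
            continue
        zs, ys, xs = np.nonzero(mask)
        z0, z1 = zs.min(), zs.max() + 1
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        sub = mask[z0:z1, y0:y1, x0:x1]
        vol = n * spacing**3
        sa = mesh_area(sub, spacing)
        coords = np.stack([zs, ys, xs], axis=1).astype(float) * spacing
        centroid = coords.mean(axis=0)
        cov = np.cov((coords - centroid).T) if n > 1 else np.zeros((3, 3))
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals[::-1], 0.0, None)
        axes = tuple(float(np.sqrt(5.0 * e)) for e in evals)
        border = z0 == 0 or y0 == 0 or x0 == 0 or z1 == shape[0] or y1 == shape[1] or x1 == shape[2]
        records.append(
            LacunaRecord(
                id=int(lid),
                volume_um3=vol,
                surface_area_um2=sa,
                sphericity=sphericity_from_vs(vol, sa),
                smoothness=smoothness_from_vs(vol, sa),
                centroid=tuple(c / spacing for c in centroid),
                axis_lengths_um=axes,
                axis_directions=evecs[:, ::-1].T,
                border_touching=bool(border),
            )
        )
    return records


def lacuna_table(records: list[LacunaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "Lc.V_um3": r.volume_um3,
                "Lc.SA_um2": r.surface_area_um2,
                "sphericity": r.sphericity,
                "smoothness": r.smoothness,
                "centroid_z": r.centroid[0],
                "centroid_y": r.centroid[1],
                "centroid_x": r.centroid[2],
                "axis_a_um": r.axis_lengths_um[0],
                "axis_b_um": r.axis_lengths_um[1],
                "axis_c_um": r.axis_lengths_um[2],
                "border_touching": r.border_touching,
            }
            for r in records
        ]
    )


def canaliculi_per_lacuna(
    skeleton: SkeletonGraph,
    lacunae_labelled: np.ndarray,
    records: list[LacunaRecord],
    attach_distance_voxels: float = 3.0,
) -> dict[int, float]:
    """Canaliculi areal density N.Ca/Lc.SA per lacuna (µm⁻²).

    Counts skeleton branches attached to each lacuna, divided by that
    lacuna's surface area.  A branch is attached when its path comes within
    ``attach_distance_voxels`` of the lacuna: thinning retracts a skeleton
    from the ends of a tube by roughly the tube radius, so a strict 1-voxel
    shell test would miss genuinely attached canaliculi.
    """
    lab = np.asarray(lacunae_labelled)
    by_id = {r.id: r for r in records}
    paths = skeleton.branch_paths()
    out: dict[int, float] = {}
    for lid in np.unique(lab):
        if lid == 0:
            continue
        if int(lid) not in by_id:
            raise KeyError(f"lacuna id {lid} missing from records")
        dist = ndi.distance_transform_edt(lab != lid)
        count = sum(1 for path in paths if dist[tuple(path.T)].min() <= attach_distance_voxels)
        out[int(lid)] = count / by_id[int(lid)].surface_area_um2
    return out


def junction_density(skeleton: SkeletonGraph, bv_um3: float) -> float:
    """Ca.nodes/BV: skeleton nodes of degree >= 3 per bone volume (µm⁻³)."""
    if bv_um3 <= 0:
        raise ValueError(f"bone volume must be > 0, got {bv_um3}")
    return skeleton.n_junctions / bv_um3


def lcn_porosity(lcn: np.ndarray, bone: np.ndarray) -> float:
    """LCN/BV: LCN voxel count over total bone voxel count.

    The bone label is the full specimen (matrix plus LCN); every LCN voxel
    must lie inside it.
    """
    lcn = require_binary(lcn, "lcn")
    bone = require_binary(bone, "bone")
    if (lcn & ~bone).any():
        raise ValueError("LCN mask extends outside the bone label")
    total = int(bone.sum())
    if total == 0:
        raise ValueError("bone label is empty")
    return float(lcn.sum()) / total


def compute_lcn_metrics(
    lacunae: np.ndarray,
    canaliculi: np.ndarray,
    bone: np.ndarray,
    spacing: float,
    prune_length: Optional[float] = None,
    records: Optional[list[LacunaRecord]] = None,
    min_component_voxels: int = 0,
) -> tuple[LCNMetrics, SkeletonGraph]:
    """Per-specimen LCN descriptors.

    Canalicular totals are divided by the number of skeleton branches, i.e.
    values are normalized per canaliculus.  N.Ca/Lc.SA is the mean of the
    per-lacuna areal densities over non-border lacunae (all lacunae when
    every one touches the border).  ``min_component_voxels`` despeckles the
    canalicular mask first (partial-volume shells left around lacunae by the
    Boolean split otherwise count as canaliculi).
    """
    lacunae = require_binary(lacunae, "lacunae")
    canaliculi = require_binary(canaliculi, "canaliculi")
    if min_component_voxels > 1 and canaliculi.any():
        comp = cc_label(canaliculi, connectivity=3)
        sizes = np.bincount(comp.ravel())
        keep = sizes >= min_component_voxels
        keep[0] = False
        canaliculi = keep[comp]
    sk = skeleton_graph(canaliculi, spacing, prune_length=prune_length)
    n_ca = sk.n_branches
    if canaliculi.any():
        # gentler smoothing than for lacunae: canaliculi are only a few
        # voxels wide and a 1-voxel sigma would erode them away
        ca_sa_total = mesh_area(canaliculi, spacing, smooth_sigma=0.5)
        ca_v_total = float(canaliculi.sum()) * spacing**3
    else:
        ca_sa_total = ca_v_total = 0.0
    mean_sa = ca_sa_total / n_ca if n_ca else 0.0
    mean_v = ca_v_total / n_ca if n_ca else 0.0

    lab = cc_label(lacunae, connectivity=3)
    if records is None:
        records = shape_descriptors(lab, spacing)
    per_lac = canaliculi_per_lacuna(sk, lab, records) if records else {}
    interior = [r.id for r in records if not r.border_touching]
    use_ids = interior if interior else [r.id for r in records]
    nca = float(np.mean([per_lac[i] for i in use_ids])) if use_ids else 0.0

    bv = float(require_binary(bone, "bone").sum()) * spacing**3
    metrics = LCNMetrics(
        mean_ca_sa_um2=mean_sa,
        mean_ca_v_um3=mean_v,
        n_canaliculi=n_ca,
        n_ca_per_lc_sa_um2=nca,
        ca_nodes_per_bv_um3=junction_density(sk, bv),
        lcn_bv_fraction=lcn_porosity(lacunae | canaliculi, bone),
    )
    return metrics, sk
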