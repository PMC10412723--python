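"""Synthetic 3D bone phantoms with exact ground truth.

The generator emulates the content of the two imaging scales used in
peri-implant bone studies:

* micro-scale (SRµCT-like) volumes: a bone block, an optional implant
  cylinder, ellipsoidal osteocyte lacunae (~100-500 µm³) and tubular
  vascular canals;
* nano-scale (TXM-like) volumes: a small bone specimen containing a handful
  of lacunae connected by sub-micron canaliculi.

Every structure is placed with rejection sampling under a minimum-gap
constraint, so the ground-truth tables correspond one-to-one to connected
components of the label volume.  Grayscale rendering applies a label
contrast map, a Gaussian point-spread function and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    BACKGROUND,
    BONE,
    CANALICULUS,
    IMPLANT,
    LACUNA,
    LABEL_NAMES,
    VASCULAR,
    LabelVolume,
    Volume3D,
)

DEFAULT_CONTRAST = {
    BACKGROUND: 20.0,
    BONE: 200.0,
    LACUNA: 60.0,
    CANALICULUS: 60.0,
    VASCULAR: 60.0,
    IMPLANT: 250.0,
}


class PhantomPlacementError(RuntimeError):
    """Raised when a structure class cannot be placed without overlap."""


@dataclass
class ImplantSpec:
    """Cylindrical implant running through the whole volume along one axis."""

    center: tuple[float, float]  # µm, in the plane perpendicular to `axis`
    radius: float  # µm
    axis: int = 0  # 0=z, 1=y, 2=x


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bone volume.

    Either ``n_lacunae`` (a count) or ``lacunar_density`` (mm⁻³, converted to
    a count from the bone volume) must be given.  All lengths are µm.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.0
    n_lacunae: Optional[int] = None
    lacunar_density: Optional[float] = None  # mm^-3
    lacuna_semiaxes_range: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (5.0, 2.0, 2.0),
        (7.5, 3.0, 3.0),
    )
    n_vascular: int = 0
    vascular_radius_range: tuple[float, float] = (6.0, 10.0)
    canaliculi_per_lacuna: int = 0
    canaliculus_radius: float = 0.5
    implant: Optional[ImplantSpec] = None
    contrast_map: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    psf_sigma: float = 0.0  # µm
    noise_sd: float = 0.0  # intensity units
    seed: int = 0
    min_gap_voxels: float = 3.0  # minimum separation between distinct pores

    def validate(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be three dimensions of at least 4 voxels")
        lo, hi = (np.asarray(v, float) for v in self.lacuna_semiaxes_range)
        if (lo <= 0).any() or (hi < lo).any():
            raise ValueError("lacuna semiaxes must be positive with lo <= hi")
        extent = min(self.grid_shape) * self.spacing
        if hi.max() * 2 >= extent:
            raise ValueError("lacuna semiaxes exceed the grid physical extent")
        if self.n_lacunae is None and self.lacunar_density is None:
            raise ValueError("give n_lacunae or lacunar_density")
        if self.n_lacunae is not None and self.n_lacunae < 0:
            raise ValueError("n_lacunae must be >= 0")
        if self.n_vascular < 0 or self.canaliculi_per_lacuna < 0:
            raise ValueError("structure counts must be >= 0")
        if self.canaliculus_radius <= 0:
            raise ValueError("canaliculus_radius must be > 0")
        if self.vascular_radius_range[0] <= 0:
            raise ValueError("vascular radii must be > 0")
        if self.implant is not None and self.implant.radius <= 0:
            raise ValueError("implant radius must be > 0")


@dataclass
class GroundTruth:
    """Exact description of a generated phantom.

    ``lacuna_instances`` assigns each lacuna's voxels its 1-based table id;
    ``pair_adjacency`` lists unordered lacuna-id pairs joined by a
    canaliculus.
    """

    label_volume: LabelVolume
    lacuna_table: pd.DataFrame
    vascular_table: pd.DataFrame
    pair_adjacency: list[tuple[int, int]]
    lacuna_instances: np.ndarray

    @property
    def n_lacunae(self) -> int:
        return len(self.lacuna_table)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ellipsoid_local_mask(
    center_vox: np.ndarray,
    semiaxes_um: np.ndarray,
    rotation: np.ndarray,
    spacing: float,
    shape: Sequence[int],
    inflate_um: float = 0.0,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxelize an ellipsoid inside its bounding box.

    Returns the bounding-box slices into the full grid and the boolean mask
    within that box.  ``inflate_um`` grows every semiaxis (used for
    conservative gap checks).
    """
    semi = np.asarray(semiaxes_um, float) + inflate_um
    half = semi.max() / spacing + 1.0
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, np.asarray(shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d = np.stack([(g - c) * spacing for g, c in zip(grids, center_vox)], axis=-1)
    local = d @ rotation  # into ellipsoid frame
    inside = (np.square(local / semi)).sum(axis=-1) <= 1.0
    return sl, inside


def _segment_distance_mask(
    p0: np.ndarray, p1: np.ndarray, radius_vox: float, shape: Sequence[int]
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxels within ``radius_vox`` of the segment p0-p1 (voxel coords)."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius_vox + 1).astype(int) + 1, np.asarray(shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack(grids, axis=-1).astype(float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
        nearest = p0 + t[..., None] * v
        dist = np.linalg.norm(pts - nearest, axis=-1)
    return sl, dist <= radius_vox


def _place_lacunae(
    labels: np.ndarray,
    instances: np.ndarray,
    spec: PhantomSpec,
    n_target: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    shape = labels.shape
    lo, hi = (np.asarray(v, float) for v in spec.lacuna_semiaxes_range)
    gap_um = spec.min_gap_voxels * spec.spacing
    rows = []
    max_tries = max(500, 300 * n_target)
    tries = 0
    while len(rows) < n_target:
        if tries >= max_tries:
            raise PhantomPlacementError(
                f"could not place lacuna {len(rows) + 1}/{n_target} "
                f"after {tries} attempts; volume too crowded"
            )
        tries += 1
        semi = rng.uniform(lo, hi)
        # the gap applies between pores, not to the volume border
        margin = semi.max() / spec.spacing + 1
        center = rng.uniform(margin, np.asarray(shape) - 1 - margin)
        rot = _random_rotation(rng)
        sl, inflated = _ellipsoid_local_mask(center, semi, rot, spec.spacing, shape, inflate_um=gap_um)
        # reject if the gap-inflated footprint leaves bone or nears another pore
        region = labels[sl]
        if (region[inflated] != BONE).any():
            continue
        sl2, mask = _ellipsoid_local_mask(center, semi, rot, spec.spacing, shape)
        if mask.sum() < 2:
            continue
        lid = len(rows) + 1
        labels[sl2][mask] = LACUNA
        instances[sl2][mask] = lid
        rows.append(
            {
                "id": lid,
                "centroid_z_um": center[0] * spec.spacing,
                "centroid_y_um": center[1] * spec.spacing,
                "centroid_x_um": center[2] * spec.spacing,
                "semiaxis_a_um": semi[0],
                "semiaxis_b_um": semi[1],
                "semiaxis_c_um": semi[2],
                "volume_analytic_um3": 4.0 / 3.0 * np.pi * semi.prod(),
                "n_voxels": int(mask.sum()),
                "volume_voxel_um3": float(mask.sum()) * spec.spacing**3,
            }
        )
    cols = [
        "id", "centroid_z_um", "centroid_y_um", "centroid_x_um",
        "semiaxis_a_um", "semiaxis_b_um", "semiaxis_c_um",
        "volume_analytic_um3", "n_voxels", "volume_voxel_um3",
    ]
    return pd.DataFrame(rows, columns=cols)


def _place_vascular(
    labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Straight vascular canals spanning the volume along a random grid axis."""
    shape = np.asarray(labels.shape)
    gap_vox = spec.min_gap_voxels
    rows = []
    tries, max_tries = 0, max(200, 200 * spec.n_vascular)
    while len(rows) < spec.n_vascular:
        if tries >= max_tries:
            raise PhantomPlacementError(
                f"could not place vascular canal {len(rows) + 1}/{spec.n_vascular} "
                f"after {tries} attempts; volume too crowded"
            )
        tries += 1
        axis = int(rng.integers(0, 3))
        radius_um = float(rng.uniform(*spec.vascular_radius_range))
        r_vox = radius_um / spec.spacing
        perp = [a for a in range(3) if a != axis]
        pos = np.zeros(3)
        ok_range = True
        for a in perp:
            lo_a, hi_a = r_vox + gap_vox + 1, shape[a] - 1 - r_vox - gap_vox - 1
            if lo_a >= hi_a:
                ok_range = False
                break
            pos[a] = rng.uniform(lo_a, hi_a)
        if not ok_range:
            continue
        p0, p1 = pos.copy(), pos.copy()
        p0[axis], p1[axis] = 0.0, float(shape[axis] - 1)
        sl_inf, inflated = _segment_distance_mask(p0, p1, r_vox + gap_vox, labels.shape)
        if (labels[sl_inf][inflated] != BONE).any():
            continue
        sl, mask = _segment_distance_mask(p0, p1, r_vox, labels.shape)
        labels[sl][mask] = VASCULAR
        direction = np.zeros(3)
        direction[axis] = 1.0
        rows.append(
            {
                "id": len(rows) + 1,
                "axis_z": direction[0], "axis_y": direction[1], "axis_x": direction[2],
                "radius_um": radius_um,
                "length_um": float(shape[axis]) * spec.spacing,
                "n_voxels": int(mask.sum()),
            }
        )
    cols = ["id", "axis_z", "axis_y", "axis_x", "radius_um", "length_um", "n_voxels"]
    return pd.DataFrame(rows, columns=cols)


def _connect_canaliculi(
    labels: np.ndarray,
    instances: np.ndarray,
    lacuna_table: pd.DataFrame,
    spec: PhantomSpec,
) -> list[tuple[int, int]]:
    """Straight canalicular tubes between centroids of nearby lacuna pairs.

    Each lacuna proposes links to its k nearest neighbours; a proposed tube is
    dropped if it would graze a third lacuna or an existing canaliculus, so
    accepted tubes touch exactly their two endpoint lacunae.
    """
    if spec.canaliculi_per_lacuna == 0 or len(lacuna_table) < 2:
        return []
    cents = lacuna_table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    cents_vox = cents / spec.spacing
    ids = lacuna_table["id"].to_numpy()
    n = len(ids)
    d2 = np.square(cents_vox[:, None, :] - cents_vox[None, :, :]).sum(-1)
    np.fill_diagonal(d2, np.inf)
    proposed: set[tuple[int, int]] = set()
    k = min(spec.canaliculi_per_lacuna, n - 1)
    for i in range(n):
        for j in np.argsort(d2[i])[:k]:
            proposed.add(tuple(sorted((int(ids[i]), int(ids[j])))))
    r_vox = spec.canaliculus_radius / spec.spacing
    accepted: list[tuple[int, int]] = []
    for a, b in sorted(proposed):
        ia, ib = int(np.where(ids == a)[0][0]), int(np.where(ids == b)[0][0])
        sl, mask = _segment_distance_mask(cents_vox[ia], cents_vox[ib], r_vox, labels.shape)
        inst = instances[sl]
        touched = np.unique(inst[mask])
        if np.setdiff1d(touched, [0, a, b]).size:
            continue  # would pierce a third lacuna
        lab = labels[sl]
        new = mask & (lab == BONE)
        grown = ndi.binary_dilation(new, ndi.generate_binary_structure(3, 3))
        if (labels[sl][grown & ~new] == CANALICULUS).any():
            continue  # would merge with an existing tube away from the lacunae
        if not new.any():
            continue
        lab[new] = CANALICULUS
        accepted.append((a, b))
    return accepted


def render_grayscale(
    labels: LabelVolume,
    contrast_map: dict[int, float],
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Volume3D:
    """Render a label volume to grayscale: contrast LUT, Gaussian PSF, noise.

    ``psf_sigma`` is in µm; blurring uses reflective boundaries so the global
    mean is preserved.  Raises ``KeyError`` listing any label that has no
    contrast entry.
    """
    present = labels.present_labels()
    missing = [l for l in present if l not in contrast_map]
    if missing:
        raise KeyError(f"contrast_map missing entries for labels {missing}")
    lut = np.zeros(max(present) + 1)
    for l in present:
        lut[l] = contrast_map[l]
    img = lut[labels.data]
    if psf_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=psf_sigma / labels.spacing, mode="reflect")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return Volume3D(img, labels.spacing)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Generate a grayscale phantom and its exact ground truth.

    Deterministic for a fixed ``spec.seed``: one master seed is split into
    independent streams per structure class.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_lac, rng_vas, rng_render = (np.random.default_rng(s) for s in ss.spawn(3))

    labels = np.full(spec.grid_shape, BONE, dtype=np.int32)
    instances = np.zeros(spec.grid_shape, dtype=np.int32)

    if spec.implant is not None:
        imp = spec.implant
        perp = [a for a in range(3) if a != imp.axis]
        grids = np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij")
        d2 = sum(
            ((grids[a] - imp.center[i] / spec.spacing) * spec.spacing) ** 2
            for i, a in enumerate(perp)
        )
        labels[d2 <= imp.radius**2] = IMPLANT

    # BV in the number-density sense is bone plus pores, i.e. the bone
    # region before any pore is carved out.
    if spec.n_lacunae is not None:
        n_target = spec.n_lacunae
    else:
        bv_mm3 = float((labels == BONE).sum()) * spec.spacing**3 * 1e-9
        n_target = int(round(spec.lacunar_density * bv_mm3))

    # canals span the whole volume, so they go in before the dense lacunar
    # packing; lacunae then avoid them
    vascular_table = _place_vascular(labels, spec, rng_vas)
    lacuna_table = _place_lacunae(labels, instances, spec, n_target, rng_lac)
    pairs = _connect_canaliculi(labels, instances, lacuna_table, spec)

    label_volume = LabelVolume(labels, spec.spacing, semantics=dict(LABEL_NAMES))
    gray = render_grayscale(
        label_volume, spec.contrast_map, spec.psf_sigma, spec.noise_sd, rng_render
    )
    truth = GroundTruth(
        label_volume=label_volume,
        lacuna_table=lacuna_table,
        vascular_table=vascular_table,
        pair_adjacency=pairs,
        lacuna_instances=instances,
    )
    return gray, truth


def microct_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Micro-scale (SRµCT-like) default phantom: 64³ voxels at 2 µm.

    The default lacunar number density (8×10⁴ mm⁻³) is in the range reported
    for rat cortical bone and yields ~170 lacunae of 100-500 µm³ in the
    128 µm cube, plus two vascular canals.
    """
    params = dict(
        grid_shape=(64, 64, 64),
        spacing=2.0,
        lacunar_density=8.0e4,
        lacuna_semiaxes_range=((5.0, 2.0, 2.0), (7.5, 3.0, 3.0)),
        n_vascular=2,
        vascular_radius_range=(6.0, 10.0),
        psf_sigma=2.0,
        noise_sd=8.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def txm_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Nano-scale (TXM-like) default phantom: a ~36 µm bone cube at 0.3 µm
    voxels with five lacunae linked by sub-micron canaliculi."""
    params = dict(
        grid_shape=(120, 120, 120),
        spacing=0.3,
        n_lacunae=5,
        lacuna_semiaxes_range=((5.0, 2.0, 2.0), (7.0, 3.0, 3.0)),
        n_vascular=0,
        canaliculi_per_lacuna=3,
        canaliculus_radius=0.45,
        psf_sigma=0.3,
        noise_sd=8.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)
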