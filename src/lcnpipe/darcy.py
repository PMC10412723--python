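"""Image-based stationary Darcy flow in lacuna-pair sub-volumes.

A pair of lacunae with their connecting canaliculi is extracted from a
labelled LCN and the incompressible Darcy problem

    div( -(k/mu) grad p ) = 0,      u = -(k/mu) grad p

is solved on the voxelized fluid geometry with a 6-connected finite-volume
discretization: Dirichlet pressures on the fluid voxels of the inlet and
outlet faces (imposed at the half-cell boundary), zero normal flux
(symmetry) everywhere else.  The fluid lumen is treated as a uniform porous
medium; defaults follow the canonical canalicular values (permeability
1e-18 m², porosity 5%, interstitial-fluid viscosity 8.55e-4 Pa·s, inlet
300 Pa / outlet 0 Pa).  Pressure and mean speed are then summarized over
the connecting canaliculi and additionally normalized by their volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve
from skimage.measure import label as cc_label

from .core import require_binary

FACES = ("z-", "z+", "y-", "y+", "x-", "x+")


class PercolationError(RuntimeError):
    """Inlet and outlet are not connected through the fluid."""


@dataclass
class FlowParams:
    """Physical parameters of the Darcy problem (SI where noted)."""

    permeability_m2: float = 1.0e-18
    viscosity_pa_s: float = 8.55e-4
    porosity: float = 0.05
    fluid_density_kg_m3: float = 997.0  # stored; unused in the stationary solve
    inlet_pressure_pa: float = 300.0
    outlet_pressure_pa: float = 0.0

    def validate(self) -> None:
        if self.permeability_m2 <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("permeability and viscosity must be > 0")
        if not 0 < self.porosity <= 1:
            raise ValueError("porosity must be in (0, 1]")


@dataclass
class FlowDomain:
    """Fluid geometry and boundary assignment for one Darcy solve."""

    fluid_mask: np.ndarray
    spacing: float  # µm
    inlet_face: str
    outlet_face: str
    connecting_mask: np.ndarray
    params: FlowParams = field(default_factory=FlowParams)
    pair_ids: tuple[int, int] | None = None
    origin: tuple[int, int, int] = (0, 0, 0)  # offset in the parent volume

    def __post_init__(self) -> None:
        self.fluid_mask = require_binary(self.fluid_mask, "fluid_mask")
        self.connecting_mask = require_binary(self.connecting_mask, "connecting_mask")
        if self.inlet_face not in FACES or self.outlet_face not in FACES:
            raise ValueError(f"faces must be one of {FACES}")
        if self.inlet_face[0] != self.outlet_face[0] or self.inlet_face == self.outlet_face:
            raise ValueError("inlet and outlet must be opposite faces")
        self.params.validate()


@dataclass
class FlowField:
    """Solution of one Darcy solve on a voxel grid."""

    pressure_pa: np.ndarray  # NaN outside the solved fluid
    velocity_m_s: np.ndarray  # (3, nz, ny, nx), zero outside the fluid
    inlet_flux_m3_s: float
    outlet_flux_m3_s: float
    residual: float

    def speed(self) -> np.ndarray:
        return np.sqrt((self.velocity_m_s**2).sum(axis=0))


@dataclass
class FlowSummary:
    """Pressure/velocity summaries over the connecting canaliculi."""

    mean_pressure_pa: float
    mean_speed_m_s: float
    connecting_volume_um3: float
    mean_pressure_per_volume: float  # Pa / µm³
    mean_speed_per_volume: float  # m s⁻¹ / µm³

    def to_dict(self) -> dict:
        return {
            "mean_pressure_Pa": self.mean_pressure_pa,
            "mean_speed_m_per_s": self.mean_speed_m_s,
            "connecting_volume_um3": self.connecting_volume_um3,
            "pressure_per_volume_Pa_per_um3": self.mean_pressure_per_volume,
            "speed_per_volume_m_per_s_per_um3": self.mean_speed_per_volume,
        }


def _face_slice(face: str, shape: tuple[int, int, int]) -> tuple[int, int]:
    axis = {"z": 0, "y": 1, "x": 2}[face[0]]
    index = 0 if face[1] == "-" else shape[axis] - 1
    return axis, index


def select_lacuna_pair(
    lacunae_labelled: np.ndarray,
    canaliculi: np.ndarray,
    spacing: float,
    seed: int = 0,
    margin: int = 2,
    params: Optional[FlowParams] = None,
) -> FlowDomain:
    """Extract a random connected lacuna pair with its connecting canaliculi.

    Connecting canaliculi are 26-connected canalicular components touching
    both lacunae of a pair.  The sub-volume is the bounding box of the pair
    plus ``margin`` voxels on the transverse axes; along the dominant
    centroid-to-centroid axis the fluid spans the box exactly, and the two
    faces perpendicular to that axis become the inlet (low side) and outlet.
    """
    lab = np.asarray(lacunae_labelled)
    if lab.dtype == bool:
        lab = cc_label(lab, connectivity=3)
    canaliculi = require_binary(canaliculi, "canaliculi")
    struct = ndi.generate_binary_structure(3, 3)
    comp = cc_label(canaliculi, connectivity=3)
    # map each canalicular component to the lacunae it touches by dilating
    # every lacuna once (there are few lacunae, many components)
    touches: dict[int, set[int]] = {}
    for lid in np.unique(lab):
        if lid == 0:
            continue
        shell = ndi.binary_dilation(lab == lid, struct)
        for cid in np.unique(comp[shell]):
            if cid > 0:
                touches.setdefault(int(cid), set()).add(int(lid))
    pair_comps: dict[tuple[int, int], list[int]] = {}
    for cid, lids in sorted(touches.items()):
        ordered = sorted(lids)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                pair_comps.setdefault((ordered[i], ordered[j]), []).append(cid)
    if not pair_comps:
        raise ValueError("no connected lacuna pair")
    pairs = sorted(pair_comps)
    rng = np.random.default_rng(seed)
    rng.shuffle(pairs)
    # adjacency above is 26-connected; the finite-volume solver needs a
    # 6-connected path, so fall through to the next candidate pair when a
    # thin canaliculus only touches diagonally
    for a, b in pairs:
        conn = np.isin(comp, pair_comps[(a, b)])
        fluid = (lab == a) | (lab == b) | conn
        comp6 = cc_label(fluid, connectivity=1)
        ids_a = set(np.unique(comp6[lab == a])) - {0}
        ids_b = set(np.unique(comp6[lab == b])) - {0}
        if ids_a & ids_b:
            break
    else:
        raise ValueError(
            "no connected lacuna pair percolates under 6-connectivity"
        )

    ca = np.argwhere(lab == a).mean(axis=0)
    cb = np.argwhere(lab == b).mean(axis=0)
    flow_axis = int(np.argmax(np.abs(cb - ca)))

    # the box spans the percolating fluid exactly along the flow axis, so
    # the pair geometry touches the inlet and outlet faces
    keep6 = np.isin(comp6, sorted(ids_a & ids_b))
    coords = np.argwhere(fluid)
    perc_coords = np.argwhere(keep6)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    lo[flow_axis] = perc_coords[:, flow_axis].min()
    hi[flow_axis] = perc_coords[:, flow_axis].max() + 1
    for ax in range(3):
        if ax != flow_axis:
            lo[ax] = max(0, lo[ax] - margin)
            hi[ax] = min(fluid.shape[ax], hi[ax] + margin)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    axis_name = "zyx"[flow_axis]
    return FlowDomain(
        fluid_mask=fluid[sl],
        spacing=spacing,
        inlet_face=f"{axis_name}-",
        outlet_face=f"{axis_name}+",
        connecting_mask=conn[sl],
        params=params if params is not None else FlowParams(),
        pair_ids=(a, b),
        origin=tuple(int(l) for l in lo),
    )


def solve_darcy(domain: FlowDomain, rtol: float = 1e-10) -> FlowField:
    """Solve stationary Darcy flow on the domain's fluid voxels.

    Finite volumes on the 6-connected voxel grid; the inlet/outlet pressures
    are imposed on fluid voxels lying on those boundary faces through
    half-cell transmissibilities, so a straight channel of N voxels has the
    exact effective length N*h.  Raises :class:`PercolationError` when no
    fluid component reaches both faces, and ``RuntimeError`` if the linear
    solve does not reach the requested relative residual.
    """
    fluid = domain.fluid_mask
    p = domain.params
    h = domain.spacing * 1e-6  # m
    mob = p.permeability_m2 / p.viscosity_pa_s  # k/mu
    shape = fluid.shape

    axis, i_in = _face_slice(domain.inlet_face, shape)
    _, i_out = _face_slice(domain.outlet_face, shape)

    def face_mask(index: int) -> np.ndarray:
        m = np.zeros(shape, bool)
        sl = [slice(None)] * 3
        sl[axis] = index
        m[tuple(sl)] = fluid[tuple(sl)]
        return m

    inlet_vox = face_mask(i_in)
    outlet_vox = face_mask(i_out)
    if not inlet_vox.any() or not outlet_vox.any():
        raise PercolationError("inlet and outlet not connected: no fluid on a boundary face")

    comp = cc_label(fluid, connectivity=1)
    good = set(np.unique(comp[inlet_vox])) & set(np.unique(comp[outlet_vox]))
    good.discard(0)
    if not good:
        raise PercolationError("inlet and outlet not connected")
    solved = np.isin(comp, sorted(good))

    idx = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(solved)
    n = len(coords)
    idx[tuple(coords.T)] = np.arange(n)

    T_int = mob * h  # (k/mu) * A / h with A = h^2
    T_bnd = 2.0 * mob * h  # half-cell distance

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs = np.zeros(n)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        a_idx = idx[tuple(sl_lo)].ravel()
        b_idx = idx[tuple(sl_hi)].ravel()
        both = (a_idx >= 0) & (b_idx >= 0)
        ai, bi = a_idx[both], b_idx[both]
        rows.extend([ai, bi])
        cols.extend([bi, ai])
        vals.extend([-T_int * np.ones(len(ai))] * 2)
        np.add.at(diag, ai, T_int)
        np.add.at(diag, bi, T_int)

    for mask_vox, p_b in ((inlet_vox, p.inlet_pressure_pa), (outlet_vox, p.outlet_pressure_pa)):
        ids = idx[mask_vox & solved]
        diag[ids] += T_bnd
        rhs[ids] += T_bnd * p_b

    A = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(n)]), np.concatenate(cols + [np.arange(n)])),
        ),
        shape=(n, n),
    ).tocsr()

    if n <= 200_000:
        x = spsolve(A, rhs)
    else:
        x, info = cg(A, rhs, rtol=1e-13, maxiter=20 * n)
        if info != 0:
            raise RuntimeError(f"CG did not converge (info={info})")
    res = float(np.linalg.norm(A @ x - rhs))
    scale = float(np.linalg.norm(rhs)) or 1.0
    if res / scale > rtol:
        raise RuntimeError(f"solver residual {res / scale:.3e} above tolerance {rtol:.1e}")

    pressure = np.full(shape, np.nan)
    pressure[solved] = x

    # cell-centred Darcy velocity from face fluxes
    velocity = np.zeros((3,) + shape)
    for ax in range(3):
        u_minus = np.zeros(shape)
        u_plus = np.zeros(shape)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        p_lo = pressure[tuple(sl_lo)]
        p_hi = pressure[tuple(sl_hi)]
        both = ~np.isnan(p_lo) & ~np.isnan(p_hi)
        u_face = np.zeros_like(p_lo)
        u_face[both] = -mob / h * (p_hi[both] - p_lo[both])
        u_plus[tuple(sl_lo)] = u_face
        u_minus[tuple(sl_hi)] = u_face
        if ax == axis:
            u_b_in = -mob / (h / 2.0) * (pressure[inlet_vox & solved] - p.inlet_pressure_pa)
            u_b_out = -mob / (h / 2.0) * (p.outlet_pressure_pa - pressure[outlet_vox & solved])
            if i_in < i_out:  # inlet on the low side
                u_minus[inlet_vox & solved] = u_b_in
                u_plus[outlet_vox & solved] = u_b_out
            else:
                u_plus[inlet_vox & solved] = -u_b_in
                u_minus[outlet_vox & solved] = -u_b_out
        velocity[ax][solved] = 0.5 * (u_minus[solved] + u_plus[solved])

    # u_b_in is positive into the domain and u_b_out positive out of it on
    # either side, so the total fluxes need no orientation sign.
    area = h * h
    q_in = float(
        (-mob / (h / 2.0) * (pressure[inlet_vox & solved] - p.inlet_pressure_pa)).sum() * area
    )
    q_out = float(
        (-mob / (h / 2.0) * (p.outlet_pressure_pa - pressure[outlet_vox & solved])).sum() * area
    )
    return FlowField(
        pressure_pa=pressure,
        velocity_m_s=velocity,
        inlet_flux_m3_s=q_in,
        outlet_flux_m3_s=q_out,
        residual=res / scale,
    )


def summarize_flow(field: FlowField, domain: FlowDomain) -> FlowSummary:
    """Mean pressure and speed over the connecting canaliculi, raw and
    normalized by the connecting-canaliculi volume."""
    conn = domain.connecting_mask
    if not conn.any():
        raise ValueError("connecting-canaliculi mask is empty")
    pvals = field.pressure_pa[conn]
    svals = field.speed()[conn]
    pvals = pvals[~np.isnan(pvals)]
    if pvals.size == 0:
        raise ValueError("no solved fluid voxels inside the connecting mask")
    vol = float(conn.sum()) * domain.spacing**3
    mp = float(pvals.mean())
    ms = float(svals.mean())
    return FlowSummary(
        mean_pressure_pa=mp,
        mean_speed_m_s=ms,
        connecting_volume_um3=vol,
        mean_pressure_per_volume=mp / vol,
        mean_speed_per_volume=ms / vol,
    )


def channel_domain(
    n_axial: int,
    n_cross: int,
    spacing: float,
    params: Optional[FlowParams] = None,
    axis: int = 0,
) -> FlowDomain:
    """A straight rectangular channel spanning the grid along one axis.

    A convenience geometry whose closed-form solution (uniform speed
    k Δp / (µ L) and a linear pressure profile) anchors solver checks.
    """
    shape = [n_cross + 2] * 3
    shape[axis] = n_axial
    fluid = np.zeros(tuple(shape), bool)
    sl = [slice(1, -1)] * 3
    sl[axis] = slice(None)
    fluid[tuple(sl)] = True
    name = "zyx"[axis]
    return FlowDomain(
        fluid_mask=fluid,
        spacing=spacing,
        inlet_face=f"{name}-",
        outlet_face=f"{name}+",
        connecting_mask=fluid.copy(),
        params=params if params is not None else FlowParams(),
    )
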