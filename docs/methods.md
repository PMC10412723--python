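# Methods

This note documents the models, conventions and numerical choices behind
`lcnpipe`, stage by stage, in the order a volume flows through the
pipeline.

## Conventions

Volumes are dense arrays in (z, y, x) order with isotropic spacing stored
in micrometres; voxel indices are 0-based and positions are voxel-centred.
All analysis lengths are µm; only the Darcy solver converts to SI
internally. Foreground connectivity is 26 and background 6 unless a stage
states otherwise (the flow solver is 6-connected by construction).

Morphological operations with Euclidean-ball structuring elements
(`B(r) = {d : |d| ≤ r}`) are computed through exact Euclidean distance
transforms — `dilate(A, B(r)) = {x : dist(x, A) ≤ r}` and
`erode(A, B(r)) = {x : dist(x, Aᶜ) > r}` — which is mathematically
identical to structuring-element morphology for this family and much
faster at the radii the pipeline needs. Outside the array is treated as
background, so a closing never fills against the volume border.

## Phantom generator

The generator emulates the two study scales:

* `microct_spec()` — a 64³ voxel block at 2 µm spacing (a 128 µm cube of
  bone) containing ellipsoidal lacunae at a lacunar number density of
  8 × 10⁴ mm⁻³ and two vascular canals (radius 6–10 µm) spanning the
  volume. The density is a deliberate default: published osteocyte lacunar
  densities in rat cortical bone are in the several-10⁴ mm⁻³ range, and at
  8 × 10⁴ mm⁻³ the half-matrix distance to the nearest lacuna comes out
  near 10 µm, the anatomically reported scale. Lacuna semiaxes are drawn
  from (5–7.5, 2–3, 2–3) µm — a ≈ 2.5:1:1 tri-axial shape whose volume
  (~100–500 µm³) and digitized sphericity (~0.65–0.85) match reported
  lacunar morphology — with uniformly random orientation.
* `txm_spec()` — a 120³ voxel cube at 0.3 µm spacing (~36 µm of bone) with
  five lacunae, each proposing canalicular links to its three nearest
  neighbours. The canaliculus radius default (0.45 µm) is resolution-driven:
  a tube must span ≥ 3 voxels across to survive digitization, which at
  desk-scale grid sizes puts the phantom tube slightly above the
  anatomical 0.1–0.3 µm radius. It is a configurable parameter, not a
  claim about anatomy.

Placement is rejection sampling: a candidate ellipsoid (inflated by the
minimum gap, default 3 voxels) must lie entirely in bone; canals are
placed before the dense lacunar packing because they span the whole
volume. The gap guarantees that ground-truth rows correspond one-to-one to
26-connected components and that a closing ball cannot bridge two pores.
A candidate canaliculus is dropped if it would pierce a third lacuna or
graze another tube, so accepted tubes touch exactly their two endpoint
lacunae; `pair_adjacency` records them. Exhausting the retry budget raises
an error naming the overcrowded structure class.

Grayscale rendering maps labels through a contrast LUT, convolves with a
Gaussian PSF (reflective boundaries, so the global mean is preserved) and
adds white Gaussian noise. One master seed is split into independent
per-structure-class streams, so identical specs give bit-identical
phantoms.

What the phantoms do **not** emulate: phase-contrast halos and ring
artefacts, beam hardening, screw threads (the implant is a plain
cylinder), curved or branching canaliculi (straight tubes by default),
and partial mineralization gradients. Tests passing on phantoms therefore
validate the measurement chain — segmentation → morphology → metrics —
not robustness to every real-data artefact.

## Micro-scale porosity

`extract_porosity` implements the morphology-only porosity route on a
binary bone label: `clean = open(bone, r_open)`;
`solid = close(clean, r_close)`; `pores = ¬clean ∧ solid`. The closing
must seal the widest pore class to recover it (`r_close` > canal radius;
the pipeline default is 6 voxels for the micro phantom), while cavities
open to the exterior wider than the closing ball are excluded by the AND
step. Because the result depends only on the opened bone, re-extracting
from the cleaned bone reproduces the same pores — the practical
idempotence of the operation. Ball closings legitimately round sharp
90°-corner lines and blind-channel floors; on smooth anatomical geometry
this is negligible, and tests assert it only on open lumina.

`classify_pores` labels 26-connected components and calls a component
vascular iff volume ≥ 1000 µm³ **or** max-Feret/equivalent-diameter ≥ 5
(ties go to vascular). The thresholds are configuration, chosen from the
scale separation between lacunae (~100–500 µm³, compact) and canals (far
larger and elongated). The Feret diameter is computed from the convex
hull only when the bounding-box diagonal — an upper bound on the Feret
diameter — could reach the elongation threshold; otherwise the component
is classified without the hull. Components touching the border are kept
for counting but flagged, and are excluded from shape means.

`build_voi` dilates the implant with the 6-connected unit cross, so *n*
iterations give a shell of exactly *n* voxels — 200 µm for 40 steps at
5 µm — along the axes; an exact-Euclidean mode (`dist ≤ n·spacing`) is
available but off by default. When a VOI is supplied, both the object
counts (by centroid membership) and the BV denominator are restricted to
it.

## Skeletons

Masks are thinned to a 26-connected medial skeleton (3D thinning), then
condensed into a branch graph: nodes are voxels of degree ≠ 2, edges carry
the traversed path and its polyline length. Terminal spurs shorter than a
prune length (a sensible choice is ~2× the tube radius) are removed and
any junction reduced to degree 2 is merged through. Thinning shortens a
tube by roughly its radius at each free end; the straight-tube length
check therefore carries a 5% tolerance.

## Nano-scale LCN morphometry

Segmentation is global thresholding (Otsu default, fixed threshold
configurable) with an explicit polarity flag, since pores are dark in
absorption contrast but can invert in Zernike phase contrast; optional
Gaussian/median denoising runs first. `split_lcn` opens the LCN with a
ball whose radius lies strictly between the canalicular radius and the
smallest lacunar semiaxis; the canaliculi are the LCN minus the lacunae,
so the two masks partition the input exactly. A ground-truth-aware caller
can pass the expected lacuna count and is warned if the opening destroyed
one.

Shape descriptors per component: volume from the voxel count; surface
area from a marching-cubes isosurface of the mask *after a 1-voxel-sigma
Gaussian smoothing* — meshing the raw 0/1 field leaves a staircase surface
~8–9% too large, which would push sphericity of a perfect sphere to ~0.92,
while the smoothed 0.5-level surface is within ~1%. (Voxel-face counting
would be ~50% high and was never an option.) For the canalicular mask,
which is only a few voxels wide, the total-surface smoothing is reduced to
σ = 0.5 so thin tubes are not erased; if smoothing removes a structure
entirely the σ is halved until a surface survives. Sphericity and
smoothness are computed from the same (V, SA) pair, so the algebraic
identity `smoothness × sphericity³ = 1` holds to round-off and is asserted
for every component. Principal axes come from the eigendecomposition of
the voxel-coordinate covariance (semi-axis estimate √(5λ)).

A canaliculus is a skeleton **branch**, not a connected component —
canaliculi meet at junctions, and component-level counting would merge the
network into one object. Mean Ca.SA and Ca.V are totals over the
canalicular mask divided by the branch count (per-canaliculus
normalization). Branch-to-lacuna attachment is distance-based: a branch
counts for a lacuna when its path comes within 3 voxels of it, because
thinning retracts the skeleton from tube ends by about the tube radius and
a literal 1-voxel shell systematically undercounts. Junction density is
the number of degree-≥ 3 nodes per bone volume; LCN/BV is the voxel-count
ratio with containment checked. The Boolean split leaves partial-volume
shells around lacunae inside the canalicular mask; a despeckle filter
(drop canalicular components below 8 voxels, configurable) removes most of
them before skeletonization in the pipeline.

## Distance statistics

Distances are exact Euclidean, voxel centre to voxel centre (a
face-adjacent matrix voxel is at one spacing) — matching the brute-force
all-pairs oracle the tests compare against, with no sub-voxel surface
correction. The cumulative histogram over matrix voxels uses bins of one
voxel width *centred on multiples of the spacing*: grid distances cluster
near those multiples, and offset bins would bias the quantile by half a
bin in near-degenerate cases. Quantiles interpolate linearly between bin
centres and are clamped from below at the smallest distance that carries
mass, so a point-mass distribution returns its own distance for every
q > 0. The matrix is the bone label minus all porosity labels.

## Darcy flow in lacuna pairs

The LCN lumen is treated as a uniform porous medium (permeability
10⁻¹⁸ m², porosity 5%, interstitial-fluid viscosity 8.55 × 10⁻⁴ Pa·s,
density 997 kg m⁻³) rather than as open Stokes flow. The stationary
incompressible problem `∇·(−(k/µ)∇p) = 0` is discretized with voxel
finite volumes on the 6-connected grid — a deliberate substitution for
tetrahedral-mesh FEM that keeps exact geometric correspondence with the
segmentation and desk-scale reproducibility. The fluid density plays no
role in a stationary incompressible solve; it is stored for completeness
and future transient extensions.

Boundary conditions: 300 Pa on the fluid voxels of the inlet face and
0 Pa on the opposite outlet face, both imposed at the half-cell boundary
(transmissibility `2·(k/µ)·h`), which makes an N-voxel channel have the
exact effective length N·h — the closed form `u = kΔp/(µL)` is then
reproduced to round-off at any resolution. All other boundaries and all
matrix faces are zero-flux (the "symmetry" condition). The linear system
(symmetric positive definite) is solved directly (SuperLU) up to 2 × 10⁵
unknowns, and by conjugate gradients beyond; a relative residual above
10⁻¹⁰ is an error. Cell velocities average the two face fluxes per axis,
so walls contribute zero normal velocity; reported speed is |u|
(mean velocity components are available on the field). Seepage velocity
(Darcy/porosity) is a trivial rescale left to the caller.

Pair selection: canalicular 26-connected components touching two lacunae
define candidate pairs; one is drawn uniformly with the given seed. The
solver needs a 6-connected path, so candidates whose thin canaliculus only
touches diagonally are skipped in seeded order until a percolating pair is
found. The sub-volume spans the percolating fluid exactly along the
dominant centroid-to-centroid axis (whose two faces become inlet/outlet,
overridable) and adds a transverse margin. Summaries average pressure and
speed over the connecting-canaliculi voxels and also divide each mean by
the connecting-canaliculi volume, reporting all four numbers.

## Group statistics

`compare_groups` runs Shapiro–Wilk per group (constant groups are flagged
NaN), one-way ANOVA (identical groups are reported as F = 0, p = 1), and
Tukey HSD over all unordered pairs at α = 0.05. Non-normal groups are
flagged but ANOVA still runs; no nonparametric fallback and no
multiple-testing correction across different parameters is applied, by
design. Note that Tukey's adjusted p is guaranteed to be ≥ the unadjusted
p *computed from the pooled ANOVA residual MSE*, not ≥ a two-sample
t-test's p, which uses a different variance estimate.

The power study (`studies.lacunar_density_power_study`) simulates the
two-material design: two groups of five specimens whose true lacunar
densities differ by 40%, each specimen's density drawn log-normally with a
15% coefficient of variation (a realistic within-group spread for
densities measured in small VOIs), then the full phantom → porosity →
density → ANOVA chain. Specimens are 40³ voxels at 2 µm — an 80 µm cube
holding ~25–45 lacunae — which keeps one 100-replicate study at a few
minutes on one CPU while preserving the contrast-to-noise structure of
the design.

## Known limitations

* Thresholding is global; no locally adaptive segmentation or trained
  bone/implant labelling is included — phantom contrast is bimodal by
  construction, and real interfacial gradients would need more.
* The skeleton stand-in is plain thinning + pruning; proprietary
  auto-skeleton tools will differ slightly in junction counts.
* Flow is solved on single lacuna pairs, not the whole network, and is
  stationary: no poroelastic coupling or load cycling.
* Distance statistics are Euclidean, not geodesic within the bone matrix,
  and there is no per-lacuna territory partitioning.
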