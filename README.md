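# lcnpipe

Multiscale analysis of peri-implant bone microarchitecture: micro-CT-scale
bone porosity and density metrics, nano-CT-scale lacunar–canalicular network
(LCN) morphometry, bone-matrix distance statistics, image-based Darcy flow
in lacuna pairs, and the group statistics to compare them — exercised
end-to-end on synthetic 3D phantoms with exact ground truth.

## Who this is for

Bone researchers quantifying how an implant (e.g. a biodegradable Mg alloy
screw vs. a permanent Ti screw) reshapes the surrounding bone at two scales:

* **micro scale** (~µm voxels): osteocyte lacunae and vascular canals as
  pores in the bone matrix, counted inside a peri-implant volume of
  interest (VOI);
* **nano scale** (~tens of nm voxels): the lacunar–canalicular network —
  the fluid space housing osteocytes and their cell processes — segmented
  into lacunae and sub-micron canaliculi.

Raw tomograms for such studies are rarely public, so the package ships a
phantom generator that emulates both scales with known ground truth; every
stage of the pipeline is validated against it.

## The quantities it computes

With `V` a voxel count times the voxel size cubed:

* **BV** = Σ(bone-mask voxels) × (voxel size)³ — bone volume, bone + pores.
* **N.Lc**, **N.Vs** = (number of lacunae | vessels) / BV, in mm⁻³ —
  lacunar / vascular number density, after separating the two porosity
  classes by component labelling (volume/elongation rule).
* **VOI**: the implant mask dilated *n* times with the 6-connected unit
  cross, minus the implant — 40 dilations at 5 µm give the canonical
  200 µm peri-implant shell.
* Per lacuna: **Lc.V**, **Lc.SA** (triangulated isosurface),
  **sphericity** = π¹ᐟ³(6V)²ᐟ³ / SA and **smoothness** = SA³/(36πV²)
  (≥ 1; the inverse cube of sphericity).
* Per specimen: **Ca.SA**, **Ca.V** per canaliculus (a canaliculus = one
  skeleton branch), **N.Ca/Lc.SA** (canaliculi per lacunar surface area),
  **Ca.nodes/BV** (skeleton junction density), **LCN/BV** (LCN porosity).
* **Lc.Dist₅₀ / Ca.Dist₅₀**: the distance within which 50% of the bone
  matrix lies from the nearest lacuna / canaliculus, from the normalized
  cumulative histogram of the exact Euclidean distance map.
* **Darcy flow** in a lacuna pair: stationary `u = −(k/µ)∇p` on the
  voxelized fluid geometry (finite volumes, 6-connected), inlet 300 Pa /
  outlet 0 Pa, symmetry (no-flux) elsewhere; defaults k = 10⁻¹⁸ m²,
  µ = 8.55 × 10⁻⁴ Pa·s, porosity 5%. Mean pressure and speed over the
  connecting canaliculi, raw and normalized by their volume.
* **Group statistics**: Shapiro–Wilk per group, one-way ANOVA, Tukey HSD
  at α = 0.05.

## Worked example

```python
import numpy as np
from skimage.measure import label as cc_label
import lcnpipe as lp

# nano-scale phantom: ~36 µm bone cube, 5 lacunae linked by canaliculi
gray, truth = lp.generate_phantom(lp.txm_spec(seed=2))

mask = lp.segment_lcn(gray, threshold=125, polarity="dark")
lacunae, canaliculi = lp.split_lcn(mask, open_radius=3)
labelled = cc_label(lacunae, connectivity=3)
records = lp.shape_descriptors(labelled, gray.spacing)
print([round(r.sphericity, 3) for r in records])
# [0.817, 0.771, 0.829, 0.804, 0.832]

metrics, _ = lp.compute_lcn_metrics(
    lacunae, canaliculi, np.ones(gray.shape, bool), gray.spacing,
    prune_length=1.0, records=records, min_component_voxels=8)
print(round(metrics.lcn_bv_fraction, 4))   # 0.0172  (LCN/BV)

dom = lp.select_lacuna_pair(labelled, canaliculi, gray.spacing, seed=3)
field = lp.solve_darcy(dom)
summary = lp.summarize_flow(field, dom)
print(f"{summary.mean_pressure_pa:.1f} Pa")  # 203.5 Pa over the connecting canaliculi
```

The sphericities sit in the anatomically expected 0.65–0.85 band for
ellipsoidal lacunae; LCN/BV of ~2% and connecting-canaliculi pressures
between the 0 Pa outlet and 300 Pa inlet are the scales reported for
osteocyte networks.

A straight-channel solve reproduces the closed form `u = kΔp/(µL)`:

```python
dom = lp.channel_domain(n_axial=50, n_cross=5, spacing=1.0)  # 50 µm channel
field = lp.solve_darcy(dom)
print(field.speed()[dom.fluid_mask].mean())  # 7.0175e-09 m/s = kΔp/(µL)
```

There is also a CLI (`lcnpipe phantom|porosity|lcn|distmap|flow|stats|run`)
mirroring these stages, and `lcnpipe run --config pipeline.yaml` for a full
configured pipeline with one master seed.

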