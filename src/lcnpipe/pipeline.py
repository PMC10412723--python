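"""End-to-end pipeline orchestration.

A :class:`PipelineConfig` (YAML-loadable, pydantic-validated) names the
input — a phantom preset or volume files on disk — and the stages to run.
Stages share a context: the porosity stage consumes a bone mask, the LCN
stage produces the lacunae/canaliculi masks consumed by the distance and
flow stages.  All numeric results are collected into one JSON report that
is byte-reproducible for a fixed master seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from skimage.measure import label as cc_label

from . import darcy, distance, io, lcn, phantom, porosity
from .core import BACKGROUND, BONE, IMPLANT, LabelVolume, Volume3D

STAGES = ("porosity", "lcn", "distmap", "flow", "stats")


class PhantomConfig(BaseModel):
    preset: Literal["microct", "txm"] = "microct"
    overrides: dict = Field(default_factory=dict)


class InputConfig(BaseModel):
    gray_path: Optional[str] = None
    labels_path: Optional[str] = None
    spacing: Optional[float] = None


class PorosityConfig(BaseModel):
    open_radius: float = 1.0
    # the closing must seal the widest pore: > max vascular-canal radius
    # (5 voxels for the micro phantom defaults)
    close_radius: float = 6.0
    vol_thresh_um3: float = 1000.0
    elongation_thresh: float = 5.0
    threshold: Optional[float] = None  # None: Otsu on grayscale when needed
    n_dilations: int = 40
    voi_mode: Literal["iterative", "euclidean"] = "iterative"
    use_voi: bool = False


class LcnConfig(BaseModel):
    threshold: Optional[float] = None
    polarity: Literal["dark", "bright"] = "dark"
    open_radius: float = 3.0
    prune_length: Optional[float] = None
    denoise: Optional[Literal["gaussian", "median"]] = None
    despeckle_voxels: int = 8  # drop canalicular specks below this size


class DistmapConfig(BaseModel):
    bin_width: Optional[float] = None


class FlowConfig(BaseModel):
    margin: int = 2
    permeability_m2: float = 1.0e-18
    viscosity_pa_s: float = 8.55e-4
    porosity: float = 0.05
    fluid_density_kg_m3: float = 997.0
    inlet_pressure_pa: float = 300.0
    outlet_pressure_pa: float = 0.0


class StatsConfig(BaseModel):
    input_csv: Optional[str] = None
    group_col: str = "group"
    value_col: str = "value"
    alpha: float = 0.05


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "lcnpipe_out"
    stages: list[Literal["porosity", "lcn", "distmap", "flow", "stats"]] = Field(
        default_factory=lambda: ["porosity"]
    )
    phantom: Optional[PhantomConfig] = None
    input: Optional[InputConfig] = None
    porosity: PorosityConfig = Field(default_factory=PorosityConfig)
    lcn: LcnConfig = Field(default_factory=LcnConfig)
    distmap: DistmapConfig = Field(default_factory=DistmapConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_inputs(config: PipelineConfig) -> None:
    if config.phantom is None and config.input is None:
        raise ValueError("config must define a phantom or an input volume")
    if config.input is not None:
        for p in (config.input.gray_path, config.input.labels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
    if config.stats.input_csv is not None and not Path(config.stats.input_csv).exists():
        raise FileNotFoundError(f"stats input does not exist: {config.stats.input_csv}")
    if "stats" in config.stages and config.stats.input_csv is None:
        raise ValueError("stats stage requires stats.input_csv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a combined report.

    Returns the report dict; also written as ``report.json`` in
    ``config.out_dir`` together with per-stage CSV/JSON/volume outputs.
    """
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages), "parameters": {}}
    ctx: dict = {}

    # --- input -----------------------------------------------------------
    if config.phantom is not None:
        factory = phantom.microct_spec if config.phantom.preset == "microct" else phantom.txm_spec
        overrides = dict(config.phantom.overrides)
        overrides.setdefault("seed", config.seed)
        spec = factory(**overrides)
        gray, truth = phantom.generate_phantom(spec)
        ctx["gray"], ctx["truth"] = gray, truth
        ctx["labels"] = truth.label_volume
        io.write_volume(gray, out / "phantom_gray.nrrd")
        io.write_volume(truth.label_volume, out / "phantom_labels.nrrd")
        truth.lacuna_table.to_csv(out / "phantom_lacunae.csv", index=False)
        report["phantom"] = {
            "preset": config.phantom.preset,
            "n_lacunae_true": truth.n_lacunae,
            "n_vascular_true": len(truth.vascular_table),
            "spacing_um": spec.spacing,
            "grid_shape": list(spec.grid_shape),
        }
    else:
        inp = config.input
        if inp.gray_path:
            ctx["gray"] = io.read_volume(inp.gray_path, "grayscale", spacing=inp.spacing)
        if inp.labels_path:
            ctx["labels"] = io.read_volume(inp.labels_path, "labels", spacing=inp.spacing)

    for stage in config.stages:
        try:
            _STAGE_FN[stage](config, ctx, report, out)
        except Exception as exc:  # keep partial outputs, name the stage
            io.write_json(report, out / "report.json")
            raise PipelineError(stage, exc) from exc

    io.write_json(report, out / "report.json")
    return report


# --- stage implementations -------------------------------------------------


def _bone_mask(config: PipelineConfig, ctx: dict) -> np.ndarray:
    """Solid-bone mask: from labels when available, else by thresholding."""
    if "labels" in ctx:
        return ctx["labels"].data == BONE
    gray = ctx["gray"]
    thr = config.porosity.threshold
    if thr is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(gray.data))
    return gray.data >= thr


def _stage_porosity(config: PipelineConfig, ctx: dict, report: dict, out: Path) -> None:
    p = config.porosity
    spacing = (ctx.get("labels") or ctx["gray"]).spacing
    bone = _bone_mask(config, ctx)
    pores = porosity.extract_porosity(bone, p.open_radius, p.close_radius)
    comps, lac_mask, vas_mask = porosity.classify_pores(
        pores, spacing, p.vol_thresh_um3, p.elongation_thresh
    )
    n_lac = sum(1 for c in comps if c.pore_class == "lacunar")
    n_vas = len(comps) - n_lac
    voi = None
    if p.use_voi and "labels" in ctx:
        implant = ctx["labels"].data == IMPLANT
        voi = porosity.build_voi(implant, p.n_dilations, spacing, mode=p.voi_mode)
        n_lac, n_vas = porosity.count_in_voi(comps, voi)
    dens = porosity.porosity_densities(n_lac, n_vas, bone | pores, spacing, voi)
    porosity.pore_table(comps).to_csv(out / "pore_components.csv", index=False)
    ctx["pores"], ctx["lacunae_mask"], ctx["vascular_mask"] = pores, lac_mask, vas_mask
    report["parameters"]["porosity"] = p.model_dump()
    report["porosity"] = dens.to_dict() | {"n_components": len(comps)}


def _stage_lcn(config: PipelineConfig, ctx: dict, report: dict, out: Path) -> None:
    c = config.lcn
    gray: Volume3D = ctx["gray"]
    mask = lcn.segment_lcn(gray, threshold=c.threshold, polarity=c.polarity, denoise=c.denoise)
    lacunae, canaliculi = lcn.split_lcn(mask, c.open_radius)
    labelled = cc_label(lacunae, connectivity=3)
    records = lcn.shape_descriptors(labelled, gray.spacing)
    bone = (
        ctx["labels"].data != BACKGROUND if "labels" in ctx else np.ones(gray.shape, bool)
    )
    metrics, sk = lcn.compute_lcn_metrics(
        lacunae, canaliculi, bone, gray.spacing, prune_length=c.prune_length,
        records=records, min_component_voxels=c.despeckle_voxels,
    )
    lcn.lacuna_table(records).to_csv(out / "lacuna_records.csv", index=False)
    io.write_json(metrics.to_dict(), out / "lcn_metrics.json")
    ctx.update(
        lcn_mask=mask, lcn_lacunae=lacunae, lcn_canaliculi=canaliculi,
        lcn_records=records, lcn_skeleton=sk, bone_mask_full=bone,
    )
    report["parameters"]["lcn"] = c.model_dump()
    report["lcn"] = metrics.to_dict() | {"n_lacunae": len(records)}


def _stage_distmap(config: PipelineConfig, ctx: dict, report: dict, out: Path) -> None:
    spacing = ctx["gray"].spacing if "gray" in ctx else ctx["labels"].spacing
    lacunae = ctx.get("lcn_lacunae", ctx.get("lacunae_mask"))
    canaliculi = ctx.get("lcn_canaliculi")
    if lacunae is None:
        raise ValueError("distmap stage needs the lcn or porosity stage first")
    bone = ctx.get("bone_mask_full", np.ones(lacunae.shape, bool))
    pores = lacunae.copy()
    if canaliculi is not None:
        pores |= canaliculi
    matrix = bone & ~pores
    res = {}
    for name, target in (("lacunae", lacunae), ("canaliculi", canaliculi)):
        if target is None or not target.any():
            continue
        prof = distance.distance_profile(
            target, matrix, spacing, target_class=name, bin_width=config.distmap.bin_width
        )
        prof.to_frame().to_csv(out / f"distance_profile_{name}.csv", index=False)
        key = "Lc.Dist50_um" if name == "lacunae" else "Ca.Dist50_um"
        res[key] = prof.dist50_um
    report["parameters"]["distmap"] = config.distmap.model_dump()
    report["distmap"] = res


def _stage_flow(config: PipelineConfig, ctx: dict, report: dict, out: Path) -> None:
    fc = config.flow
    spacing = ctx["gray"].spacing if "gray" in ctx else ctx["labels"].spacing
    lacunae = ctx.get("lcn_lacunae")
    canaliculi = ctx.get("lcn_canaliculi")
    if lacunae is None or canaliculi is None:
        raise ValueError("flow stage needs the lcn stage first")
    params = darcy.FlowParams(
        permeability_m2=fc.permeability_m2,
        viscosity_pa_s=fc.viscosity_pa_s,
        porosity=fc.porosity,
        fluid_density_kg_m3=fc.fluid_density_kg_m3,
        inlet_pressure_pa=fc.inlet_pressure_pa,
        outlet_pressure_pa=fc.outlet_pressure_pa,
    )
    domain = darcy.select_lacuna_pair(
        cc_label(lacunae, connectivity=3), canaliculi, spacing,
        seed=config.seed, margin=fc.margin, params=params,
    )
    field = darcy.solve_darcy(domain)
    summary = darcy.summarize_flow(field, domain)
    io.write_json(summary.to_dict() | {"pair_ids": list(domain.pair_ids)}, out / "flow_summary.json")
    io.write_vtk_structured_points(
        out / "flow_field.vtk",
        domain.spacing,
        scalars={"pressure_Pa": field.pressure_pa},
        vectors={"velocity_m_s": field.velocity_m_s},
    )
    report["parameters"]["flow"] = fc.model_dump()
    report["flow"] = summary.to_dict() | {"pair_ids": list(domain.pair_ids)}


def _stage_stats(config: PipelineConfig, ctx: dict, report: dict, out: Path) -> None:
    from . import stats as st

    sc = config.stats
    df = pd.read_csv(sc.input_csv)
    res = st.compare_groups(df, group_col=sc.group_col, value_col=sc.value_col, alpha=sc.alpha)
    io.write_json(res.to_dict(), out / "stats_report.json")
    res.tukey.to_csv(out / "stats_tukey.csv", index=False)
    report["parameters"]["stats"] = sc.model_dump()
    report["stats"] = {"anova_F": res.anova_f, "anova_p": res.anova_p}


_STAGE_FN = {
    "porosity": _stage_porosity,
    "lcn": _stage_lcn,
    "distmap": _stage_distmap,
    "flow": _stage_flow,
    "stats": _stage_stats,
}
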