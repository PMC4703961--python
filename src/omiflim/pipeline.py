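"""End-to-end pipeline: simulate -> fit -> segment -> endpoints -> stats.

The statistics stages run on the study-scale generated endpoint table (the
same shape as the emulated experiment: samples x preparations x treatments x
timepoints, 6 organoids and tens to hundreds of cells per group).  The
image stages — per-pixel decay fitting and segmentation — run on a small,
configurable number of rendered demo scenes per run, since per-pixel fitting
of every organoid image is an interactive, per-image step in practice.
Every run writes its resolved configuration next to its outputs; stage
outputs are cached (a stage whose output files already exist is skipped).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import endpoints as ep
from . import io as fio
from . import stats as st
from . import synthetic as syn
from .flim import FitConfig, fit_cube
from .segmentation import SegmentationConfig, segment_cells

log = logging.getLogger("omiflim.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    seed: int = 0
    # acquisition defaults
    n_bins: int = syn.DEFAULT_N_BINS
    bin_width_ps: float = syn.DEFAULT_BIN_WIDTH_PS
    irf_fwhm_ps: float = syn.DEFAULT_IRF_FWHM_PS
    mean_photons_per_pixel: float = syn.DEFAULT_MEAN_PHOTONS_PER_PIXEL
    # demo imaging stage
    demo_scenes: int = 1
    demo_image_shape: tuple[int, int] = (64, 64)
    demo_cells: int = 5
    demo_cell_radius: tuple[float, float] = (6.0, 9.0)
    # study design
    design: syn.ExperimentDesign = field(default_factory=syn.ExperimentDesign)
    # analysis settings
    fit: FitConfig = field(default_factory=FitConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    omi_scale: bool = True  # center-and-scale vs center-only OMI index
    alpha: float = 0.05
    overwrite: bool = False

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        return enc(self)


def _parse_effects(raw: dict) -> dict:
    out = {}
    for k, v in raw.items():
        sample, prep, treatment, tp = k.split("|")
        out[(sample, prep, treatment, int(tp))] = tuple(float(x) for x in v)
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a JSON document.

    Unknown keys raise; the design's effects use ``"sample|prep|treatment|hr"``
    string keys.  Validation (including presence of the control arm) happens
    at construction, before any compute.
    """
    doc = json.loads(Path(path).read_text())
    kwargs: dict = {}
    for key, val in doc.items():
        if key == "design":
            if "effects" in val:
                val = dict(val, effects=_parse_effects(val["effects"]))
            if "prep_shifts" in val:
                val = dict(val, prep_shifts={
                    tuple(k.split("|")): tuple(v)
                    for k, v in val["prep_shifts"].items()})
            if "baseline" in val:
                val = dict(val, baseline=syn.EndpointBaseline(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in val["baseline"].items()}))
            kwargs["design"] = syn.ExperimentDesign(**val)
        elif key == "fit":
            kwargs["fit"] = FitConfig(**val)
        elif key == "segmentation":
            kwargs["segmentation"] = SegmentationConfig(**val)
        elif key == "demo_image_shape":
            kwargs[key] = tuple(val)
        elif key in {f.name for f in dataclasses.fields(PipelineConfig)}:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PipelineConfig(**kwargs)


def _fresh_done(path: Path, overwrite: bool) -> bool:
    return path.exists() and not overwrite


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the results directory.

    Outputs: ``cubes/*.h5`` (demo scenes), ``maps/*.tiff``, ``labels/*.tiff``,
    ``cells_image.csv`` (endpoints of the imaged demo scenes), ``cells.csv``
    (study-scale endpoint table with OMI index), ``tests.csv``, ``calls.csv``,
    ``concordance.csv`` and ``report.md``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(
        json.dumps(config.resolved(), indent=2))

    irf = syn.make_irf(config.irf_fwhm_ps, config.bin_width_ps, config.n_bins)

    # --- simulate -----------------------------------------------------
    cells_path = out / "cells_raw.csv"
    calls_truth_path = out / "truth_calls.csv"
    if not _fresh_done(cells_path, config.overwrite):
        tables = syn.generate_experiment(config.design)
        tables.cells.to_csv(cells_path, index=False)
        tables.truth_calls.to_csv(calls_truth_path, index=False)
        log.info("simulate: %d cells in %d groups", len(tables.cells),
                 tables.cells.groupby(["sample", "preparation",
                                       "recovery_days", "treatment",
                                       "timepoint_hr"]).ngroups)
    cubes_dir = out / "cubes"
    cubes_dir.mkdir(exist_ok=True)
    scene_paths = []
    for i in range(config.demo_scenes):
        p = cubes_dir / f"scene_{i:02d}.h5"
        scene_paths.append(p)
        if _fresh_done(p, config.overwrite):
            continue
        scene = syn.random_scene(
            config.demo_cells, seed=syn.substream(config.seed, "scene", i),
            image_shape=config.demo_image_shape,
            cell_radius_range=config.demo_cell_radius,
        )
        render = syn.render_scene(
            scene, irf, config.mean_photons_per_pixel,
            seed=syn.substream(config.seed, "render", i),
        )
        fio.write_cube_h5(p, render, irf)

    # --- fit + segment + endpoints on the demo scenes -----------------
    maps_dir = out / "maps"
    labels_dir = out / "labels"
    maps_dir.mkdir(exist_ok=True)
    labels_dir.mkdir(exist_ok=True)
    image_cells = []
    for i, p in enumerate(scene_paths):
        nadh_map_p = maps_dir / f"scene_{i:02d}_nadh.ome.tiff"
        fad_map_p = maps_dir / f"scene_{i:02d}_fad.ome.tiff"
        labels_p = labels_dir / f"scene_{i:02d}.ome.tiff"
        nadh, fad, irf_r, _, _ = fio.read_cube_h5(p)
        if not _fresh_done(nadh_map_p, config.overwrite):
            fio.write_param_maps(
                nadh_map_p,
                fit_cube(nadh, irf_r, dataclasses.replace(config.fit,
                                                          channel="nadh")))
            log.info("fit: %s nadh done", p.name)
        if not _fresh_done(fad_map_p, config.overwrite):
            fio.write_param_maps(
                fad_map_p,
                fit_cube(fad, irf_r, dataclasses.replace(config.fit,
                                                         channel="fad")))
            log.info("fit: %s fad done", p.name)
        maps_nadh = fio.read_param_maps(nadh_map_p)
        maps_fad = fio.read_param_maps(fad_map_p)
        if not _fresh_done(labels_p, config.overwrite):
            fio.write_labels(labels_p,
                             segment_cells(maps_nadh.intensity,
                                           config.segmentation))
        labels = fio.read_labels(labels_p)
        redox = ep.redox_image(maps_nadh.intensity, maps_fad.intensity)
        image_cells.append(ep.per_cell_endpoints(
            maps_nadh, maps_fad, redox, labels,
            group_key={"scene": i}, organoid_id=i))
    if image_cells:
        pd.concat(image_cells, ignore_index=True).to_csv(
            out / "cells_image.csv", index=False)

    # --- OMI index + statistics on the study table --------------------
    cells = pd.read_csv(cells_path)
    cells = ep.omi_index(cells,
                         control_treatment=config.design.control_treatment,
                         scale=config.omi_scale)
    cells.to_csv(out / "cells.csv", index=False)

    all_tests, all_calls = [], []
    for (sample, prep, days), sub in cells.groupby(
            ["sample", "preparation", "recovery_days"]):
        tests, calls = st.drug_response_timecourse(
            sub, control=config.design.control_treatment, alpha=config.alpha)
        for df in (tests, calls):
            df.insert(0, "sample", sample)
            df.insert(1, "preparation", prep)
            df.insert(2, "recovery_days", days)
        all_tests.append(tests)
        all_calls.append(calls)
    tests = pd.concat(all_tests, ignore_index=True)
    calls = pd.concat(all_calls, ignore_index=True)
    tests.to_csv(out / "tests.csv", index=False)
    calls.to_csv(out / "calls.csv", index=False)

    fresh = calls[calls["preparation"] == "fresh"]
    frozen = calls[calls["preparation"] != "fresh"]
    if len(fresh) and len(frozen):
        conc = st.concordance(fresh, frozen)
        conc.rows.to_csv(out / "concordance.csv", index=False)
        summary = conc.by_preparation
        summary.to_csv(out / "concordance_summary.csv", index=False)
    else:
        conc = None

    _write_report(out, calls, conc)
    log.info("pipeline complete: %s", out)
    return out


def _write_report(out: Path, calls: pd.DataFrame, conc) -> None:
    lines = ["# OMI drug-response report", "",
             "## Response calls (vs time-matched control)", ""]
    grid = calls.pivot_table(
        index=["sample", "preparation", "recovery_days", "treatment"],
        columns="timepoint_hr", values="call", aggfunc="first")
    lines.append(grid.to_markdown())
    if conc is not None:
        lines += ["", "## Fresh-vs-frozen concordance", "",
                  f"Discordant: {conc.n_discordant}/{conc.n_total} "
                  f"({100 * conc.inconsistency_fraction:.1f}%)", "",
                  conc.by_preparation.to_markdown(index=False)]
    (out / "report.md").write_text("\n".join(lines) + "\n")
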