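"""Study-scale validation experiments.

Each function reproduces one of the package's headline checks from scratch —
generating its own synthetic inputs, running the pipeline stage under test,
and measuring the result.  They are used by the test suite and by
``scripts/acceptance.py``; problem sizes default to the scales the checks
are quoted at.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import flim
from . import stats as st
from . import synthetic as syn
from .reference import reference_calls_72hr
from .segmentation import segment_cells
from .types import DecayParams

__all__ = [
    "concordance_worked_example", "fit_recovery_benchmark",
    "omi_normalization_benchmark", "type_i_calibration",
    "end_to_end_recovery", "segmentation_benchmark",
]


def concordance_worked_example() -> tuple[int, int]:
    """Discordant / total 72-hr calls for the six 7-day frozen preparations
    scored against their fresh counterparts (published worked example)."""
    fresh, frozen = reference_calls_72hr()
    conc = st.concordance(fresh, frozen,
                          scope={"timepoint_hr": 72, "recovery_days": 7})
    return conc.n_discordant, conc.n_total


def fit_recovery_benchmark(
    seed: int = 0, n_sims: int = 100, n_oracle: int = 20,
    photons: float = 5e3,
) -> dict:
    """Recovery of the canonical NAD(P)H decay (tau_m = 0.95 ns) at the
    stated photon budget, plus chi-square optimality against the exhaustive
    grid reference (both minimizing the same data-weighted objective)."""
    irf = syn.make_irf()
    p = DecayParams.make(0.75, 0.4, 2.6)
    truth = flim.mean_lifetime(p)
    rng = syn.substream(seed, "fit-recovery")
    errs = []
    for _ in range(n_sims):
        sim = syn.simulate_decay(p, irf, photons, seed=rng)
        fit = flim.fit_decay(sim.counts, irf)
        errs.append(abs(fit.tau_m - truth) / truth)
    cfg = flim.FitConfig(reweight_passes=1)
    ratios = []
    for _ in range(n_oracle):
        sim = syn.simulate_decay(p, irf, photons, seed=rng)
        fit = flim.fit_decay(sim.counts, irf, config=cfg)
        grid = flim.grid_fit_decay(sim.counts, irf)
        ratios.append(fit.chi2_reduced / grid.chi2_reduced)
    return {
        "tau_m_true_ns": truth,
        "median_rel_err": float(np.median(errs)),
        "max_chi2_ratio": float(np.max(ratios)),
        "n_sims": n_sims,
        "n_oracle": n_oracle,
    }


def omi_normalization_benchmark(
    seed: int = 0, n_cells: int = 1000, replicates: int = 20
) -> dict:
    """Mean OMI index of a matched control group (0 by construction) and of
    a population shifted (-1, -1, +1) control-SD on the three endpoints
    (expected -3), at ``n_cells`` cells per group, averaged over
    replicate experiments."""
    ctrl_means, shift_means = [], []
    for r in range(replicates):
        with warnings.catch_warnings():
            # n_cells=1000 deliberately exceeds the emulated 30-300 range
            warnings.simplefilter("ignore", UserWarning)
            design = syn.ExperimentDesign(
                samples=("S1",), preparations=("fresh",),
                treatments=("control", "drug"), timepoints_hr=(24,),
                organoids_per_group=10, cells_per_organoid=n_cells // 10,
                effects={("S1", "fresh", "drug", 24): (-1.0, -1.0, 1.0)},
                seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                         % 2**31),
            )
            cells = syn.generate_experiment(design).cells
        out = ep.omi_index(cells)
        g = out.groupby("treatment")["omi_index"].mean()
        ctrl_means.append(g["control"])
        shift_means.append(g["drug"])
    return {
        "control_mean": float(np.mean(ctrl_means)),
        "max_abs_control_mean": float(np.max(np.abs(ctrl_means))),
        "shifted_mean": float(np.mean(shift_means)),
        "n_cells": n_cells,
        "replicates": replicates,
    }


def type_i_calibration(seed: int = 0, replicates: int = 1000) -> dict:
    """Null rejection rates at alpha = 0.05 for the Tukey-adjusted response
    caller, the Kruskal-Wallis test, and the D'Agostino-Pearson normality
    test.

    The caller is calibrated on the smallest design it supports (control
    plus one treatment at two timepoints, 30 cells/group), where the
    studentized range with two groups reduces to the two-sample comparison
    and the nominal per-comparison rate applies.
    """
    rng = syn.substream(seed, "calibration")

    hits = total = 0
    for _ in range(replicates):
        rows = [pd.DataFrame({"treatment": tr, "timepoint_hr": tp,
                              "omi_index": rng.normal(0.0, 1.0, 30)})
                for tr in ("control", "drug") for tp in (24, 48)]
        _, calls = st.drug_response_timecourse(
            pd.concat(rows, ignore_index=True))
        hits += int((calls["call"] != "none").sum())
        total += len(calls)
    tukey_rate = hits / total

    kw_hits = 0
    for _ in range(replicates):
        groups = {g: rng.normal(0.0, 1.0, 20) for g in ("a", "b", "c")}
        res = st.compare_morphology_groups(groups)
        kw_hits += res.iloc[0]["p_raw"] < 0.05
    kw_rate = kw_hits / replicates

    norm_hits = 0
    for _ in range(replicates):
        _, p = st.test_normality(rng.normal(0.0, 1.0, 10_000))
        norm_hits += p < 0.05
    norm_rate = norm_hits / replicates

    return {"tukey_caller": tukey_rate, "kruskal_wallis": kw_rate,
            "normality": norm_rate, "replicates": replicates}


def _study_effects(seed: int, samples, preps, drugs, timepoints):
    """Deterministic assignment of treatment effects (in control-SD units)
    over a full design; every non-null arm shifts the OMI index by at least
    1.5 units, mixed with genuine nulls."""
    palette = [(-1.0, -1.0, 1.0), (-0.5, -0.5, 0.5), (0.0, 0.0, 0.0),
               (0.5, 0.5, -0.5)]
    rng = syn.substream(seed, "effects")
    effects = {}
    for s in samples:
        for p in preps:
            for d in drugs:
                for tp in timepoints:
                    effects[(s, p, d, tp)] = palette[int(rng.integers(4))]
    return effects


def end_to_end_recovery(seed: int = 0, cells_per_group: int = 180) -> dict:
    """Fraction of ground-truth response calls recovered on a full
    2-sample x 3-preparation x 4-treatment x 3-timepoint experiment."""
    samples = ("S1", "S2")
    preps = ("fresh", "flash_frozen", "dmso_frozen")
    treatments = ("control", "drug_A", "drug_B", "drug_C", "combo")
    timepoints = (24, 48, 72)
    design = syn.ExperimentDesign(
        samples=samples, preparations=preps, treatments=treatments,
        timepoints_hr=timepoints, organoids_per_group=6,
        cells_per_organoid=cells_per_group // 6,
        effects=_study_effects(seed, samples, preps, treatments[1:],
                               timepoints),
        seed=seed,
    )
    tables = syn.generate_experiment(design)
    cells = ep.omi_index(tables.cells)
    all_calls = []
    for (sample, prep, days), sub in cells.groupby(
            ["sample", "preparation", "recovery_days"]):
        _, calls = st.drug_response_timecourse(sub)
        calls.insert(0, "sample", sample)
        calls.insert(1, "preparation", prep)
        calls.insert(2, "recovery_days", days)
        all_calls.append(calls)
    calls = pd.concat(all_calls, ignore_index=True)
    merged = calls.merge(
        tables.truth_calls,
        on=["sample", "preparation", "recovery_days", "treatment",
            "timepoint_hr"], suffixes=("", "_truth"))
    assert len(merged) == len(tables.truth_calls)
    frac = float((merged["call"] == merged["call_truth"]).mean())
    return {"recovered_fraction": frac, "n_calls": len(merged),
            "cells_per_group": cells_per_group}


def segmentation_benchmark(seed: int = 0, n_scenes: int = 50) -> dict:
    """Cell-count accuracy and matched IoU over random organoid scenes of
    5-50 cells at the default acquisition scale."""
    rng = syn.substream(seed, "segmentation")
    n_true = n_pred = 0
    ious = []
    for i in range(n_scenes):
        k = int(rng.integers(5, 51))
        scene = syn.random_scene(k, seed=rng, max_tries=50_000)
        img, truth = syn.render_intensity_image(scene, seed=rng)
        pred = segment_cells(img)
        n_true += truth.n_cells
        n_pred += pred.n_cells
        for lbl in truth.labels:
            tmask = truth.cell_labels == lbl
            labs, cnts = np.unique(pred.cell_labels[tmask],
                                   return_counts=True)
            keep = labs > 0
            labs, cnts = labs[keep], cnts[keep]
            if labs.size == 0:
                ious.append(0.0)
                continue
            pmask = pred.cell_labels == labs[np.argmax(cnts)]
            ious.append(float((tmask & pmask).sum() / (tmask | pmask).sum()))
    return {
        "count_accuracy": 1.0 - abs(n_pred - n_true) / n_true,
        "mean_iou": float(np.mean(ious)),
        "n_scenes": n_scenes,
        "n_cells_true": n_true,
        "n_cells_pred": n_pred,
    }
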