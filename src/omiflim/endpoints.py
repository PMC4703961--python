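"""Per-cell OMI endpoints and the control-normalized OMI index.

The optical redox ratio (NAD(P)H intensity / FAD intensity), the NAD(P)H
mean lifetime and the FAD mean lifetime are treated as independent measures
of cellular metabolism; the OMI index combines them per cell as

    omi_index = z(redox) + z(NAD(P)H tau_m) - z(FAD tau_m)

where z(.) centers an endpoint on the matched control-group mean and (by
default) scales by the matched control-group SD.  Control matching is
time-matched within (sample, preparation, recovery_days): drug response is
always read against the same-time control arm.  A decrease in the OMI index
indicates drug response.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .flim import ParamMaps
from .segmentation import LabelMaps, morphology_metrics

__all__ = ["redox_image", "per_cell_endpoints", "omi_index",
           "GROUP_COLS", "OMI_ENDPOINTS"]

log = logging.getLogger(__name__)

GROUP_COLS = ("sample", "preparation", "recovery_days", "timepoint_hr")
#: endpoint -> OMI-index coefficient
OMI_ENDPOINTS = {"redox_ratio": 1.0, "nadh_tau_m": 1.0, "fad_tau_m": -1.0}


def redox_image(
    nadh_intensity_map: np.ndarray,
    fad_intensity_map: np.ndarray,
    fad_floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise NAD(P)H / FAD intensity ratio with a validity mask.

    Pixels whose FAD counts fall below ``fad_floor`` are invalid (the ratio
    diverges) and must be excluded from any average.
    """
    nadh = np.asarray(nadh_intensity_map, dtype=float)
    fad = np.asarray(fad_intensity_map, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError("intensity maps must share one shape")
    valid = fad >= fad_floor
    ratio = np.full(nadh.shape, np.nan)
    np.divide(nadh, fad, out=ratio, where=valid)
    return ratio, valid


def per_cell_endpoints(
    param_maps_nadh: ParamMaps,
    param_maps_fad: ParamMaps,
    redox: tuple[np.ndarray, np.ndarray] | np.ndarray,
    labels: LabelMaps,
    group_key: Optional[Mapping[str, object]] = None,
    region: str = "cytoplasm",
    organoid_id: int | str = 0,
) -> pd.DataFrame:
    """Average every endpoint over each cell's measurement region.

    ``region`` selects the pixels averaged (default the cytoplasm, since the
    coenzymes are extranuclear; ``"cell"`` uses the whole cell).  Only
    unmasked pixels — fit succeeded, redox valid — contribute; cells with no
    usable pixel are dropped and counted in the log.
    """
    if region not in ("cytoplasm", "cell"):
        raise ValueError("region must be 'cytoplasm' or 'cell'")
    if isinstance(redox, tuple):
        redox_map, redox_valid = redox
    else:
        redox_map = np.asarray(redox, dtype=float)
        redox_valid = np.isfinite(redox_map)
    for m in (param_maps_fad.alpha1, redox_map, labels.cell_labels):
        if m.shape != param_maps_nadh.shape:
            raise ValueError("maps and labels must share one shape")

    region_labels = (labels.cytoplasm_labels if region == "cytoplasm"
                     else labels.cell_labels)
    morph, _ = morphology_metrics(labels, organoid_id=organoid_id)

    fields = {
        "nadh_intensity": (param_maps_nadh.intensity, ~param_maps_nadh.mask),
        "fad_intensity": (param_maps_fad.intensity, ~param_maps_fad.mask),
        "redox_ratio": (redox_map, redox_valid),
        "nadh_tau_m": (param_maps_nadh.tau_m, ~param_maps_nadh.mask),
        "nadh_alpha1": (param_maps_nadh.alpha1, ~param_maps_nadh.mask),
        "nadh_tau1": (param_maps_nadh.tau1, ~param_maps_nadh.mask),
        "nadh_tau2": (param_maps_nadh.tau2, ~param_maps_nadh.mask),
        "fad_tau_m": (param_maps_fad.tau_m, ~param_maps_fad.mask),
        "fad_alpha1": (param_maps_fad.alpha1, ~param_maps_fad.mask),
        "fad_tau1": (param_maps_fad.tau1, ~param_maps_fad.mask),
        "fad_tau2": (param_maps_fad.tau2, ~param_maps_fad.mask),
    }
    rows = []
    dropped = 0
    for k in labels.labels:
        in_region = region_labels == k
        row: dict[str, object] = {"cell_id": int(k), "organoid_id": organoid_id}
        usable = 0
        for name, (img, ok) in fields.items():
            sel = in_region & ok & np.isfinite(img)
            if sel.any():
                row[name] = float(img[sel].mean())
                usable += int(sel.sum())
            else:
                row[name] = np.nan
        if usable == 0:
            dropped += 1
            continue
        rows.append(row)
    if dropped:
        log.info("per_cell_endpoints: dropped %d cells with no usable pixels",
                 dropped)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["cell_id", "organoid_id", *fields])
    df = df.merge(morph.drop(columns=["organoid_id"]), on="cell_id",
                  how="left")
    if group_key:
        for i, (key, val) in enumerate(group_key.items()):
            df.insert(i, key, val)
    return df


def omi_index(
    cells: pd.DataFrame,
    control_treatment: str = "control",
    scale: bool = True,
    group_cols: Sequence[str] = GROUP_COLS,
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Fill the per-cell OMI index, normalized to the matched control group.

    For every group (same ``group_cols``, i.e. same sample, preparation,
    recovery and timepoint) the control arm's mean and SD of each endpoint
    define the standardization; the index is the (+1, +1, -1) combination of
    the standardized redox ratio, NAD(P)H tau_m and FAD tau_m.  With
    ``scale=False`` endpoints are centered only.  The control group's mean
    OMI index is exactly 0 by construction.

    Raises ``KeyError`` naming the group when a matched control is missing.
    """
    group_cols = [c for c in group_cols if c in cells.columns]
    out = cells.copy()
    out["omi_index"] = np.nan
    grouped = out.groupby(group_cols, sort=False) if group_cols \
        else [((), out)]
    for key, sub in grouped:
        ctrl = sub[sub[treatment_col] == control_treatment]
        if ctrl.empty:
            raise KeyError(
                f"no control arm ({control_treatment!r}) for group "
                f"{dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))}"
            )
        z = np.zeros(len(sub))
        for name, coef in OMI_ENDPOINTS.items():
            mu = ctrl[name].mean()
            sd = ctrl[name].std(ddof=1) if scale else 1.0
            if scale and (not np.isfinite(sd) or sd == 0):
                raise ValueError(
                    f"control SD of {name} is zero/undefined for group {key}"
                )
            z += coef * (sub[name].to_numpy() - mu) / sd
        out.loc[sub.index, "omi_index"] = z
    return out
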