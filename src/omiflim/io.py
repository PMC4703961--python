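"""File formats: HDF5 photon cubes, OME-TIFF maps/labels, CSV tables.

HDF5 cube layout
----------------
::

    /nadh/counts   uint32 (y, x, t)
    /fad/counts    uint32 (y, x, t)
    /irf/samples   float64 (t,)
    /truth/cell_labels, /truth/nucleus_labels, /truth/cytoplasm_labels
    /truth/cells   (CSV-serialized per-cell table, stored as bytes)

with root attributes ``bin_width_ps``, ``n_bins``, ``pixel_size_um`` and
``irf_fwhm_ps``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

from .flim import ParamMaps
from .segmentation import LabelMaps
from .synthetic import SceneRender
from .types import FlimCube, IrfKernel

__all__ = ["write_cube_h5", "read_cube_h5", "write_param_maps",
           "read_param_maps", "write_labels", "read_labels"]

_MAP_PAGES = ("alpha1", "tau1", "tau2", "tau_m", "intensity", "chi2",
              "bin_radius")


def write_cube_h5(path: str | Path, render: SceneRender,
                  irf: IrfKernel) -> None:
    """Write a rendered scene (both channels + ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["bin_width_ps"] = irf.bin_width_ps
        f.attrs["n_bins"] = irf.n_bins
        f.attrs["pixel_size_um"] = render.nadh.pixel_size_um
        f.attrs["irf_fwhm_ps"] = irf.fwhm_ps
        for name, cube in (("nadh", render.nadh), ("fad", render.fad)):
            g = f.create_group(name)
            g.create_dataset("counts", data=cube.counts.astype(np.uint32),
                             compression="gzip")
        f.create_dataset("irf/samples", data=irf.samples)
        t = f.create_group("truth")
        lm = render.truth_labels
        t.create_dataset("cell_labels", data=lm.cell_labels)
        t.create_dataset("nucleus_labels", data=lm.nucleus_labels)
        t.create_dataset("cytoplasm_labels", data=lm.cytoplasm_labels)
        t.create_dataset(
            "cells",
            data=np.void(render.truth_cells.to_csv(index=False).encode()),
        )


def read_cube_h5(
    path: str | Path,
) -> tuple[FlimCube, FlimCube, IrfKernel, Optional[LabelMaps],
           Optional[pd.DataFrame]]:
    """Read both channels, the IRF and any ground truth from HDF5."""
    with h5py.File(path, "r") as f:
        bw = float(f.attrs["bin_width_ps"])
        px = float(f.attrs["pixel_size_um"])
        fwhm = float(f.attrs.get("irf_fwhm_ps", 260.0))
        cubes = {}
        for name in ("nadh", "fad"):
            cubes[name] = FlimCube(counts=f[name]["counts"][...],
                                   bin_width_ps=bw, pixel_size_um=px,
                                   channel=name)
        irf = IrfKernel(samples=f["irf/samples"][...], bin_width_ps=bw,
                        fwhm_ps=fwhm)
        labels = None
        cells = None
        if "truth" in f:
            t = f["truth"]
            labels = LabelMaps(
                cell_labels=t["cell_labels"][...],
                nucleus_labels=t["nucleus_labels"][...],
                cytoplasm_labels=t["cytoplasm_labels"][...],
                pixel_size_um=px,
            )
            if "cells" in t:
                import io as _io
                cells = pd.read_csv(_io.BytesIO(t["cells"][()].tobytes()))
    return cubes["nadh"], cubes["fad"], irf, labels, cells


def write_param_maps(path: str | Path, maps: ParamMaps,
                     fit_config: Optional[dict] = None) -> None:
    """Write fitted maps as a multi-page OME-TIFF plus a JSON sidecar.

    Masked pixels hold NaN in every parameter page; page order is recorded
    in the sidecar and in the page names.
    """
    path = Path(path)
    pages = [np.asarray(getattr(maps, name), dtype=np.float32)
             for name in _MAP_PAGES]
    pages.append(maps.mask.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), ome=True,
                     metadata={"axes": "CYX",
                               "Channel": {"Name": [*_MAP_PAGES, "mask"]}})
    sidecar = {
        "channel": maps.channel,
        "pages": [*_MAP_PAGES, "mask"],
        "fit_config": fit_config or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_param_maps(path: str | Path) -> ParamMaps:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = sidecar["pages"]
    data = {n: stack[i] for i, n in enumerate(names)}
    return ParamMaps(
        alpha1=data["alpha1"], tau1=data["tau1"], tau2=data["tau2"],
        tau_m=data["tau_m"], intensity=data["intensity"], chi2=data["chi2"],
        mask=data["mask"] > 0.5, bin_radius=data["bin_radius"],
        channel=sidecar.get("channel", "nadh"),
    )


def write_labels(path: str | Path, labels: LabelMaps) -> None:
    """Label maps as a 3-page 16-bit TIFF (cells, nuclei, cytoplasms)."""
    stack = np.stack([labels.cell_labels, labels.nucleus_labels,
                      labels.cytoplasm_labels]).astype(np.uint16)
    tifffile.imwrite(path, stack, ome=True, metadata={"axes": "CYX"})
    Path(path).with_suffix(".json").write_text(
        json.dumps({"pixel_size_um": labels.pixel_size_um,
                    "pages": ["cell", "nucleus", "cytoplasm"]})
    )


def read_labels(path: str | Path) -> LabelMaps:
    stack = tifffile.imread(path).astype(np.int32)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return LabelMaps(cell_labels=stack[0], nucleus_labels=stack[1],
                     cytoplasm_labels=stack[2],
                     pixel_size_um=float(meta["pixel_size_um"]))
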