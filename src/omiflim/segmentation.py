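"""Cell / nucleus / cytoplasm segmentation of NAD(P)H intensity images.

NAD(P)H autofluorescence is cytoplasmic and mitochondrial, so nuclei appear
as dim, roughly convex regions inside a brighter cell body, and the organoid
sits on a dark background.  Segmentation therefore proceeds:

1. foreground by automatic (Otsu) threshold on a smoothed image, holes
   (the dim nuclei) filled;
2. nuclei as the dim class inside the (eroded) foreground, by a second Otsu
   split restricted to foreground pixels;
3. cells as foreground connected components, split between multiple nuclei
   by a watershed flooded from the nucleus seeds (distance-to-nucleus
   elevation, so touching cells divide midway between their nuclei);
4. size filters; cytoplasm = cell minus nucleus.

Everything is deterministic.  One image is treated as one organoid for the
cells-per-organoid endpoint (the acquisition design images one plane per
organoid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, erosion, remove_small_objects
from skimage.segmentation import watershed

__all__ = ["LabelMaps", "SegmentationConfig", "segment_cells",
           "morphology_metrics"]


@dataclass
class LabelMaps:
    """Integer masks for cells, nuclei and cytoplasms in one organoid image.

    Invariants: nucleus k is contained in cell k, cytoplasm k = cell k minus
    nucleus k, background is 0, and the three maps carry the same label set.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self):
        for m in (self.cell_labels, self.nucleus_labels, self.cytoplasm_labels):
            if m.shape != self.cell_labels.shape:
                raise ValueError("label maps must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def from_cells_and_nuclei(
        cls, cell_labels: np.ndarray, nucleus_labels: np.ndarray,
        pixel_size_um: float = 0.5,
    ) -> "LabelMaps":
        """Build the triple from cell and nucleus maps, enforcing containment
        (nucleus pixels outside their cell are dropped; nuclei are re-labeled
        to match their cell id)."""
        nuc = np.where(nucleus_labels > 0, cell_labels, 0)
        cyto = np.where(nuc > 0, 0, cell_labels)
        return cls(cell_labels=cell_labels.astype(np.int32),
                   nucleus_labels=nuc.astype(np.int32),
                   cytoplasm_labels=cyto.astype(np.int32),
                   pixel_size_um=pixel_size_um)

    @property
    def labels(self) -> np.ndarray:
        lbl = np.unique(self.cell_labels)
        return lbl[lbl > 0]

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)

    def validate(self) -> None:
        for k in self.labels:
            cell = self.cell_labels == k
            nuc = self.nucleus_labels == k
            cyto = self.cytoplasm_labels == k
            if np.any(nuc & ~cell):
                raise ValueError(f"nucleus {k} leaks outside its cell")
            if np.any(cyto != (cell & ~nuc)):
                raise ValueError(f"cytoplasm {k} != cell minus nucleus")


@dataclass
class SegmentationConfig:
    pixel_size_um: float = 0.5
    smooth_sigma: float = 2.0
    min_cell_area_px: int = 30
    min_nucleus_area_px: int = 12
    rim_erosion_px: int = 3  # keeps the dim cell rim out of the nucleus class


def segment_cells(
    nadh_intensity_image: np.ndarray,
    config: Optional[SegmentationConfig] = None,
) -> LabelMaps:
    """Segment an NAD(P)H intensity image into cells, nuclei and cytoplasms.

    Returns empty (all-zero) label maps for blank or flat images rather than
    raising.
    """
    config = config or SegmentationConfig()
    img = np.asarray(nadh_intensity_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if np.any(img < 0):
        raise ValueError("intensity image must be nonnegative")

    empty = LabelMaps.from_cells_and_nuclei(
        np.zeros(img.shape, dtype=np.int32),
        np.zeros(img.shape, dtype=np.int32),
        pixel_size_um=config.pixel_size_um,
    )
    if img.max() <= 0 or np.ptp(img) == 0:
        return empty

    sm = gaussian(img, sigma=config.smooth_sigma, preserve_range=True)
    try:
        thr = threshold_otsu(sm)
    except ValueError:  # single-valued image after smoothing
        return empty
    fg = sm > thr
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=config.min_cell_area_px - 1)
    if not fg.any():
        return empty

    # nuclei: dim class within the eroded foreground
    interior = erosion(fg, disk(config.rim_erosion_px))
    vals = sm[fg]
    try:
        nuc_thr = threshold_otsu(vals)
    except ValueError:
        nuc_thr = -np.inf
    nuclei_mask = interior & (sm < nuc_thr)
    nuclei_mask = remove_small_objects(
        nuclei_mask, max_size=config.min_nucleus_area_px - 1)
    nucleus_seeds = sk_label(nuclei_mask)
    if nucleus_seeds.max() == 0:
        return empty

    # cells: flood foreground from the nucleus seeds; components with several
    # nuclei split midway between them
    elevation = ndi.distance_transform_edt(~nuclei_mask)
    cells = watershed(elevation, markers=nucleus_seeds, mask=fg)

    # size filter and consecutive relabeling
    keep = np.zeros(cells.max() + 1, dtype=np.int32)
    next_id = 0
    for r in regionprops(cells):
        if r.area >= config.min_cell_area_px:
            next_id += 1
            keep[r.label] = next_id
    cells = keep[cells]
    return LabelMaps.from_cells_and_nuclei(
        cells, np.where(nuclei_mask, cells, 0),
        pixel_size_um=config.pixel_size_um,
    )


def morphology_metrics(
    labels: LabelMaps, organoid_id: int | str = 0
) -> tuple[pd.DataFrame, int]:
    """Per-cell morphology endpoints and the cells-per-organoid count.

    cell_area is pixel count times pixel_size^2 (um^2); nucleus_diameter is
    the nucleus region's major-axis length times pixel_size (um), automating
    the longest-axis-through-the-nucleus measurement; ncr is nucleus area
    over cytoplasm area.  Cells whose cytoplasm is empty are flagged
    (``ncr_valid`` False) and should be excluded from NCR summaries.
    """
    px = labels.pixel_size_um
    cell_props = {r.label: r for r in regionprops(labels.cell_labels)}
    nuc_props = {r.label: r for r in regionprops(labels.nucleus_labels)}
    cyto_areas = {r.label: r.area for r in regionprops(labels.cytoplasm_labels)}

    rows = []
    for k, cp in sorted(cell_props.items()):
        np_ = nuc_props.get(k)
        nuc_area = float(np_.area) if np_ is not None else 0.0
        cyto_area = float(cyto_areas.get(k, 0.0))
        rows.append({
            "cell_id": k,
            "organoid_id": organoid_id,
            "cell_area_um2": float(cp.area) * px * px,
            "nucleus_diameter_um": (
                float(np_.axis_major_length) * px if np_ is not None else np.nan
            ),
            "ncr": nuc_area / cyto_area if cyto_area > 0 else np.nan,
            "ncr_valid": cyto_area > 0,
        })
    df = pd.DataFrame(
        rows, columns=["cell_id", "organoid_id", "cell_area_um2",
                       "nucleus_diameter_um", "ncr", "ncr_valid"],
    )
    return df, len(rows)
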