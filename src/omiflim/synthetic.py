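"""Ground-truthed synthetic FLIM organoid experiments.

Generates everything the downstream stages consume, at the scale of the
emulated acquisition: 256 x 256 pixel two-channel (NAD(P)H, FAD) TCSPC photon
cubes over a 12.5 ns window (80 MHz repetition) in 256 bins of 48.8 ps, a
Gaussian instrument response of 260 ps FWHM, organoid scenes of 5-50 cells
with dark nuclei on brighter cytoplasm, and multi-arm drug studies with 6
organoids and 30-300 cells per treatment group.  Every output carries its
ground truth (labels, per-cell endpoints, expected response calls), so the
fitting, segmentation and statistics stages are testable without any
acquired data.

The default photon budget of ~458 photons/pixel is the printed acquisition
scale: a sustained count rate of 5e5 photons/s over a 60 s frame spread over
256^2 pixels.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import flim
from .segmentation import LabelMaps, morphology_metrics
from .types import DecayParams, FlimCube, IrfKernel

__all__ = [
    "DEFAULT_N_BINS", "DEFAULT_BIN_WIDTH_PS", "DEFAULT_IRF_FWHM_PS",
    "DEFAULT_MEAN_PHOTONS_PER_PIXEL",
    "make_irf", "simulate_decay", "SimulatedDecay",
    "CellSpec", "SceneSpec", "random_scene", "rasterize_scene",
    "render_scene", "render_intensity_image", "SceneRender",
    "EndpointBaseline", "ExperimentDesign", "ExperimentTables",
    "generate_experiment", "substream",
]

DEFAULT_N_BINS = 256
DEFAULT_BIN_WIDTH_PS = 48.8          # 12.5 ns window / 256 bins (80 MHz)
DEFAULT_IRF_FWHM_PS = 260.0
# printed acquisition scale: 5e5 counts/s * 60 s / 256^2 pixels
DEFAULT_MEAN_PHOTONS_PER_PIXEL = 5e5 * 60.0 / (256 * 256)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed.

    Stage and group names are hashed (CRC-32) into the seed sequence so each
    stage gets an independent stream regardless of call order.
    """
    hashes = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + hashes))


# ---------------------------------------------------------------------------
# IRF and single-decay simulation


def make_irf(
    fwhm_ps: float = DEFAULT_IRF_FWHM_PS,
    bin_width_ps: float = DEFAULT_BIN_WIDTH_PS,
    n_bins: int = DEFAULT_N_BINS,
    center_fraction: float = 0.1,
) -> IrfKernel:
    """Gaussian instrument-response kernel, normalized to sum 1.

    The kernel peaks at ``center_fraction`` of the time window (early enough
    to leave pre-rise bins for background estimation, late enough that the
    rising edge is sampled).  The measured FWHM of the returned samples is
    within one bin of the request.
    """
    if fwhm_ps <= 0 or bin_width_ps <= 0:
        raise ValueError("fwhm_ps and bin_width_ps must be positive")
    if n_bins < 16:
        raise ValueError("n_bins must be at least 16")
    if not (0.0 < center_fraction < 1.0):
        raise ValueError("center_fraction must lie in (0, 1)")
    t = (np.arange(n_bins) + 0.5) * bin_width_ps
    center = center_fraction * n_bins * bin_width_ps
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    samples = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    samples /= samples.sum()
    return IrfKernel(samples=samples, bin_width_ps=bin_width_ps, fwhm_ps=fwhm_ps)


@dataclass
class SimulatedDecay:
    """One simulated photon histogram with its ground truth."""

    counts: np.ndarray
    expected: np.ndarray
    params: DecayParams
    tau_m: float
    photon_budget: float
    ill_conditioned: bool = False


def simulate_decay(
    params: DecayParams,
    irf: IrfKernel,
    photon_budget: float,
    n_bins: Optional[int] = None,
    bin_width_ps: Optional[float] = None,
    seed: int | np.random.Generator = 0,
) -> SimulatedDecay:
    """Draw one TCSPC histogram from the two-component model.

    The expected curve is the bi-exponential (with one-period wrap-around)
    convolved with the IRF, scaled so the decay contributes ``photon_budget``
    photons, plus the flat ``params.background`` counts per bin.  Counts are
    independent Poisson draws per bin.
    """
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    if n_bins is not None and n_bins != irf.n_bins:
        raise ValueError("n_bins must match the IRF")
    if bin_width_ps is not None and not np.isclose(bin_width_ps, irf.bin_width_ps):
        raise ValueError("bin_width_ps must match the IRF")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    window_ns = irf.period_ps * 1e-3
    ill = params.tau2 >= 5.0 * window_ns
    if ill:
        warnings.warn(
            "tau2 exceeds 5x the time window; the fit problem is "
            "ill-conditioned", stacklevel=2,
        )
    expected = flim.model_curve(params, irf, total_photons=photon_budget)
    counts = rng.poisson(expected)
    return SimulatedDecay(
        counts=counts, expected=expected, params=params,
        tau_m=flim.mean_lifetime(params), photon_budget=photon_budget,
        ill_conditioned=ill,
    )


# ---------------------------------------------------------------------------
# scenes


@dataclass
class CellSpec:
    """Geometry and photophysics of one rendered cell.

    The nucleus (an ellipse concentric with the cell disk) is rendered dimmer
    than the cytoplasm by ``nucleus_intensity_factor`` (nuclei are dark in
    NAD(P)H images because the coenzymes are extranuclear).
    """

    center: tuple[float, float]  # (row, col), pixels
    cell_radius: float
    nucleus_axes: tuple[float, float]  # (major, minor) full lengths, pixels
    nucleus_angle: float  # radians
    nadh_params: DecayParams
    fad_params: DecayParams
    nadh_rate: float  # photons/pixel (relative until the scene is scaled)
    fad_rate: float
    nucleus_intensity_factor: float = 0.4

    def __post_init__(self):
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if max(self.nucleus_axes) / 2.0 >= self.cell_radius:
            raise ValueError("nucleus must fit inside the cell disk")
        if self.nadh_rate <= 0 or self.fad_rate <= 0:
            raise ValueError("photon rates must be positive")
        if not (0.0 < self.nucleus_intensity_factor < 1.0):
            raise ValueError("nucleus_intensity_factor must lie in (0, 1)")


@dataclass
class SceneSpec:
    """One organoid image: a set of cells on a dark background."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    cells: Sequence[CellSpec] = field(default_factory=list)
    # photon rates (cells and background) are relative until the scene is
    # scaled to the acquisition's mean photons/pixel at render time; the
    # default cytoplasm rate is ~1, so 0.05 is a dim, flat-in-time background
    background_rate: float = 0.05
    allow_overlap: bool = False

    def __post_init__(self):
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if not self.allow_overlap:
            for i, a in enumerate(self.cells):
                for b in self.cells[i + 1:]:
                    d = np.hypot(a.center[0] - b.center[0],
                                 a.center[1] - b.center[1])
                    if d < a.cell_radius + b.cell_radius - 1e-9:
                        raise ValueError(
                            "cells overlap; set allow_overlap=True to permit"
                        )


def _default_nadh_params(rng: np.random.Generator) -> DecayParams:
    return DecayParams.make(
        alpha1=float(np.clip(rng.normal(0.75, 0.03), 0.55, 0.92)),
        tau1=float(np.clip(rng.normal(0.4, 0.04), 0.2, 0.7)),
        tau2=float(np.clip(rng.normal(2.6, 0.2), 1.8, 3.4)),
    )


def _default_fad_params(rng: np.random.Generator) -> DecayParams:
    return DecayParams.make(
        alpha1=float(np.clip(rng.normal(0.6, 0.04), 0.4, 0.8)),
        tau1=float(np.clip(rng.normal(0.3, 0.04), 0.15, 0.6)),
        tau2=float(np.clip(rng.normal(2.8, 0.2), 2.0, 3.8)),
    )


def random_scene(
    n_cells: int,
    seed: int | np.random.Generator = 0,
    image_shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.5,
    cell_radius_range: tuple[float, float] = (8.0, 13.0),
    min_gap_px: float = 3.0,
    background_rate: float = 0.05,
    max_tries: int = 5000,
) -> SceneSpec:
    """Random non-overlapping organoid scene of ``n_cells`` cells.

    Cell radii, nucleus ellipses and decay parameters are drawn from
    NAD(P)H/FAD-like baselines; centers are placed by rejection sampling with
    at least ``min_gap_px`` between cell rims.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ny, nx = image_shape
    placed: list[tuple[float, float, float]] = []
    cells: list[CellSpec] = []
    tries = 0
    while len(cells) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in "
                f"{image_shape} after {max_tries} tries"
            )
        r = rng.uniform(*cell_radius_range)
        cy = rng.uniform(r + 2, ny - r - 2)
        cx = rng.uniform(r + 2, nx - r - 2)
        if any(np.hypot(cy - y, cx - x) < r + rr + min_gap_px
               for y, x, rr in placed):
            continue
        major = rng.uniform(0.9, 1.2) * r
        minor = rng.uniform(0.6, 0.9) * major
        major = min(major, 2 * r - 2.0)
        minor = min(minor, major)
        cells.append(CellSpec(
            center=(cy, cx),
            cell_radius=r,
            nucleus_axes=(major, minor),
            nucleus_angle=rng.uniform(0, np.pi),
            nadh_params=_default_nadh_params(rng),
            fad_params=_default_fad_params(rng),
            nadh_rate=float(rng.uniform(0.8, 1.2)),
            fad_rate=float(rng.uniform(0.4, 0.6)),
        ))
        placed.append((cy, cx, r))
    return SceneSpec(image_shape=image_shape, pixel_size_um=pixel_size_um,
                     cells=cells, background_rate=background_rate)


def rasterize_scene(scene: SceneSpec) -> LabelMaps:
    """Ground-truth label maps (cells, nuclei, cytoplasms) for a scene."""
    ny, nx = scene.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cell_labels = np.zeros((ny, nx), dtype=np.int32)
    nucleus_labels = np.zeros((ny, nx), dtype=np.int32)
    for k, cell in enumerate(scene.cells, start=1):
        cy, cx = cell.center
        dy, dx = yy - cy, xx - cx
        disk = dy * dy + dx * dx <= cell.cell_radius ** 2
        cell_labels[disk] = k
        a = cell.nucleus_axes[0] / 2.0
        b = cell.nucleus_axes[1] / 2.0
        c, s = np.cos(cell.nucleus_angle), np.sin(cell.nucleus_angle)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        nucleus_labels[ell & disk] = k
    return LabelMaps.from_cells_and_nuclei(
        cell_labels, nucleus_labels, pixel_size_um=scene.pixel_size_um
    )


def _scaled_rate_maps(
    scene: SceneSpec, labels: LabelMaps, mean_photons_per_pixel: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-pixel expected photon totals for both channels, with one common
    scale factor chosen so the NAD(P)H image mean hits the target (a common
    factor preserves the ground-truth redox ratio)."""
    ny, nx = scene.image_shape
    nadh = np.full((ny, nx), float(scene.background_rate))
    fad = np.full((ny, nx), float(scene.background_rate))
    for k, cell in enumerate(scene.cells, start=1):
        cyto = labels.cytoplasm_labels == k
        nuc = labels.nucleus_labels == k
        f = cell.nucleus_intensity_factor
        nadh[cyto] = cell.nadh_rate
        nadh[nuc] = cell.nadh_rate * f
        fad[cyto] = cell.fad_rate
        fad[nuc] = cell.fad_rate * f
    scale = mean_photons_per_pixel / nadh.mean()
    return nadh * scale, fad * scale, scale


@dataclass
class SceneRender:
    """Rendered scene: two photon cubes plus full ground truth."""

    nadh: FlimCube
    fad: FlimCube
    truth_labels: LabelMaps
    truth_cells: pd.DataFrame
    scene: SceneSpec
    scale: float


def render_scene(
    scene: SceneSpec,
    irf: IrfKernel,
    mean_photons_per_pixel: float = DEFAULT_MEAN_PHOTONS_PER_PIXEL,
    seed: int | np.random.Generator = 0,
    n_bins: Optional[int] = None,
    bin_width_ps: Optional[float] = None,
) -> SceneRender:
    """Render a scene into NAD(P)H and FAD photon cubes with ground truth.

    Every pixel's histogram is Poisson-drawn around its region's expected
    decay curve; background pixels are flat in time (background light).  The
    truth table carries the exact per-cell tau_m, redox ratio (the common
    intensity scaling cancels in the ratio) and the morphology endpoints
    recomputed from the truth label maps.
    """
    if n_bins is not None and n_bins != irf.n_bins:
        raise ValueError("n_bins must match the IRF")
    if bin_width_ps is not None and not np.isclose(bin_width_ps, irf.bin_width_ps):
        raise ValueError("bin_width_ps must match the IRF")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rasterize_scene(scene)
    nadh_rate, fad_rate, scale = _scaled_rate_maps(
        scene, labels, mean_photons_per_pixel
    )
    nb = irf.n_bins
    ny, nx = scene.image_shape

    def channel_cube(rate_map: np.ndarray, which: str) -> FlimCube:
        expected = np.empty((ny, nx, nb))
        flat = np.full(nb, 1.0 / nb)
        expected[:] = rate_map[:, :, None] * flat[None, None, :]
        for k, cell in enumerate(scene.cells, start=1):
            params = cell.nadh_params if which == "nadh" else cell.fad_params
            shape = flim.decay_shape(params.alpha1, params.tau1, params.tau2, irf)
            region = labels.cell_labels == k
            expected[region] = rate_map[region][:, None] * shape[None, :]
        counts = rng.poisson(expected).astype(np.uint32)
        return FlimCube(counts=counts, bin_width_ps=irf.bin_width_ps,
                        pixel_size_um=scene.pixel_size_um, channel=which)

    nadh_cube = channel_cube(nadh_rate, "nadh")
    fad_cube = channel_cube(fad_rate, "fad")

    morph, _ = morphology_metrics(labels)
    rows = []
    for k, cell in enumerate(scene.cells, start=1):
        npar, fpar = cell.nadh_params, cell.fad_params
        rows.append({
            "cell_id": k,
            "nadh_intensity": cell.nadh_rate * scale,
            "fad_intensity": cell.fad_rate * scale,
            "redox_ratio": cell.nadh_rate / cell.fad_rate,
            "nadh_tau_m": flim.mean_lifetime(npar),
            "fad_tau_m": flim.mean_lifetime(fpar),
            "nadh_alpha1": npar.alpha1, "nadh_tau1": npar.tau1,
            "nadh_tau2": npar.tau2,
            "fad_alpha1": fpar.alpha1, "fad_tau1": fpar.tau1,
            "fad_tau2": fpar.tau2,
        })
    truth = pd.DataFrame(rows).merge(morph, on="cell_id")
    return SceneRender(nadh=nadh_cube, fad=fad_cube, truth_labels=labels,
                       truth_cells=truth, scene=scene, scale=scale)


def render_intensity_image(
    scene: SceneSpec,
    mean_photons_per_pixel: float = DEFAULT_MEAN_PHOTONS_PER_PIXEL,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, LabelMaps]:
    """Fast path: the NAD(P)H intensity image only (Poisson photon totals
    per pixel, no time axis), with ground-truth labels.  Sufficient input for
    the segmentation stage."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rasterize_scene(scene)
    nadh_rate, _, _ = _scaled_rate_maps(scene, labels, mean_photons_per_pixel)
    return rng.poisson(nadh_rate).astype(float), labels


# ---------------------------------------------------------------------------
# study designs


@dataclass
class EndpointBaseline:
    """Control-group endpoint distributions (means and SDs).

    Redox ratio is dimensionless; lifetimes in ns.  Per-cell lifetime
    components are drawn first (alpha1, tau1) and the long lifetime solved
    from the drawn tau_m, so every record satisfies tau_m = a1*t1 + a2*t2
    exactly while tau_m keeps the stated mean and SD.
    """

    redox_mean: float = 1.0
    redox_sd: float = 0.25
    nadh_tau_m_mean: float = 0.9
    nadh_tau_m_sd: float = 0.15
    fad_tau_m_mean: float = 1.3
    fad_tau_m_sd: float = 0.2
    nadh_alpha1: tuple[float, float] = (0.75, 0.03)
    nadh_tau1: tuple[float, float] = (0.4, 0.04)
    fad_alpha1: tuple[float, float] = (0.6, 0.04)
    fad_tau1: tuple[float, float] = (0.3, 0.04)
    nadh_intensity: tuple[float, float] = (450.0, 80.0)
    fad_intensity: tuple[float, float] = (450.0, 80.0)
    cell_area_um2: tuple[float, float] = (150.0, 30.0)
    nucleus_diameter_um: tuple[float, float] = (7.0, 1.0)
    ncr: tuple[float, float] = (0.35, 0.08)


EffectKey = tuple[str, str, str, int]  # (sample, preparation, treatment, hr)
Effect = tuple[float, float, float]  # shifts on (redox, NAD(P)H tau_m, FAD
#                                       tau_m) in control-SD units


@dataclass
class ExperimentDesign:
    """A multi-arm fresh/frozen drug study at the emulated scale.

    ``effects`` holds additive treatment shifts on (redox ratio, NAD(P)H
    tau_m, FAD tau_m) in units of the control SD, keyed by (sample,
    preparation, treatment, timepoint_hr); ``prep_shifts`` holds freezing
    shifts applied to every arm of a preparation (they cancel in
    control-referenced endpoints but move the basal level).  Cells are iid
    within a group by default (the analysis unit is the cell); set
    ``organoid_sd`` to add an organoid-level random intercept.
    """

    samples: Sequence[str] = ("S1", "S2")
    preparations: Sequence[str] = ("fresh", "flash_frozen", "dmso_frozen")
    recovery_days: Sequence[int] = (0, 7)  # 0 applies to fresh only
    treatments: Sequence[str] = ("control", "drug_A", "drug_B", "drug_C")
    control_treatment: str = "control"
    timepoints_hr: Sequence[int] = (24, 48, 72)
    organoids_per_group: int = 6
    cells_per_organoid: int = 30
    baseline: EndpointBaseline = field(default_factory=EndpointBaseline)
    effects: Mapping[EffectKey, Effect] = field(default_factory=dict)
    prep_shifts: Mapping[tuple[str, str], Effect] = field(default_factory=dict)
    organoid_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.control_treatment not in self.treatments:
            raise ValueError(
                f"control arm {self.control_treatment!r} missing from "
                f"treatments {tuple(self.treatments)}"
            )
        if self.organoids_per_group < 1:
            raise ValueError("organoids_per_group must be >= 1")
        n = self.organoids_per_group * self.cells_per_organoid
        if not (30 <= n <= 300):
            warnings.warn(
                f"{n} cells/group falls outside the emulated 30-300 range",
                stacklevel=2,
            )

    def arms(self) -> list[tuple[str, str, int]]:
        """(sample, preparation, recovery_days) combinations."""
        out = []
        for s in self.samples:
            for p in self.preparations:
                days = [0] if p == "fresh" else [d for d in self.recovery_days
                                                 if d > 0] or [0]
                for d in days:
                    out.append((s, p, d))
        return out


@dataclass
class ExperimentTables:
    cells: pd.DataFrame
    truth_calls: pd.DataFrame
    design: ExperimentDesign


def _draw_group(
    rng: np.random.Generator,
    design: ExperimentDesign,
    shift: Effect,
    n_organoids: int,
    n_cells: int,
) -> pd.DataFrame:
    b = design.baseline
    rows = []
    for org in range(1, n_organoids + 1):
        org_fx = rng.normal(0.0, design.organoid_sd, size=3) \
            if design.organoid_sd > 0 else np.zeros(3)
        n = n_cells
        redox = rng.normal(b.redox_mean + shift[0] * b.redox_sd + org_fx[0],
                           b.redox_sd, n)
        nadh_tm = rng.normal(
            b.nadh_tau_m_mean + shift[1] * b.nadh_tau_m_sd + org_fx[1],
            b.nadh_tau_m_sd, n)
        fad_tm = rng.normal(
            b.fad_tau_m_mean + shift[2] * b.fad_tau_m_sd + org_fx[2],
            b.fad_tau_m_sd, n)
        na1 = np.clip(rng.normal(*b.nadh_alpha1, size=n), 0.05, 0.95)
        nt1 = np.clip(rng.normal(*b.nadh_tau1, size=n), 0.1, None)
        fa1 = np.clip(rng.normal(*b.fad_alpha1, size=n), 0.05, 0.95)
        ft1 = np.clip(rng.normal(*b.fad_tau1, size=n), 0.1, None)
        # solve the long component from the drawn tau_m so the record is
        # internally consistent: tau2 = (tau_m - a1*t1) / a2
        nt2 = np.maximum((nadh_tm - na1 * nt1) / (1 - na1), nt1)
        ft2 = np.maximum((fad_tm - fa1 * ft1) / (1 - fa1), ft1)
        df = pd.DataFrame({
            "organoid_id": org,
            "cell_id": np.arange(1, n + 1),
            "nadh_intensity": np.clip(
                rng.normal(*b.nadh_intensity, size=n), 1.0, None),
            "fad_intensity": np.clip(
                rng.normal(*b.fad_intensity, size=n), 1.0, None),
            "redox_ratio": np.clip(redox, 0.0, None),
            "nadh_tau_m": na1 * nt1 + (1 - na1) * nt2,
            "fad_tau_m": fa1 * ft1 + (1 - fa1) * ft2,
            "nadh_alpha1": na1, "nadh_tau1": nt1, "nadh_tau2": nt2,
            "fad_alpha1": fa1, "fad_tau1": ft1, "fad_tau2": ft2,
            "cell_area_um2": np.clip(
                rng.normal(*b.cell_area_um2, size=n), 10.0, None),
            "nucleus_diameter_um": np.clip(
                rng.normal(*b.nucleus_diameter_um, size=n), 1.0, None),
            "ncr": np.clip(rng.normal(*b.ncr, size=n), 0.02, None),
        })
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_experiment(design: ExperimentDesign) -> ExperimentTables:
    """Generate the per-cell endpoint table for a full study design.

    Control groups are drawn from the baseline distributions; treated and
    frozen groups are shifted by ``design.effects`` / ``design.prep_shifts``.
    Deterministic under ``design.seed`` (each group has a named substream, so
    adding arms does not reshuffle existing ones).  Also emits the
    ground-truth expected response calls: the sign of the induced OMI-index
    shift ``e_redox + e_nadh - e_fad`` for every treated arm.
    """
    cells = []
    calls = []
    for sample, prep, days in design.arms():
        base_shift = np.asarray(
            design.prep_shifts.get((sample, prep), (0.0, 0.0, 0.0)), float)
        for tp in design.timepoints_hr:
            for treatment in design.treatments:
                eff = np.asarray(
                    design.effects.get((sample, prep, treatment, tp),
                                       (0.0, 0.0, 0.0)), float)
                rng = substream(design.seed, "experiment", sample, prep,
                                days, treatment, tp)
                df = _draw_group(rng, design, tuple(base_shift + eff),
                                 design.organoids_per_group,
                                 design.cells_per_organoid)
                df.insert(0, "sample", sample)
                df.insert(1, "preparation", prep)
                df.insert(2, "recovery_days", days)
                df.insert(3, "treatment", treatment)
                df.insert(4, "timepoint_hr", tp)
                cells.append(df)
                if treatment != design.control_treatment:
                    omi_shift = eff[0] + eff[1] - eff[2]
                    call = ("none" if omi_shift == 0
                            else "decrease" if omi_shift < 0 else "increase")
                    calls.append({
                        "sample": sample, "preparation": prep,
                        "recovery_days": days, "treatment": treatment,
                        "timepoint_hr": tp, "call": call,
                        "omi_shift": omi_shift,
                    })
    return ExperimentTables(
        cells=pd.concat(cells, ignore_index=True),
        truth_calls=pd.DataFrame(
            calls, columns=["sample", "preparation", "recovery_days",
                            "treatment", "timepoint_hr", "call", "omi_shift"]),
        design=design,
    )
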