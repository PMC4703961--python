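"""Two-component fluorescence-decay model and per-pixel TCSPC fitting.

The measured decay in one pixel of a time-correlated single-photon-counting
(TCSPC) image is modeled as

    I(t) = A * [ a1 * exp(-t / tau1) + a2 * exp(-t / tau2) ] (x) IRF + C

with a1 + a2 = 1, tau1 <= tau2 (short component first), C a flat background,
and (x) denoting convolution with the instrument response function over one
laser period.  The free and protein-bound pools of NAD(P)H and FAD motivate
the two components.  The amplitude-weighted mean lifetime is

    tau_m = a1 * tau1 + a2 * tau2.

Fitting is weighted nonlinear least squares (Poisson-motivated weights
1/max(counts, 1)) with the amplitude A and background C profiled out linearly
at every step (variable projection), which keeps the nonlinear search in the
three shape parameters (a1, tau1, tau2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .types import DecayParams, IrfKernel

__all__ = [
    "FitConfig",
    "FitResult",
    "ParamMaps",
    "model_curve",
    "decay_shape",
    "mean_lifetime",
    "bin_pixels",
    "fit_decay",
    "grid_fit_decay",
    "fit_cube",
]


def mean_lifetime(params: DecayParams) -> float:
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + a2*tau2, in ns."""
    return params.alpha1 * params.tau1 + params.alpha2 * params.tau2


def decay_shape(
    alpha1: float,
    tau1_ns: float,
    tau2_ns: float,
    irf: IrfKernel,
) -> np.ndarray:
    """Unit-sum IRF-convolved bi-exponential decay sampled at bin centers.

    Includes the incomplete-decay ("wrap-around") contribution of exactly one
    preceding laser pulse: each component is multiplied by
    ``1 + exp(-T / tau)`` where T is the laser period (the full time window).
    The convolution with the IRF is circular over the period, so the IRF tail
    and the decay tail both fold into the early (pre-rise) bins as they do in
    a real high-repetition-rate measurement.
    """
    n = irf.n_bins
    dt = irf.bin_width_ps * 1e-3  # ns
    period = n * dt
    t = (np.arange(n) + 0.5) * dt
    d = np.zeros(n)
    for a, tau in ((alpha1, tau1_ns), (1.0 - alpha1, tau2_ns)):
        if a == 0.0:
            continue
        d += a * np.exp(-t / tau) * (1.0 + np.exp(-period / tau))
    curve = np.fft.irfft(np.fft.rfft(irf.samples) * np.fft.rfft(d), n)
    np.clip(curve, 0.0, None, out=curve)
    s = curve.sum()
    if s <= 0:
        raise ValueError("degenerate decay shape (all-zero curve)")
    return curve / s


def model_curve(
    params: DecayParams,
    irf: IrfKernel,
    n_bins: Optional[int] = None,
    bin_width_ps: Optional[float] = None,
    total_photons: float = 1.0,
) -> np.ndarray:
    """Expected counts per bin: unit-sum decay shape scaled by ``total_photons``
    plus the flat background ``params.background`` (counts/bin).

    ``n_bins``/``bin_width_ps``, when given, must match the IRF calibration.
    """
    if n_bins is not None and n_bins != irf.n_bins:
        raise ValueError(f"n_bins={n_bins} does not match IRF ({irf.n_bins})")
    if bin_width_ps is not None and not np.isclose(bin_width_ps, irf.bin_width_ps):
        raise ValueError(
            f"bin_width_ps={bin_width_ps} does not match IRF ({irf.bin_width_ps})"
        )
    shape = decay_shape(params.alpha1, params.tau1, params.tau2, irf)
    return total_photons * shape + params.background


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """Settings for per-pixel decay fitting.

    The initial values bracket published NAD(P)H / FAD coenzyme lifetimes;
    `channel` selects the preset.  Bounds follow the physically sensible
    sub-ns .. 10 ns range.
    """

    channel: str = "nadh"  # "nadh" or "fad": initializer preset
    init_alpha1: Optional[float] = None
    init_tau1_ns: Optional[float] = None
    init_tau2_ns: Optional[float] = None
    tau_bounds_ns: tuple[float, float] = (0.05, 10.0)
    min_photons: int = 100  # minimum background-subtracted photons to fit
    photon_threshold: int = 300  # binning target (summed counts)
    max_bin_radius: int = 3
    tie_tol_ns: float = 1e-3  # tau1 ~ tau2 -> collapse to monoexponential
    max_nfev: int = 200
    # Poisson-motivated iterative reweighting: pass 1 weights 1/max(y,1),
    # later passes 1/max(model,1) (removes the low-count bias of
    # data-derived weights)
    reweight_passes: int = 2

    _PRESETS = {
        "nadh": (0.7, 0.3, 2.0),
        "fad": (0.7, 0.3, 2.2),
    }

    def initial(self) -> tuple[float, float, float]:
        a, t1, t2 = self._PRESETS.get(self.channel, self._PRESETS["nadh"])
        return (
            a if self.init_alpha1 is None else self.init_alpha1,
            t1 if self.init_tau1_ns is None else self.init_tau1_ns,
            t2 if self.init_tau2_ns is None else self.init_tau2_ns,
        )


@dataclass
class FitResult:
    params: Optional[DecayParams]
    tau_m: float
    chi2_reduced: float
    photons_used: float
    converged: bool
    bin_radius: int = 0
    amplitude: float = np.nan

    @property
    def masked(self) -> bool:
        return self.params is None


def _pre_rise_bins(irf: IrfKernel) -> slice:
    """Bins safely before the IRF rise, used to initialize the background."""
    peak = int(np.argmax(irf.samples))
    sigma_bins = irf.fwhm_ps / 2.3548 / irf.bin_width_ps
    stop = max(int(peak - 3.0 * sigma_bins - 1), 0)
    return slice(0, stop)


def _solve_amplitude_background(
    y: np.ndarray, w: np.ndarray, s: np.ndarray
) -> tuple[float, float]:
    """Weighted linear solve of y ~ A*s + C with A >= 0, C >= 0."""
    sw = w.sum()
    sws = w @ s
    swss = w @ (s * s)
    swy = w @ y
    swsy = w @ (s * y)
    det = swss * sw - sws * sws
    if det <= 0:
        return max(swsy / max(swss, 1e-300), 0.0), 0.0
    amp = (swsy * sw - sws * swy) / det
    bg = (swss * swy - sws * swsy) / det
    if bg < 0.0:
        bg = 0.0
        amp = max(swsy / max(swss, 1e-300), 0.0)
    elif amp < 0.0:
        amp = 0.0
        bg = swy / sw
    return amp, bg


def fit_decay(
    histogram: np.ndarray,
    irf: IrfKernel,
    init: Optional[DecayParams] = None,
    bounds: Optional[tuple[float, float]] = None,
    config: Optional[FitConfig] = None,
    bin_radius: int = 0,
) -> FitResult:
    """Fit the IRF-convolved two-component model to one photon histogram.

    Returns a masked :class:`FitResult` (``params=None``) when the histogram
    holds fewer background-subtracted photons than ``config.min_photons``.
    The short component is always reported first (tau1 <= tau2); if the two
    lifetimes collapse within ``tie_tol_ns`` the result is reported as
    monoexponential (alpha1 = 1).
    """
    config = config or FitConfig()
    y = np.asarray(histogram, dtype=float)
    if y.ndim != 1 or y.size != irf.n_bins:
        raise ValueError("histogram length must match the IRF bin count")

    pre = _pre_rise_bins(irf)
    bg0 = float(np.mean(y[pre])) if (pre.stop or 0) >= 3 else 0.0
    total = float(y.sum())
    net = total - bg0 * y.size
    if net < config.min_photons:
        return FitResult(
            params=None,
            tau_m=np.nan,
            chi2_reduced=np.nan,
            photons_used=total,
            converged=False,
            bin_radius=bin_radius,
        )

    w = 1.0 / np.maximum(y, 1.0)
    lo, hi = bounds if bounds is not None else config.tau_bounds_ns

    if init is not None:
        x0 = [init.alpha1, init.tau1, init.tau2]
    else:
        x0 = list(config.initial())
    # canonical ordering of the initializer: makes the fit exactly invariant
    # under the (tau1, a1) <-> (tau2, a2) relabeling of its starting point
    if x0[1] > x0[2]:
        x0 = [1.0 - x0[0], x0[2], x0[1]]
    x0[1] = min(max(x0[1], lo), hi)
    x0[2] = min(max(x0[2], lo), hi)
    x0[0] = min(max(x0[0], 0.0), 1.0)

    success = True
    for _ in range(max(config.reweight_passes, 1)):
        sqw = np.sqrt(w)

        def residual(x):
            s = decay_shape(x[0], x[1], x[2], irf)
            amp, bg = _solve_amplitude_background(y, w, s)
            return sqw * (y - amp * s - bg)

        res = least_squares(
            residual,
            x0,
            bounds=([0.0, lo, lo], [1.0, hi, hi]),
            max_nfev=config.max_nfev,
        )
        x0 = list(res.x)
        success = bool(res.success)
        s = decay_shape(*x0, irf)
        amp, bg = _solve_amplitude_background(y, w, s)
        w = 1.0 / np.maximum(amp * s + bg, 1.0)
    a1, t1, t2 = x0

    if t1 > t2:  # relabel: short component first
        a1, t1, t2 = 1.0 - a1, t2, t1
    if abs(t2 - t1) < config.tie_tol_ns:  # non-identifiable ridge
        a1, t2 = 1.0, t1

    # goodness of fit reported with the standard data-derived weights
    w_neyman = 1.0 / np.maximum(y, 1.0)
    chi2 = float(np.sum(w_neyman * (y - amp * s - bg) ** 2))
    dof = max(y.size - 5, 1)
    params = DecayParams(alpha1=a1, alpha2=1.0 - a1, tau1=t1, tau2=t2, background=bg)
    return FitResult(
        params=params,
        tau_m=mean_lifetime(params),
        chi2_reduced=chi2 / dof,
        photons_used=total,
        converged=success,
        bin_radius=bin_radius,
        amplitude=amp,
    )


def grid_fit_decay(
    histogram: np.ndarray,
    irf: IrfKernel,
    alpha_grid: Optional[np.ndarray] = None,
    tau1_grid: Optional[np.ndarray] = None,
    tau2_grid: Optional[np.ndarray] = None,
) -> FitResult:
    """Exhaustive grid-search reference fit over (alpha1, tau1, tau2).

    Brute-force minimizer of the same weighted chi-square objective as
    :func:`fit_decay`, with amplitude and background solved in closed form at
    every grid node.  Used as an optimality reference for the iterative
    fitter; far too slow for images but exact up to the grid resolution.
    """
    y = np.asarray(histogram, dtype=float)
    w = 1.0 / np.maximum(y, 1.0)
    if alpha_grid is None:
        alpha_grid = np.arange(0.30, 1.0001, 0.01)
    if tau1_grid is None:
        tau1_grid = np.arange(0.10, 0.9001, 0.02)
    if tau2_grid is None:
        tau2_grid = np.arange(1.50, 3.5001, 0.02)

    n = irf.n_bins
    dt = irf.bin_width_ps * 1e-3
    period = n * dt
    t = (np.arange(n) + 0.5) * dt
    girf = np.fft.rfft(irf.samples)

    def component(tau: float) -> np.ndarray:
        # unnormalized convolved monoexponential with one-period wrap; the
        # linear amplitude absorbs the overall scale, so the amplitude
        # fractions of the mixture are the model's alpha directly
        d = np.exp(-t / tau) * (1.0 + np.exp(-period / tau))
        return np.clip(np.fft.irfft(girf * np.fft.rfft(d), n), 0.0, None)

    c1 = np.stack([component(tt) for tt in tau1_grid])  # (n1, nb)
    c2 = np.stack([component(tt) for tt in tau2_grid])  # (n2, nb)

    sw = w.sum()
    swy = w @ y
    swyy = w @ (y * y)
    s1 = c1 @ w  # sum w * curve
    s2 = c2 @ w
    s1y = c1 @ (w * y)
    s2y = c2 @ (w * y)
    s11 = (c1 * c1) @ w
    s22 = (c2 * c2) @ w
    s12 = c1 @ (w[None, :] * c2).T  # (n1, n2) cross terms

    best = (np.inf, 0, 0, 0, 0.0, 0.0)
    for ia, a in enumerate(alpha_grid):
        b = 1.0 - a
        sws = a * s1[:, None] + b * s2[None, :]
        swsy = a * s1y[:, None] + b * s2y[None, :]
        swss = a * a * s11[:, None] + 2 * a * b * s12 + b * b * s22[None, :]
        det = swss * sw - sws * sws
        det = np.where(det <= 0, np.nan, det)
        amp = (swsy * sw - sws * swy) / det
        bg = (swss * swy - sws * swsy) / det
        # clip to the A >= 0, C >= 0 constraint
        neg_bg = bg < 0
        amp = np.where(neg_bg, np.maximum(swsy / swss, 0.0), amp)
        bg = np.where(neg_bg, 0.0, bg)
        amp = np.maximum(amp, 0.0)
        chi2 = (
            swyy
            - 2 * amp * swsy
            - 2 * bg * swy
            + amp * amp * swss
            + 2 * amp * bg * sws
            + bg * bg * sw
        )
        chi2 = np.where(np.isnan(chi2), np.inf, chi2)
        i, j = np.unravel_index(int(np.argmin(chi2)), chi2.shape)
        if chi2[i, j] < best[0]:
            best = (float(chi2[i, j]), ia, i, j, float(amp[i, j]), float(bg[i, j]))

    chi2_min, ia, i, j, amp, bg = best
    a1 = float(alpha_grid[ia])
    t1, t2 = float(tau1_grid[i]), float(tau2_grid[j])
    if t1 > t2:
        a1, t1, t2 = 1.0 - a1, t2, t1
    params = DecayParams(alpha1=a1, alpha2=1.0 - a1, tau1=t1, tau2=t2, background=bg)
    return FitResult(
        params=params,
        tau_m=mean_lifetime(params),
        chi2_reduced=chi2_min / max(y.size - 5, 1),
        photons_used=float(y.sum()),
        converged=True,
        amplitude=amp,
    )


# ---------------------------------------------------------------------------
# image-level operations


def bin_pixels(
    counts: np.ndarray,
    photon_threshold: int,
    max_radius: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatially bin a photon cube until each pixel reaches a photon target.

    For each pixel the smallest odd square window (1x1, 3x3, ..., capped at
    ``(2*max_radius+1)``) whose summed histogram reaches ``photon_threshold``
    is used; windows are clipped at the image edge.  Standard TCSPC practice
    to trade spatial resolution for fit stability.

    Returns ``(binned_counts, bin_radius_map, mask)`` where ``mask`` is True
    for pixels whose threshold was unreachable even at the cap.
    """
    if photon_threshold <= 0:
        raise ValueError("photon_threshold must be positive")
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError("expected a (y, x, t) photon cube")
    ny, nx, nt = counts.shape

    # integral image over (y, x) for box sums of any radius
    c = counts.astype(np.float64)
    ii = np.zeros((ny + 1, nx + 1, nt))
    ii[1:, 1:, :] = c.cumsum(axis=0).cumsum(axis=1)

    def box_sum(r: int) -> np.ndarray:
        y0 = np.clip(np.arange(ny) - r, 0, ny)
        y1 = np.clip(np.arange(ny) + r + 1, 0, ny)
        x0 = np.clip(np.arange(nx) - r, 0, nx)
        x1 = np.clip(np.arange(nx) + r + 1, 0, nx)
        return (
            ii[y1][:, x1]
            - ii[y0][:, x1]
            - ii[y1][:, x0]
            + ii[y0][:, x0]
        )

    binned = c.copy()
    radius = np.zeros((ny, nx), dtype=np.int16)
    totals = c.sum(axis=2)
    unmet = totals < photon_threshold
    for r in range(1, max_radius + 1):
        if not unmet.any():
            break
        bs = box_sum(r)
        bs_tot = bs.sum(axis=2)
        take = unmet & (bs_tot >= photon_threshold)
        binned[take] = bs[take]
        radius[take] = r
        unmet &= ~take
    if unmet.any():
        bs = box_sum(max_radius)
        binned[unmet] = bs[unmet]
        radius[unmet] = max_radius
    return binned, radius, unmet


@dataclass
class ParamMaps:
    """Per-pixel fitted parameter images for one channel."""

    alpha1: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    intensity: np.ndarray  # time-summed raw (unbinned) counts
    chi2: np.ndarray
    mask: np.ndarray  # True where the pixel was NOT fit
    bin_radius: np.ndarray
    channel: str = "nadh"

    def __post_init__(self):
        shapes = {m.shape for m in (self.alpha1, self.tau1, self.tau2,
                                    self.tau_m, self.intensity, self.chi2,
                                    self.mask, self.bin_radius)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha1.shape


def fit_cube(
    cube,
    irf: IrfKernel,
    config: Optional[FitConfig] = None,
) -> ParamMaps:
    """Bin and fit every pixel of a photon cube; returns per-pixel maps.

    ``cube`` is a :class:`~omiflim.types.FlimCube` (or a bare (y, x, t)
    array).  Masked (unfit) pixels carry NaN in every parameter map and True
    in ``mask`` — never silent zeros.
    """
    from .types import FlimCube  # local import to avoid cycle at load time

    config = config or FitConfig()
    if isinstance(cube, FlimCube):
        if cube.n_bins != irf.n_bins or not np.isclose(
            cube.bin_width_ps, irf.bin_width_ps
        ):
            raise ValueError("cube and IRF time calibration differ")
        counts = cube.counts
        channel = cube.channel or config.channel
    else:
        counts = np.asarray(cube)
        channel = config.channel
    ny, nx, _ = counts.shape

    binned, radius, unreachable = bin_pixels(
        counts, config.photon_threshold, config.max_bin_radius
    )
    nanmap = lambda: np.full((ny, nx), np.nan)
    maps = ParamMaps(
        alpha1=nanmap(), tau1=nanmap(), tau2=nanmap(), tau_m=nanmap(),
        intensity=counts.sum(axis=2).astype(float), chi2=nanmap(),
        mask=np.ones((ny, nx), dtype=bool), bin_radius=radius.astype(float),
        channel=channel,
    )
    cfg = replace(config, channel=channel)
    n_unreachable = int(unreachable.sum())
    if n_unreachable:
        warnings.warn(
            f"{n_unreachable} pixels never reached the binning photon "
            f"threshold and were masked", stacklevel=2,
        )
    cache: dict[bytes, FitResult] = {}
    for iy in range(ny):
        for ix in range(nx):
            if unreachable[iy, ix]:
                continue
            h = binned[iy, ix]
            key = h.tobytes()
            fit = cache.get(key)
            if fit is None:
                fit = fit_decay(h, irf, config=cfg, bin_radius=int(radius[iy, ix]))
                cache[key] = fit
            if fit.masked:
                continue
            maps.alpha1[iy, ix] = fit.params.alpha1
            maps.tau1[iy, ix] = fit.params.tau1
            maps.tau2[iy, ix] = fit.params.tau2
            maps.tau_m[iy, ix] = fit.tau_m
            maps.chi2[iy, ix] = fit.chi2_reduced
            maps.mask[iy, ix] = False
    return maps
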