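"""Shared domain containers for the FLIM pipeline.

These are deliberately thin: the raw measurement (a per-channel photon
histogram cube), the instrument response kernel, and the bi-exponential decay
parameters that both the simulator and the fitter speak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["IrfKernel", "DecayParams", "FlimCube"]


def _measured_fwhm(samples: np.ndarray, bin_width_ps: float) -> float:
    """FWHM of a sampled unimodal kernel, by linear interpolation of the
    half-maximum crossings (in ps)."""
    s = np.asarray(samples, dtype=float)
    half = s.max() / 2.0
    above = np.flatnonzero(s >= half)
    i0, i1 = int(above[0]), int(above[-1])
    left = float(i0)
    if i0 > 0 and s[i0] != s[i0 - 1]:
        left = i0 - (s[i0] - half) / (s[i0] - s[i0 - 1])
    right = float(i1)
    if i1 < s.size - 1 and s[i1] != s[i1 + 1]:
        right = i1 + (s[i1] - half) / (s[i1] - s[i1 + 1])
    return (right - left) * bin_width_ps


@dataclass(frozen=True)
class IrfKernel:
    """Instrument response function sampled on the TCSPC time axis.

    ``samples`` are nonnegative, sum to 1, and are single-moded; ``fwhm_ps``
    is the nominal width the kernel was built with.
    """

    samples: np.ndarray
    bin_width_ps: float
    fwhm_ps: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.fwhm_ps <= 0 or self.bin_width_ps <= 0:
            raise ValueError("fwhm_ps and bin_width_ps must be positive")
        if s.ndim != 1 or s.size < 2:
            raise ValueError("IRF samples must be a 1-D array")
        if np.any(s < 0):
            raise ValueError("IRF samples must be nonnegative")
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("IRF samples must sum to 1 within 1e-9")
        # single mode: nonzero support rises then falls exactly once
        nz = s > s.max() * 1e-12
        core = s[nz]
        d = np.sign(np.diff(core))
        d = d[d != 0]
        if np.any(np.diff(d) > 0):
            raise ValueError("IRF must be single-moded")

    @property
    def n_bins(self) -> int:
        return int(self.samples.size)

    @property
    def period_ps(self) -> float:
        return self.n_bins * self.bin_width_ps

    @property
    def centroid_ps(self) -> float:
        t = (np.arange(self.n_bins) + 0.5) * self.bin_width_ps
        return float(t @ self.samples)

    def measured_fwhm_ps(self) -> float:
        return _measured_fwhm(self.samples, self.bin_width_ps)


@dataclass(frozen=True)
class DecayParams:
    """Two-component decay: fractional amplitudes and lifetimes (ns).

    ``tau1`` is always the short component; ``background`` is the flat
    background-light level in counts per bin.
    """

    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    background: float = 0.0

    def __post_init__(self):
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            raise ValueError("alpha1 + alpha2 must equal 1 within 1e-9")
        if not (0.0 <= self.alpha1 <= 1.0):
            raise ValueError("alpha1 must lie in [0, 1]")
        if not (0.0 < self.tau1 <= self.tau2):
            raise ValueError("need 0 < tau1 <= tau2 (short component first)")
        if self.background < 0:
            raise ValueError("background must be nonnegative")

    @classmethod
    def make(cls, alpha1: float, tau1: float, tau2: float,
             background: float = 0.0) -> "DecayParams":
        """Build from alpha1 alone (alpha2 = 1 - alpha1), relabeling so the
        short lifetime comes first."""
        if tau1 > tau2:
            alpha1, tau1, tau2 = 1.0 - alpha1, tau2, tau1
        return cls(alpha1=alpha1, alpha2=1.0 - alpha1, tau1=tau1, tau2=tau2,
                   background=background)


@dataclass
class FlimCube:
    """Per-channel 3-D photon-count histogram (y, x, time-bin)."""

    counts: np.ndarray
    bin_width_ps: float
    pixel_size_um: float = 0.5
    channel: Optional[str] = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be a (y, x, t) array")
        if np.any(c < 0):
            raise ValueError("photon counts must be nonnegative")
        self.counts = c

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        """Time-summed photon counts per pixel."""
        return self.counts.sum(axis=2)
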