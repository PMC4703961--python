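import numpy as np
import pytest

from omiflim import synthetic as syn
from omiflim.types import DecayParams, IrfKernel


@pytest.fixture(scope="session")
def irf() -> IrfKernel:
    """Default acquisition IRF: 260 ps FWHM Gaussian, 256 x 48.8 ps bins."""
    return syn.make_irf()


@pytest.fixture(scope="session")
def nadh_params() -> DecayParams:
    """Canonical NAD(P)H-like decay: a1=0.75, tau1=0.4 ns, tau2=2.6 ns."""
    return DecayParams.make(0.75, 0.4, 2.6)


def delta_irf(n_bins: int = 256, bin_width_ps: float = 48.8) -> IrfKernel:
    """Near-delta kernel (all mass in bin 0) for convolution identities."""
    samples = np.zeros(n_bins)
    samples[0] = 1.0
    return IrfKernel(samples=samples, bin_width_ps=bin_width_ps, fwhm_ps=1.0)


def match_cells(truth, pred):
    """Per-true-cell best-overlap IoU against a predicted labeling."""
    ious = []
    for k in truth.labels:
        tmask = truth.cell_labels == k
        labs, cnts = np.unique(pred.cell_labels[tmask], return_counts=True)
        keep = labs > 0
        labs, cnts = labs[keep], cnts[keep]
        if labs.size == 0:
            ious.append(0.0)
            continue
        pmask = pred.cell_labels == labs[np.argmax(cnts)]
        ious.append((tmask & pmask).sum() / (tmask | pmask).sum())
    return np.asarray(ious)
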