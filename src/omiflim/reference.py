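"""Published 72-hr OMI-index response calls used as a worked example.

The study behind this pipeline reported, for four tumor samples (two
HER2-overexpressing xenografts, BT474 and its trastuzumab-resistant
derivative HR6, and two patient breast-tumor biopsies), whether each drug
arm showed a significant OMI-index decrease, increase, or no change versus
the time-matched control at 72 h of treatment — once for organoids from
fresh tissue and once for each frozen-tissue preparation grown for 7 days
before treatment (N7 = flash-frozen, D7 = DMSO-frozen; the patient samples
had only flash-frozen arms).

Encoded here as plain data, these calls are the canonical input for the
concordance scorer: six frozen preparations x four drug arms = 24
treatment-level comparisons, of which 4 are discordant with the fresh
counterpart (~16%).

Drug abbreviations: P = paclitaxel, H = trastuzumab, X = XL147,
T = tamoxifen, combo = triple combination (H+P+X for the xenografts,
H+P+T for the patient samples).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["fresh_calls_72hr", "frozen_calls_72hr_day7",
           "reference_calls_72hr"]

_FRESH = [
    # sample, treatment, call at 72 hr vs time-matched control
    ("BT474", "paclitaxel", "decrease"),
    ("BT474", "trastuzumab", "decrease"),
    ("BT474", "xl147", "decrease"),
    ("BT474", "combo", "decrease"),
    ("HR6", "paclitaxel", "increase"),
    ("HR6", "trastuzumab", "none"),
    ("HR6", "xl147", "increase"),
    ("HR6", "combo", "decrease"),
    ("Patient1", "paclitaxel", "none"),
    ("Patient1", "trastuzumab", "none"),
    ("Patient1", "tamoxifen", "none"),
    ("Patient1", "combo", "decrease"),
    ("Patient2", "paclitaxel", "decrease"),
    ("Patient2", "trastuzumab", "none"),
    ("Patient2", "tamoxifen", "decrease"),
    ("Patient2", "combo", "decrease"),
]

_FROZEN_DAY7 = [
    # sample, preparation, treatment, call at 72 hr
    ("BT474", "flash_frozen", "paclitaxel", "none"),
    ("BT474", "flash_frozen", "trastuzumab", "decrease"),
    ("BT474", "flash_frozen", "xl147", "decrease"),
    ("BT474", "flash_frozen", "combo", "decrease"),
    ("BT474", "dmso_frozen", "paclitaxel", "decrease"),
    ("BT474", "dmso_frozen", "trastuzumab", "decrease"),
    ("BT474", "dmso_frozen", "xl147", "decrease"),
    ("BT474", "dmso_frozen", "combo", "decrease"),
    ("HR6", "flash_frozen", "paclitaxel", "none"),
    ("HR6", "flash_frozen", "trastuzumab", "none"),
    ("HR6", "flash_frozen", "xl147", "none"),
    ("HR6", "flash_frozen", "combo", "decrease"),
    ("HR6", "dmso_frozen", "paclitaxel", "increase"),
    ("HR6", "dmso_frozen", "trastuzumab", "none"),
    ("HR6", "dmso_frozen", "xl147", "increase"),
    ("HR6", "dmso_frozen", "combo", "decrease"),
    ("Patient1", "flash_frozen", "paclitaxel", "none"),
    ("Patient1", "flash_frozen", "trastuzumab", "none"),
    ("Patient1", "flash_frozen", "tamoxifen", "none"),
    ("Patient1", "flash_frozen", "combo", "none"),
    ("Patient2", "flash_frozen", "paclitaxel", "decrease"),
    ("Patient2", "flash_frozen", "trastuzumab", "none"),
    ("Patient2", "flash_frozen", "tamoxifen", "decrease"),
    ("Patient2", "flash_frozen", "combo", "decrease"),
]


def fresh_calls_72hr() -> pd.DataFrame:
    """Fresh-tissue 72-hr response calls, one per (sample, treatment)."""
    df = pd.DataFrame(_FRESH, columns=["sample", "treatment", "call"])
    df.insert(1, "preparation", "fresh")
    df.insert(2, "recovery_days", 0)
    df["timepoint_hr"] = 72
    return df[["sample", "preparation", "recovery_days", "treatment",
               "timepoint_hr", "call"]]


def frozen_calls_72hr_day7() -> pd.DataFrame:
    """72-hr calls for the six 7-day frozen-tissue preparations."""
    df = pd.DataFrame(_FROZEN_DAY7,
                      columns=["sample", "preparation", "treatment", "call"])
    df.insert(2, "recovery_days", 7)
    df["timepoint_hr"] = 72
    return df[["sample", "preparation", "recovery_days", "treatment",
               "timepoint_hr", "call"]]


def reference_calls_72hr() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(fresh, frozen-day-7) call tables for the concordance worked example."""
    return fresh_calls_72hr(), frozen_calls_72hr_day7()
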