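"""The drug-response statistical ladder and fresh-vs-frozen concordance.

The experimental unit is the cell (n = 30-300 cells per group), matching the
study design this pipeline emulates; organoid-level mixed models are
deliberately not used (a documented caveat).  Alpha = 0.05 throughout.

Ladder:

* immunofluorescence / morphology: Kruskal-Wallis, then Dunn's pairwise
  mean-rank z tests (Bonferroni over the performed pairs) when KW rejects;
* control FLIM endpoints, fresh vs frozen: D'Agostino-Pearson omnibus
  normality check, then two-sided t tests with Bonferroni correction;
* drug-response time courses: two-way ANOVA (treatment x time, Type II sums
  of squares for unbalanced groups) followed by Tukey HSD comparisons of
  each treatment against the time-matched control, yielding a three-level
  response call (decrease / increase / none) per (treatment, timepoint);
* fresh-frozen agreement: Spearman rank correlation of group OMI means, and
  the concordance table of response calls (a significant increase, a
  significant decrease and no change are mutually discordant).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ALPHA", "ConcordanceTable",
    "test_normality", "dunn_posthoc", "compare_morphology_groups",
    "compare_control_flim", "drug_response_timecourse", "concordance",
    "correlate_fresh_frozen", "positive_fraction",
]

log = logging.getLogger(__name__)

ALPHA = 0.05

RESULT_COLS = ["group", "comparator", "endpoint", "test", "statistic",
               "p_raw", "p_adjusted", "adjustment", "direction"]


def _direction(delta: float, significant: bool) -> str:
    if not significant or delta == 0:
        return "none"
    return "decrease" if delta < 0 else "increase"


# ---------------------------------------------------------------------------
# normality


def test_normality(values: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K^2 normality test.

    Combines sample skewness and kurtosis into K^2, referred to its
    asymptotic chi-square(2) null.  Requires n >= 20 (the asymptotics are
    unreliable below that) and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"normality test needs n >= 20 (got {x.size})")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    stat, p = sps.normaltest(x)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def dunn_posthoc(
    groups: Mapping[str, np.ndarray], alpha: float = ALPHA
) -> pd.DataFrame:
    """Dunn's multiple-comparison z tests on pooled mean ranks.

    Pairwise z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the standard tie correction T = sum(t^3 - t) / (12 (N - 1)),
    two-sided normal p values, Bonferroni-adjusted over the performed pairs.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    ns = np.array([d.size for d in data])
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks = {}
    start = 0
    for g, n in zip(names, ns):
        mean_ranks[g] = ranks[start:start + n].mean()
        start += n

    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        na, nb = groups[a], groups[b]
        se = np.sqrt(var_base * (1.0 / len(na) + 1.0 / len(nb)))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        p_adj = min(1.0, m * p)
        rows.append({
            "group": a, "comparator": b, "endpoint": "", "test": "dunn",
            "statistic": z, "p_raw": p, "p_adjusted": p_adj,
            "adjustment": "bonferroni",
            "direction": _direction(mean_ranks[a] - mean_ranks[b],
                                    p_adj < alpha),
        })
    return pd.DataFrame(rows, columns=RESULT_COLS)


def compare_morphology_groups(
    groups: Mapping[str, np.ndarray],
    endpoint: str = "",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Kruskal-Wallis across groups; Dunn's pairwise tests if it rejects.

    Returns one row for the omnibus test plus one per performed pairwise
    comparison.  All-tied data yield H = 0, p = 1 and no pairwise tests.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if any(d.size < 3 for d in data):
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:  # scipy raises on all-identical data
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*data)
    omnibus = pd.DataFrame([{
        "group": "|".join(names), "comparator": "", "endpoint": endpoint,
        "test": "kruskal-wallis", "statistic": float(h), "p_raw": float(p),
        "p_adjusted": float(p), "adjustment": "none",
        "direction": "none",
    }], columns=RESULT_COLS)
    if p >= alpha:
        return omnibus
    posthoc = dunn_posthoc(groups, alpha=alpha)
    posthoc["endpoint"] = endpoint
    return pd.concat([omnibus, posthoc], ignore_index=True)


# ---------------------------------------------------------------------------
# fresh-vs-frozen control comparisons (t + Bonferroni)


def compare_control_flim(
    fresh: pd.DataFrame,
    frozen: pd.DataFrame,
    endpoints: Sequence[str],
    frozen_label: str = "frozen",
    alpha: float = ALPHA,
    min_n: int = 30,
) -> pd.DataFrame:
    """Two-sided t tests per endpoint, Bonferroni over the family.

    Intended for control-group FLIM endpoints where the large sample size
    (n > 30 cells) justifies the parametric test; ``min_n`` enforces it.
    """
    for df, who in ((fresh, "fresh"), (frozen, "frozen")):
        if len(df) < min_n:
            raise ValueError(f"{who} group has n={len(df)} < {min_n}")
    m = len(endpoints)
    rows = []
    for ep in endpoints:
        a = fresh[ep].to_numpy(dtype=float)
        b = frozen[ep].to_numpy(dtype=float)
        t, p = sps.ttest_ind(b, a)
        p_adj = min(1.0, m * float(p))
        delta = float(np.mean(b) - np.mean(a))
        rows.append({
            "group": frozen_label, "comparator": "fresh", "endpoint": ep,
            "test": "t", "statistic": float(t), "p_raw": float(p),
            "p_adjusted": p_adj, "adjustment": "bonferroni",
            "direction": _direction(delta, p_adj < alpha),
        })
    return pd.DataFrame(rows, columns=RESULT_COLS)


# ---------------------------------------------------------------------------
# drug-response time course


def tukey_vs_control(
    values: np.ndarray, groups: np.ndarray, control: str
) -> list[tuple[str, float, float]]:
    """Tukey-Kramer comparisons of every group against ``control``.

    Pooled within-group MSE over all k groups present; each pair's
    studentized-range statistic q = |diff| / sqrt(MSE/2 * (1/n_i + 1/n_j))
    is referred to the range distribution with k groups and N - k error df
    (exactly the two-sample t comparison when k = 2).  Returns
    ``(group, mean_diff_vs_control, p_adj)`` per treated group.
    """
    values = np.asarray(values, dtype=float)
    names, inv = np.unique(groups, return_inverse=True)
    k = names.size
    ns = np.bincount(inv)
    means = np.bincount(inv, weights=values) / ns
    n_total = values.size
    sse = float(np.sum((values - means[inv]) ** 2))
    df_err = n_total - k
    if df_err <= 0:
        raise ValueError("need more observations than groups")
    mse = sse / df_err
    ctrl_idx = int(np.flatnonzero(names == control)[0])
    out = []
    for i, name in enumerate(names):
        if i == ctrl_idx:
            continue
        delta = float(means[i] - means[ctrl_idx])
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[ctrl_idx]))
        q = abs(delta) / se if se > 0 else 0.0
        if k == 2:  # q reduces to sqrt(2)|t|
            p = float(2.0 * sps.t.sf(q / np.sqrt(2.0), df_err))
        else:
            p = float(sps.studentized_range.sf(q, k, df_err))
        out.append((str(name), delta, min(max(p, 0.0), 1.0)))
    return out


def drug_response_timecourse(
    cells: pd.DataFrame,
    response_col: str = "omi_index",
    treatment_col: str = "treatment",
    time_col: str = "timepoint_hr",
    control: str = "control",
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA + Tukey response calls for one sample/preparation.

    Fits ``response ~ treatment * time`` on cell-level observations (Type II
    sums of squares, appropriate for the unbalanced 30-300-cell groups),
    then at each timepoint runs Tukey's HSD across the treatment groups and
    reads off each treatment's comparison against the time-matched control.
    A (treatment, timepoint) is called ``decrease``/``increase`` when its
    Tukey-adjusted p falls below alpha with that sign, else ``none``.

    Returns ``(results, calls)``; raises if any cell of the treatment x time
    design is empty, listing the missing groups.
    """
    needed = {response_col, treatment_col, time_col}
    if not needed <= set(cells.columns):
        raise ValueError(f"cells table must have columns {sorted(needed)}")
    treatments = sorted(cells[treatment_col].unique())
    times = sorted(cells[time_col].unique())
    if control not in treatments:
        raise ValueError(f"control arm {control!r} absent from the table")
    missing = [
        (tr, tp) for tr in treatments for tp in times
        if cells[(cells[treatment_col] == tr) & (cells[time_col] == tp)].empty
    ]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    df = cells[[response_col, treatment_col, time_col]].rename(
        columns={response_col: "resp", treatment_col: "treat",
                 time_col: "time"}
    ).copy()
    df = df.sort_values(["treat", "time"], kind="stable").reset_index(drop=True)

    rows = []
    if len(treatments) > 1 and len(times) > 1:
        model = ols("resp ~ C(treat) * C(time)", data=df).fit()
        tbl = anova_lm(model, typ=2)
        for term in tbl.index:
            if term == "Residual":
                continue
            rows.append({
                "group": term, "comparator": "", "endpoint": response_col,
                "test": "anova2", "statistic": float(tbl.loc[term, "F"]),
                "p_raw": float(tbl.loc[term, "PR(>F)"]),
                "p_adjusted": float(tbl.loc[term, "PR(>F)"]),
                "adjustment": "none", "direction": "none",
            })

    calls = []
    for tp in times:
        sub = df[df["time"] == tp]
        if sub["treat"].nunique() < 2:
            continue
        for treated, delta, p_adj in tukey_vs_control(
                sub["resp"].to_numpy(), sub["treat"].to_numpy(), control):
            direction = _direction(delta, p_adj < alpha)
            rows.append({
                "group": f"{treated}@{tp}", "comparator": f"{control}@{tp}",
                "endpoint": response_col, "test": "tukey",
                "statistic": delta, "p_raw": np.nan, "p_adjusted": p_adj,
                "adjustment": "tukey", "direction": direction,
            })
            calls.append({"treatment": treated, "timepoint_hr": tp,
                          "call": direction})
    results = pd.DataFrame(rows, columns=RESULT_COLS)
    calls_df = pd.DataFrame(calls, columns=["treatment", "timepoint_hr",
                                            "call"])
    calls_df = calls_df.sort_values(["treatment", "timepoint_hr"],
                                    kind="stable").reset_index(drop=True)
    return results, calls_df


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordanceTable:
    """Fresh-vs-frozen response-call agreement (the discordance summary)."""

    rows: pd.DataFrame  # per (sample, prep, recovery, treatment, timepoint)
    by_preparation: pd.DataFrame
    by_recovery: pd.DataFrame
    n_discordant: int
    n_total: int

    @property
    def inconsistency_fraction(self) -> float:
        return self.n_discordant / self.n_total if self.n_total else np.nan


def concordance(
    fresh_calls: pd.DataFrame,
    frozen_calls: pd.DataFrame,
    scope: Optional[Mapping[str, object]] = None,
) -> ConcordanceTable:
    """Score frozen-preparation response calls against fresh counterparts.

    Calls are matched on (sample, treatment, timepoint_hr); the comparison
    is three-level, so a significant increase vs a significant decrease vs
    no change are mutually discordant.  ``scope`` filters the frozen calls
    first (e.g. ``{"timepoint_hr": 72, "recovery_days": 7}``).  Frozen calls
    without a fresh counterpart are skipped and logged.
    """
    frozen = frozen_calls.copy()
    if scope:
        for k, v in scope.items():
            frozen = frozen[frozen[k] == v]
    keys = ["sample", "treatment", "timepoint_hr"]
    fresh_idx = fresh_calls.set_index(keys)["call"]
    if fresh_idx.index.has_duplicates:
        raise ValueError("fresh calls must be unique per (sample, treatment, "
                         "timepoint)")
    rows = []
    skipped = 0
    for _, r in frozen.iterrows():
        key = (r["sample"], r["treatment"], r["timepoint_hr"])
        if key not in fresh_idx.index:
            skipped += 1
            continue
        fresh_call = fresh_idx.loc[key]
        rows.append({
            "sample": r["sample"],
            "preparation": r.get("preparation", "frozen"),
            "recovery_days": r.get("recovery_days", np.nan),
            "treatment": r["treatment"],
            "timepoint_hr": r["timepoint_hr"],
            "fresh_call": fresh_call,
            "frozen_call": r["call"],
            "concordant": fresh_call == r["call"],
        })
    if skipped:
        log.warning("concordance: skipped %d frozen calls without a fresh "
                    "counterpart", skipped)
    table = pd.DataFrame(rows, columns=["sample", "preparation",
                                        "recovery_days", "treatment",
                                        "timepoint_hr", "fresh_call",
                                        "frozen_call", "concordant"])

    def summarize(by: str) -> pd.DataFrame:
        if table.empty:
            return pd.DataFrame(columns=[by, "n_discordant", "n_total",
                                         "inconsistency_fraction"])
        g = table.groupby(by, dropna=False)["concordant"]
        out = pd.DataFrame({
            "n_discordant": g.apply(lambda s: int((~s).sum())),
            "n_total": g.size(),
        })
        out["inconsistency_fraction"] = out["n_discordant"] / out["n_total"]
        return out.reset_index()

    n_total = len(table)
    n_disc = int((~table["concordant"]).sum()) if n_total else 0
    return ConcordanceTable(
        rows=table,
        by_preparation=summarize("preparation"),
        by_recovery=summarize("recovery_days"),
        n_discordant=n_disc,
        n_total=n_total,
    )


# ---------------------------------------------------------------------------
# correlation and staining


def correlate_fresh_frozen(
    fresh_means: np.ndarray, frozen_means: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between paired group OMI means."""
    a = np.asarray(fresh_means, dtype=float)
    b = np.asarray(frozen_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def positive_fraction(
    stain_table: pd.DataFrame,
    positive_col: str = "positive",
    organoid_col: str = "organoid_id",
    group_col: Optional[str] = None,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Per-organoid percentage of positively stained cells.

    Returns the per-organoid table (optionally with a group column) and,
    when ``group_col`` is given and every group has >= 3 organoids, the
    Kruskal-Wallis + Dunn comparison of the per-organoid percentages.
    Organoids with zero cells are excluded and logged.
    """
    df = stain_table.copy()
    counts = df.groupby(organoid_col).size()
    empty = counts[counts == 0]
    if len(empty):
        log.warning("positive_fraction: excluded %d empty organoids",
                    len(empty))
    agg_cols = {organoid_col: "first"}
    grouping = [organoid_col] + ([group_col] if group_col else [])
    per_org = (
        df.groupby(grouping)[positive_col]
        .agg(["mean", "size"])
        .rename(columns={"mean": "fraction", "size": "n_cells"})
        .reset_index()
    )
    per_org["percent_positive"] = per_org["fraction"] * 100.0
    per_org = per_org.drop(columns=["fraction"])

    tests = None
    if group_col is not None and per_org[group_col].nunique() >= 2:
        groups = {
            str(g): sub["percent_positive"].to_numpy()
            for g, sub in per_org.groupby(group_col)
        }
        if all(v.size >= 3 for v in groups.values()):
            tests = compare_morphology_groups(
                groups, endpoint="percent_positive", alpha=alpha)
    return per_org, tests
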