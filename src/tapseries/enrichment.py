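"""Max-time-point enrichment statistics for bait-prey time courses.

The core interaction score asks, per protein: is the bait pulldown at
its best time point significantly more abundant than the pooled
control pulldowns?  Fold enrichment is the ratio of the highest bait
time-point mean (excluding the wrap-around ZT 31 point, which repeats
ZT 7) to the mean over all control samples.  Significance comes from a
two-sided Welch t-test of the bait replicates at that time point
against all control samples, with Benjamini-Hochberg correction across
testable proteins.  Candidates are tiered by fold enrichment:
``high`` (>= 4-fold, q < 0.05), ``weak`` (2-4-fold, q < 0.05),
``none`` otherwise, and ``untestable`` when missing quantifications
make the t-test impossible.

The control group pools all control samples across time points:
controls are singletons per time point in the reference design, so a
per-time-point comparison has no replication.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BAIT, CONTROL, SampleRecord, WRAP_TIMEPOINT, sample_columns

__all__ = [
    "fold_enrichment",
    "enrichment_test",
    "bh_adjust",
    "assign_tier",
    "enrich",
    "TIER_HIGH",
    "TIER_WEAK",
    "TIER_NONE",
    "TIER_UNTESTABLE",
]

TIER_HIGH = "high"
TIER_WEAK = "weak"
TIER_NONE = "none"
TIER_UNTESTABLE = "untestable"

DEFAULT_Q_CUT = 0.05
DEFAULT_HIGH_FOLD = 4.0
DEFAULT_WEAK_FOLD = 2.0


def _bait_groups(
    table: pd.DataFrame, design: Sequence[SampleRecord]
) -> dict[float, list[str]]:
    groups: dict[float, list[str]] = {}
    for s in design:
        if s.genotype == BAIT and s.sample_id in table.columns:
            groups.setdefault(s.zt, []).append(s.sample_id)
    return groups


def fold_enrichment(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    wrap_zt: float = WRAP_TIMEPOINT,
) -> pd.DataFrame:
    """Per-protein maximum bait time point and fold enrichment.

    Time-point means treat missing values as zero (below-detection
    convention).  The wrap-around time point is omitted from the
    argmax; ties break to the earliest ZT.  Returns a DataFrame with
    columns ``max_zt``, ``bait_max_mean``, ``control_mean`` and
    ``fold_enrichment`` (NaN when no control value is quantified).
    """
    groups = _bait_groups(table, design)
    control_ids = [s for s in sample_columns(design, CONTROL) if s in table.columns]
    if not control_ids:
        raise ValueError("design contains no control samples present in the table")
    zts = sorted(z for z in groups if z != wrap_zt)

    means = {
        z: np.nan_to_num(table[groups[z]].to_numpy(dtype=float), nan=0.0).mean(axis=1)
        for z in zts
    }
    M = np.column_stack([means[z] for z in zts])
    argmax = M.argmax(axis=1)  # first occurrence wins -> earliest ZT
    bait_max = M[np.arange(len(M)), argmax]
    max_zt = np.array(zts)[argmax]

    ctrl = table[control_ids].to_numpy(dtype=float)
    all_missing = np.all(np.isnan(ctrl), axis=1)
    ctrl_mean = np.nan_to_num(ctrl, nan=0.0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(all_missing, np.nan, bait_max / ctrl_mean)

    return pd.DataFrame(
        {
            "max_zt": max_zt,
            "bait_max_mean": bait_max,
            "control_mean": np.where(all_missing, np.nan, ctrl_mean),
            "fold_enrichment": fold,
        },
        index=table.index,
    )


def enrichment_test(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    max_zt: pd.Series | None = None,
    wrap_zt: float = WRAP_TIMEPOINT,
) -> pd.DataFrame:
    """Welch t-test of bait replicates at the maximum time point vs controls.

    Uses the quantified (non-missing) values only; a protein with
    fewer than two quantified bait replicates at its maximum time
    point, or fewer than two quantified control values, is untestable
    (``p`` = NaN) and is excluded from multiplicity correction.
    """
    if max_zt is None:
        max_zt = fold_enrichment(table, design, wrap_zt=wrap_zt)["max_zt"]
    groups = _bait_groups(table, design)
    control_ids = [s for s in sample_columns(design, CONTROL) if s in table.columns]
    t_stat = np.full(len(table), np.nan)
    p_val = np.full(len(table), np.nan)
    ctrl = table[control_ids].to_numpy(dtype=float)
    for i, key in enumerate(table.index):
        z = float(max_zt.loc[key])
        bait = table.loc[key, groups[z]].to_numpy(dtype=float)
        b = bait[~np.isnan(bait)]
        c = ctrl[i][~np.isnan(ctrl[i])]
        if len(b) < 2 or len(c) < 2:
            continue
        if np.var(b) == 0 and np.var(c) == 0:
            # degenerate but testable: identical constants -> no evidence
            t_stat[i], p_val[i] = (0.0, 1.0) if b.mean() == c.mean() else (np.inf, 0.0)
            continue
        t, p = stats.ttest_ind(b, c, equal_var=False)
        t_stat[i], p_val[i] = float(t), float(p)
    return pd.DataFrame({"t_statistic": t_stat, "p": p_val}, index=table.index)


def bh_adjust(p_values: Sequence[float] | np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_(j >= i) (m * p_(j) / j)`` over the sorted p-values,
    clipped at 1 and mapped back to the input order.  NaN entries
    (untestable proteins) are passed through and never counted in
    ``m`` unless ``m`` is given explicitly; an explicit ``m`` may
    exceed the number of supplied p-values (tests that could not be
    performed still inflate the multiplicity).
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if np.any((p[defined] < 0) | (p[defined] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = int(defined.sum())
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m={m} smaller than number of defined p-values ({k})")
    q = np.full_like(p, np.nan)
    if k == 0:
        return q
    order = np.argsort(p[defined], kind="stable")
    sorted_p = p[defined][order]
    ranks = np.arange(1, k + 1)
    stepped = np.minimum.accumulate((m * sorted_p / ranks)[::-1])[::-1]
    adj = np.minimum(stepped, 1.0)
    out = np.empty(k)
    out[order] = adj
    q[defined] = out
    return q


def assign_tier(
    q: float,
    fold: float,
    q_cut: float = DEFAULT_Q_CUT,
    high_fold: float = DEFAULT_HIGH_FOLD,
    weak_fold: float = DEFAULT_WEAK_FOLD,
) -> str:
    """Tier a single protein from its q-value and fold enrichment."""
    if np.isnan(q) or np.isnan(fold):
        return TIER_UNTESTABLE
    if q < q_cut and fold >= high_fold:
        return TIER_HIGH
    if q < q_cut and weak_fold <= fold < high_fold:
        return TIER_WEAK
    return TIER_NONE


def enrich(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    q_cut: float = DEFAULT_Q_CUT,
    high_fold: float = DEFAULT_HIGH_FOLD,
    weak_fold: float = DEFAULT_WEAK_FOLD,
    wrap_zt: float = WRAP_TIMEPOINT,
    m: int | None = None,
) -> pd.DataFrame:
    """Full enrichment analysis: fold, Welch test, BH correction, tiers."""
    fe = fold_enrichment(table, design, wrap_zt=wrap_zt)
    test = enrichment_test(table, design, max_zt=fe["max_zt"], wrap_zt=wrap_zt)
    out = pd.concat([fe, test], axis=1)
    out["q"] = bh_adjust(out["p"].to_numpy(), m=m)
    out["tier"] = [
        assign_tier(q, f, q_cut=q_cut, high_fold=high_fold, weak_fold=weak_fold)
        for q, f in zip(out["q"], out["fold_enrichment"])
    ]
    return out
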