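"""Candidate summaries: phase histogram, profile correlation,
over-representation testing and heatmap row ordering."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import TIER_HIGH, TIER_WEAK, bh_adjust
from .io import BAIT, SampleRecord, WRAP_TIMEPOINT

__all__ = [
    "phase_histogram",
    "profile_correlation",
    "go_fisher",
    "heatmap_order",
    "bait_profile",
]


def bait_profile(
    table: pd.DataFrame, design: Sequence[SampleRecord], accession: str
) -> pd.Series:
    """Bait time-point mean profile of one protein (wrap point included).

    Missing values count as zero in the means, matching the
    enrichment-stage convention.
    """
    groups: dict[float, list[str]] = {}
    for s in design:
        if s.genotype == BAIT and s.sample_id in table.columns:
            groups.setdefault(s.zt, []).append(s.sample_id)
    zts = sorted(groups)
    vals = [
        float(np.nan_to_num(table.loc[accession, groups[z]].to_numpy(dtype=float), nan=0.0).mean())
        for z in zts
    ]
    return pd.Series(vals, index=zts, name=accession)


def phase_histogram(
    rhythm: pd.DataFrame,
    enrichment: pd.DataFrame,
    design: Sequence[SampleRecord],
    q_cut: float = 0.05,
    wrap_zt: float = WRAP_TIMEPOINT,
) -> pd.Series:
    """Peak-time counts of enriched, temporally significant proteins.

    Restricts to proteins tiered ``high`` or ``weak`` whose ANOVA q or
    JTK q falls below ``q_cut``; counts ``peak_zt`` per (non-wrap)
    bait time point.  Counts sum to the number of selected proteins.
    """
    zts = sorted({s.zt for s in design if s.genotype == BAIT and s.zt != wrap_zt})
    counts = pd.Series(0, index=pd.Index(zts, name="zt"), dtype=int)
    enriched = enrichment["tier"].isin([TIER_HIGH, TIER_WEAK])
    sig = (rhythm["anova_q"] < q_cut) | (rhythm["jtk_q"] < q_cut)
    selected = rhythm.index[enriched.reindex(rhythm.index, fill_value=False) & sig.fillna(False)]
    for acc in selected:
        z = float(rhythm.loc[acc, "peak_zt"])
        if z in counts.index:
            counts[z] += 1
    return counts


def profile_correlation(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    a: str,
    b: str,
) -> float:
    """Pearson correlation between two proteins' bait mean profiles.

    Profiles run over all bait time points including the wrap-around
    one.  Returns NaN when either profile is constant.
    """
    pa = bait_profile(table, design, a).to_numpy()
    pb = bait_profile(table, design, b).to_numpy()
    if len(pa) < 3:
        raise ValueError("profile correlation needs at least 3 time points")
    if np.std(pa) == 0 or np.std(pb) == 0:
        return float("nan")
    return float(np.corrcoef(pa, pb)[0, 1])


def go_fisher(
    foreground: set[str],
    background: set[str],
    terms: Mapping[str, set[str]],
    min_node: int = 3,
) -> pd.DataFrame:
    """One-sided over-representation test per annotation term.

    For every term annotating at least ``min_node`` background
    members: hypergeometric p-value for over-representation of the
    term in the foreground, BH-corrected across tested terms.
    """
    if not background:
        raise ValueError("background set is empty")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    term_members: dict[str, set[str]] = {}
    for acc in background:
        for t in terms.get(acc, ()):
            term_members.setdefault(t, set()).add(acc)
    rows = []
    N, n = len(background), len(foreground)
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        if K < min_node:
            continue
        k = len(members & foreground)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, K, k, p))
    out = pd.DataFrame(rows, columns=["term", "n_background", "n_foreground", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.set_index("term")


def heatmap_order(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    subset: Sequence[str] | None = None,
) -> list[str]:
    """Row order for an abundance heatmap.

    Bait time-point mean profiles are z-scored per protein, then
    hierarchically clustered with distance 1 - Pearson and average
    linkage; the dendrogram leaf order is returned.  Rows are sorted
    by accession before clustering so ties resolve deterministically.
    """
    accs = sorted(subset) if subset is not None else sorted(table.index)
    if not accs:
        raise ValueError("empty subset")
    if len(accs) == 1:
        return list(accs)
    profiles = np.vstack([bait_profile(table, design, a).to_numpy() for a in accs])
    sd = profiles.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = np.corrcoef(z)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return [accs[i] for i in leaves]
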