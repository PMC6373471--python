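"""Temporal-change and rhythm detection for bait time courses.

Two complementary detectors run on the bait samples:

* **arcsinh ANOVA** -- a one-way fixed-effects ANOVA across time-point
  groups (the wrap-around ZT 31 point is its own group) on
  arcsinh-transformed abundances, sensitive to any temporal change.
* **JTK scan** -- a nonparametric rhythm test in the spirit of
  JTK_CYCLE: the observed series is rank-correlated (Kendall S)
  against cosine reference waveforms over a grid of periods (22-26 h)
  and phase lags (2-h steps), and the one-sided p-value of the best
  reference comes from the exact combinatorial null distribution of S
  under random orderings, computed by generating-function dynamic
  programming over the reference tie groups (replicates at one time
  point share a reference value and are tied by construction).

The minimum p over the reference grid is Bonferroni-corrected for the
number of (period, lag) combinations scanned, as the JTK_CYCLE tool
does for its adjusted p-value; without this within-protein correction
the minimum of ~60 dependent exact tests is strongly anti-conservative
and the downstream across-protein BH step loses false-discovery-rate
control.  Peak time is the Zeitgeber time of the maximal bait
replicate mean, with the wrap-around point folded onto the time point
it replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .io import BAIT, SampleRecord, WRAP_TIMEPOINT

__all__ = [
    "ReferenceWaveform",
    "build_references",
    "arcsinh_anova",
    "kendall_s",
    "jtk_exact_null",
    "jtk_scan",
    "peak_time",
    "rhythm_analysis",
    "DEFAULT_PERIODS",
    "DEFAULT_LAG_STEP",
]

DEFAULT_PERIODS = (22.0, 23.0, 24.0, 25.0, 26.0)
DEFAULT_LAG_STEP = 2.0

_ROUND = 9  # decimals for tie detection among reference cosine values


@dataclass(frozen=True)
class ReferenceWaveform:
    """Cosine reference ordering for one (period, lag) combination.

    ``values[i] = cos(2*pi*(zt_i - lag)/period)`` at each bait
    sample's Zeitgeber time, rounded so replicate samples (and any
    coincidentally equal cosine values) are exact ties.
    """

    period: float
    lag: float
    values: tuple[float, ...]


def build_references(
    zts: Sequence[float],
    periods: Sequence[float] = DEFAULT_PERIODS,
    lag_step: float = DEFAULT_LAG_STEP,
) -> list[ReferenceWaveform]:
    """Reference waveforms over the period grid with lags in [0, period)."""
    refs = []
    zt = np.asarray(zts, dtype=float)
    for period in periods:
        for lag in np.arange(0.0, period, lag_step):
            vals = np.cos(2.0 * np.pi * (zt - lag) / period)
            refs.append(ReferenceWaveform(float(period), float(lag), tuple(np.round(vals, _ROUND))))
    return refs


# ---------------------------------------------------------------------------
# ANOVA on arcsinh-transformed abundances
# ---------------------------------------------------------------------------


def arcsinh_anova(table: pd.DataFrame, design: Sequence[SampleRecord]) -> pd.DataFrame:
    """One-way ANOVA across bait time points on arcsinh(x) = ln(x + sqrt(x^2+1)).

    The wrap-around time point forms its own group.  Groups with fewer
    than two quantified values are dropped; a protein needs at least
    two usable groups, otherwise F and p are undefined (NaN).
    """
    groups: dict[float, list[str]] = {}
    for s in design:
        if s.genotype == BAIT and s.sample_id in table.columns:
            groups.setdefault(s.zt, []).append(s.sample_id)
    zts = sorted(groups)
    F = np.full(len(table), np.nan)
    P = np.full(len(table), np.nan)
    data = {z: table[groups[z]].to_numpy(dtype=float) for z in zts}
    for i in range(len(table)):
        samples = []
        for z in zts:
            v = data[z][i]
            v = v[~np.isnan(v)]
            if len(v) >= 2:
                samples.append(np.arcsinh(v))
        if len(samples) < 2:
            continue
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            F[i], P[i] = 0.0, 1.0
            continue
        f, p = stats.f_oneway(*samples)
        if np.isnan(f):  # zero between-group variance with zero within
            f, p = 0.0, 1.0
        F[i], P[i] = float(f), float(p)
    return pd.DataFrame({"anova_F": F, "anova_p": P}, index=table.index)


# ---------------------------------------------------------------------------
# Kendall S against a reference and its exact null
# ---------------------------------------------------------------------------


def kendall_s(data: Sequence[float], reference: Sequence[float]) -> tuple[int, float]:
    """Kendall concordance score of a series against a reference ordering.

    ``S = sum_{i<j} sign(x_i - x_j) * sign(r_i - r_j)`` over pairs of
    non-missing observations; pairs tied in either the data or the
    reference contribute zero.  ``tau`` is S divided by the maximum
    attainable |S| given both tie patterns (the number of pairs untied
    in both).  Requires at least three non-missing points.
    """
    x = np.asarray(data, dtype=float)
    r = np.asarray(reference, dtype=float)
    ok = ~np.isnan(x)
    x, r = x[ok], r[ok]
    n = len(x)
    if n < 3:
        raise ValueError("kendall_s requires at least 3 non-missing points")
    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[i] - x[j])
    sr = np.sign(r[i] - r[j])
    s = int(np.sum(sx * sr))
    denom = int(np.sum((sx != 0) & (sr != 0)))
    tau = s / denom if denom else 0.0
    return s, float(tau)


def _qbinom_counts(m: int, n: int) -> list[int]:
    """Coefficients of the Gaussian binomial [m choose n]_q as exact ints.

    Coefficient of q^u counts the interleavings of n new items among
    m-n old ones producing a Mann-Whitney count of u; this is the
    partition-counting block of the Harding recursion for the
    Jonckheere-Terpstra null.  Computed as
    prod_{i=1..n} (1 - q^{b+i}) / (1 - q^i) with all polynomial
    arithmetic exact in integers mod q^{n(m-n)+1} (the result has
    degree exactly n(m-n), so truncation is lossless).
    """
    a, b = n, m - n
    size = a * b + 1
    coeffs = [0] * size
    coeffs[0] = 1
    for i in range(1, a + 1):
        prev = coeffs[:]
        # multiply by (1 - q^{b+i})
        for u in range(size - 1, b + i - 1, -1):
            coeffs[u] = prev[u] - prev[u - (b + i)]
        # divide by (1 - q^i): power-series expansion, forward accumulation
        for u in range(i, size):
            coeffs[u] += coeffs[u - i]
    return coeffs


@lru_cache(maxsize=4096)
def _jt_null_counts(group_sizes: tuple[int, ...]) -> tuple[int, ...]:
    """Exact ordering counts of the Jonckheere-Terpstra statistic.

    For reference tie groups of the given sizes, returns counts[u] =
    number of orderings of distinct data values whose total
    between-group Mann-Whitney count is u.  Built by convolving
    Gaussian-binomial blocks, one per group merged into the running
    pool (Harding's generating-function construction).
    """
    counts: list[int] = [1]
    pooled = 0
    for n in group_sizes:
        if pooled and n:
            block = _qbinom_counts(pooled + n, n)
            out = [0] * (len(counts) + len(block) - 1)
            for u, cu in enumerate(counts):
                if cu:
                    for v, bv in enumerate(block):
                        if bv:
                            out[u + v] += cu * bv
            counts = out
        pooled += n
    return tuple(counts)


def jtk_exact_null(group_sizes: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the Kendall score S for a reference tie pattern.

    Under uniformly random orderings of distinct data values, with the
    reference tying ``group_sizes[g]`` observations at each of its
    levels, returns ``(s_values, pmf)``.  S relates to the
    Jonckheere-Terpstra count U by ``S = 2U - M`` with M the number of
    between-group pairs, so the support has stride 2 and the pmf is
    symmetric about zero and sums to one.
    """
    sizes = tuple(int(n) for n in group_sizes if n > 0)
    counts = np.array(_jt_null_counts(sizes), dtype=object)
    total = sum(int(c) for c in counts)
    m_pairs = 0
    pooled = 0
    for n in sizes:
        m_pairs += pooled * n
        pooled += n
    s_values = 2 * np.arange(len(counts)) - m_pairs
    pmf = np.array([int(c) / total for c in counts], dtype=float)
    return s_values, pmf


def _null_tail(group_sizes: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """(s_values, P(S >= s)) lookup arrays for one tie pattern."""
    s_values, pmf = jtk_exact_null(group_sizes)
    tail = np.cumsum(pmf[::-1])[::-1]
    return s_values, tail


def _one_sided_p(s_obs: int, s_values: np.ndarray, tail: np.ndarray) -> float:
    idx = np.searchsorted(s_values, s_obs, side="left")
    if idx >= len(tail):
        return 0.0 if s_obs > s_values[-1] else float(tail[-1])
    return float(tail[idx])


def _group_sizes(ref_values: np.ndarray) -> tuple[int, ...]:
    """Tie-group sizes of a reference, ordered by reference value."""
    vals, counts = np.unique(ref_values, return_counts=True)
    return tuple(int(c) for c in counts)


def jtk_scan(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    periods: Sequence[float] = DEFAULT_PERIODS,
    lag_step: float = DEFAULT_LAG_STEP,
    grid_correction: bool = True,
) -> pd.DataFrame:
    """Scan every protein against the cosine reference grid.

    For each protein the one-sided exact p-value ``P(S >= S_obs)`` is
    computed for every reference.  When several references tie at the
    minimal p (common for clean rhythms, where e.g. a short period
    with a late lag and a long period with an early lag induce the
    same ordering), the reported period is their mean and the reported
    lag their circular mean on the 24-h circle -- the convention of
    the JTK_CYCLE tool; S and tau come from the first tied reference
    in scan order.  With ``grid_correction`` (default) the minimal p
    is Bonferroni-scaled by the number of references scanned before
    the across-protein BH step; disabling it reports the raw minimum,
    which is anti-conservative.  BH across proteins yields ``jtk_q``.
    Proteins with fewer than three quantified bait values are
    undefined (NaN).
    """
    bait = [s for s in design if s.genotype == BAIT and s.sample_id in table.columns]
    if len({s.zt for s in bait}) < 4:
        raise ValueError("JTK scan requires at least 4 distinct bait time points")
    ids = [s.sample_id for s in bait]
    zts = [s.zt for s in bait]
    refs = build_references(zts, periods=periods, lag_step=lag_step)

    X = table[ids].to_numpy(dtype=float)
    n_prot, n = X.shape
    i_idx, j_idx = np.triu_indices(n, k=1)
    diff = X[:, i_idx] - X[:, j_idx]
    sx = np.sign(diff)
    missing_pair = np.isnan(diff)
    sx = np.where(missing_pair, 0.0, sx)
    mask = ~np.isnan(X)
    usable = mask.sum(axis=1) >= 3

    # group proteins by missing pattern once; the exact null depends on
    # the tie groups surviving in the non-missing subset
    tail_cache: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}
    pattern_rows: dict[bytes, list[int]] = {}
    for k in np.nonzero(usable)[0]:
        pattern_rows.setdefault(mask[k].tobytes(), []).append(k)
    patterns = [
        (np.frombuffer(key, dtype=bool), np.array(rows))
        for key, rows in pattern_rows.items()
    ]

    n_refs = len(refs)
    P = np.full((n_refs, n_prot), np.nan)
    S_all = np.zeros((n_refs, n_prot), dtype=np.int32)
    for ref_id, ref in enumerate(refs):
        rv = np.asarray(ref.values)
        sr = np.sign(rv[i_idx] - rv[j_idx])
        S = (sx * sr).sum(axis=1).astype(np.int32)
        S_all[ref_id] = S
        for pat, rows in patterns:
            sizes = _group_sizes(rv[pat])
            if sizes not in tail_cache:
                tail_cache[sizes] = _null_tail(sizes)
            s_values, tail = tail_cache[sizes]
            idxs = np.searchsorted(s_values, S[rows], side="left")
            idxs = np.clip(idxs, 0, len(tail) - 1)
            pr = tail[idxs]
            pr = np.where(S[rows] > s_values[-1], 0.0, pr)
            P[ref_id, rows] = pr

    periods_arr = np.array([r.period for r in refs])
    lags_arr = np.array([r.lag for r in refs])
    period_out = np.full(n_prot, np.nan)
    lag_out = np.full(n_prot, np.nan)
    s_out = np.zeros(n_prot, dtype=int)
    tau_out = np.full(n_prot, np.nan)
    p_out = np.full(n_prot, np.nan)
    for k in np.nonzero(usable)[0]:
        pmin = np.nanmin(P[:, k])
        tied = np.nonzero(P[:, k] == pmin)[0]
        first = int(tied[0])
        period_out[k] = periods_arr[tied].mean()
        ang = 2.0 * np.pi * lags_arr[tied] / 24.0
        mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        lag_out[k] = round((mean_ang * 24.0 / (2.0 * np.pi)) % 24.0, 9)
        s_out[k] = int(S_all[first, k])
        _, tau_out[k] = kendall_s(X[k], np.asarray(refs[first].values))
        p_out[k] = pmin

    out = pd.DataFrame(index=table.index)
    out["jtk_period"] = period_out
    out["jtk_lag"] = lag_out
    out["jtk_S"] = s_out
    out["jtk_tau"] = tau_out
    if grid_correction:
        p_out = np.minimum(p_out * n_refs, 1.0)
    out["jtk_p"] = p_out
    out["jtk_q"] = bh_adjust(out["jtk_p"].to_numpy())
    return out


def peak_time(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    wrap_zt: float = WRAP_TIMEPOINT,
    wrap_onto: float | None = None,
) -> pd.Series:
    """Zeitgeber time of each protein's maximal bait replicate mean.

    Samples at the wrap-around time point are pooled with the time
    point they replicate (ZT 31 -> ZT 7 by default, i.e. 24 h
    earlier).  Ties break to the earliest ZT.  Missing values count as
    zero in the means.
    """
    if wrap_onto is None:
        wrap_onto = wrap_zt - 24.0
    groups: dict[float, list[str]] = {}
    for s in design:
        if s.genotype == BAIT and s.sample_id in table.columns:
            z = wrap_onto if s.zt == wrap_zt else s.zt
            groups.setdefault(z, []).append(s.sample_id)
    zts = sorted(groups)
    M = np.column_stack(
        [
            np.nan_to_num(table[groups[z]].to_numpy(dtype=float), nan=0.0).mean(axis=1)
            for z in zts
        ]
    )
    peak = np.array(zts)[M.argmax(axis=1)]
    return pd.Series(peak, index=table.index, name="peak_zt")


def rhythm_analysis(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    periods: Sequence[float] = DEFAULT_PERIODS,
    lag_step: float = DEFAULT_LAG_STEP,
) -> pd.DataFrame:
    """Combined ANOVA + JTK + peak-time results per protein."""
    anova = arcsinh_anova(table, design)
    anova["anova_q"] = bh_adjust(anova["anova_p"].to_numpy())
    jtk = jtk_scan(table, design, periods=periods, lag_step=lag_step)
    peaks = peak_time(table, design)
    return pd.concat([anova, jtk, peaks], axis=1)
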