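"""Technical-outlier detection for replicated pulldown time courses.

A bait sample is flagged only when two independent signals agree: its
mean Pearson correlation with same-time-point replicates falls below a
threshold (default 0.95) AND it separates from the sample cloud in the
first two principal components (default: more than 3 pooled standard
deviations from the centroid).  The conjunction makes the decision
deterministic and conservative -- neither noisy correlations at a
single time point nor PCA leverage alone can discard a sample.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import BAIT, SampleRecord, sample_columns

__all__ = [
    "replicate_correlation",
    "pca_scores",
    "flag_outliers",
    "qc_report",
    "DEFAULT_R_THRESHOLD",
    "DEFAULT_PC_SD_MULT",
]

DEFAULT_R_THRESHOLD = 0.95
DEFAULT_PC_SD_MULT = 3.0


def replicate_correlation(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    log_scale: bool = False,
) -> pd.Series:
    """Mean within-time-point Pearson correlation of each bait sample.

    For every bait sample, the Pearson r against each same-time-point
    bait replicate is computed over proteins quantified in both runs,
    then averaged.  Samples at a time point with a single replicate get
    NaN (undefined, never flagged).  ``log_scale`` correlates
    log-transformed abundances instead of raw ones.
    """
    bait = [s for s in design if s.genotype == BAIT and s.sample_id in table.columns]
    out = pd.Series(np.nan, index=pd.Index([s.sample_id for s in bait], name="sample_id"))
    by_zt: dict[float, list[str]] = {}
    for s in bait:
        by_zt.setdefault(s.zt, []).append(s.sample_id)
    for ids in by_zt.values():
        if len(ids) < 2:
            continue
        for sid in ids:
            rs = []
            for other in ids:
                if other == sid:
                    continue
                x = table[sid].to_numpy(dtype=float)
                y = table[other].to_numpy(dtype=float)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    continue
                xa, ya = x[ok], y[ok]
                if log_scale:
                    xa, ya = np.log1p(xa), np.log1p(ya)
                if np.std(xa) == 0 or np.std(ya) == 0:
                    continue
                rs.append(float(np.corrcoef(xa, ya)[0, 1]))
            if rs:
                out[sid] = float(np.mean(rs))
    return out


def pca_scores(table: pd.DataFrame, sample_ids: Sequence[str] | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples over protein abundances.

    Proteins with any missing value are omitted from the input (the
    simplest bias-free treatment); samples are the observations and are
    mean-centered.  Returns per-sample scores (columns ``PC1``,
    ``PC2``, ...) and the explained-variance fractions.
    """
    if sample_ids is None:
        sample_ids = [c for c in table.columns if c not in ("gene_name", "n_unique_peptides")]
    if len(sample_ids) < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = table[list(sample_ids)].to_numpy(dtype=float).T  # samples x proteins
    complete = ~np.isnan(X).any(axis=0)
    X = X[:, complete]
    n_comp = min(X.shape[0], X.shape[1])
    if n_comp == 0:
        raise ValueError("no completely quantified protein available for PCA")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    df = pd.DataFrame(scores, index=pd.Index(sample_ids, name="sample_id"), columns=cols)
    return df, pca.explained_variance_ratio_


def flag_outliers(
    mean_r: pd.Series,
    scores: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    pc_sd_mult: float = DEFAULT_PC_SD_MULT,
) -> pd.DataFrame:
    """Combine correlation and PCA evidence into flag decisions.

    A sample is flagged iff its mean replicate correlation is below
    ``r_threshold`` and its Euclidean distance from the sample centroid
    in the PC1/PC2 plane exceeds ``pc_sd_mult`` times the pooled
    per-axis standard deviation.
    """
    pcs = scores[["PC1", "PC2"]] if "PC2" in scores.columns else scores[["PC1"]].assign(PC2=0.0)
    centroid = pcs.mean(axis=0)
    centered = pcs - centroid
    pooled_sd = float(np.sqrt(centered.to_numpy().var(axis=0, ddof=1).mean()))
    dist = np.sqrt((centered**2).sum(axis=1))

    rows = []
    for sid in scores.index:
        r = float(mean_r.get(sid, np.nan))
        d = float(dist[sid])
        low_r = not np.isnan(r) and r < r_threshold
        far = pooled_sd > 0 and d > pc_sd_mult * pooled_sd
        flagged = bool(low_r and far)
        reason = ""
        if flagged:
            reason = (
                f"mean replicate r={r:.3f} < {r_threshold:g} and "
                f"PC distance {d:.3g} > {pc_sd_mult:g} x pooled sd {pooled_sd:.3g}"
            )
        rows.append((sid, r, float(pcs.loc[sid, "PC1"]), float(pcs.loc[sid, "PC2"]), flagged, reason))
    return pd.DataFrame(
        rows, columns=["sample_id", "mean_r", "PC1", "PC2", "flagged", "reason"]
    ).set_index("sample_id")


def qc_report(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    pc_sd_mult: float = DEFAULT_PC_SD_MULT,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Full QC pass over the bait samples of a protein table."""
    bait_ids = [s for s in sample_columns(design, BAIT) if s in table.columns]
    mean_r = replicate_correlation(table, design, log_scale=log_scale)
    scores, _ = pca_scores(table, bait_ids)
    return flag_outliers(mean_r, scores, r_threshold=r_threshold, pc_sd_mult=pc_sd_mult)
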