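"""Background removal and the qualitative presence/absence screen.

Two complementary filters remove likely nonspecific preys from a
pulldown: a tag-binder exclusion list (proteins known to co-purify
with the affinity tag alone) and a compartment filter that discards
proteins annotated exclusively to organelles the bait cannot reach in
an intact cell (plastid/mitochondrion with no cytosolic or nuclear
annotation).  Exclusion acts at the protein-group level: if any member
accession of a group is excluded the whole group is removed, so a tag
binder can never hide inside a shared-peptide group.  A filter ledger
records survivor counts after each stage.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import BAIT, CONTROL, SampleRecord, sample_columns

__all__ = [
    "apply_exclusion_list",
    "compartment_filter",
    "qualitative_screen",
    "filter_ledger",
    "removal_audit",
]

_ORGANELLE = {"plastid", "mitochondrion"}


def _group_accessions(key: str) -> list[str]:
    return [a.strip().upper() for a in key.split(";") if a.strip()]


def apply_exclusion_list(table: pd.DataFrame, accessions: Iterable[str]) -> pd.DataFrame:
    """Drop protein groups intersecting an exclusion list."""
    excl = {a.upper() for a in accessions}
    keep = [not (set(_group_accessions(k)) & excl) for k in table.index]
    return table.loc[keep]


def compartment_filter(table: pd.DataFrame, annotations: Mapping[str, set[str]]) -> pd.DataFrame:
    """Drop groups annotated only to inaccessible compartments.

    A group is removed when the union of its members' location
    annotations is non-empty and lies entirely within
    {plastid, mitochondrion}.  Unannotated groups are retained.
    """
    keep = []
    for key in table.index:
        locs: set[str] = set()
        for acc in _group_accessions(key):
            locs |= set(annotations.get(acc, ()))
        keep.append(not locs or not locs <= _ORGANELLE)
    return table.loc[keep]


def qualitative_screen(
    peptide_counts: pd.DataFrame, design: Sequence[SampleRecord]
) -> set[str]:
    """Presence/absence candidate screen on qualitative peptide counts.

    Selects accessions detected by at least one peptide in every bait
    sample and by none in any control sample.  ``peptide_counts`` is an
    accession x sample_id table of nonnegative integers; samples absent
    from the table count as zero.
    """
    bait_ids = sample_columns(design, BAIT)
    control_ids = sample_columns(design, CONTROL)
    if not bait_ids:
        raise ValueError("design contains no bait samples")
    selected = set()
    for acc, row in peptide_counts.iterrows():
        in_all_bait = all(row.get(s, 0) >= 1 for s in bait_ids)
        in_no_control = all(row.get(s, 0) == 0 for s in control_ids)
        if in_all_bait and in_no_control:
            selected.add(str(acc))
    return selected


def filter_ledger(
    stages: Sequence[tuple[str, pd.DataFrame]],
    rhythm_significant: set[str] | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Survivor counts after each named filtering stage.

    For every stage the ledger reports the number of remaining protein
    groups, the subset with at least ``min_peptides`` unique peptides
    and (when rhythm calls are supplied) the subset called rhythmic.
    """
    if not stages:
        raise ValueError("at least one stage required")
    rows = []
    for name, table in stages:
        n = len(table)
        n_multi = (
            int((table["n_unique_peptides"] >= min_peptides).sum())
            if "n_unique_peptides" in table.columns and n
            else 0
        )
        n_rhy = (
            len(set(table.index) & rhythm_significant)
            if rhythm_significant is not None
            else pd.NA
        )
        rows.append((name, n, n_multi, n_rhy))
    return pd.DataFrame(
        rows, columns=["stage", "n_remaining", "n_min_peptides", "n_rhythmic"]
    )


def removal_audit(
    stages: Sequence[tuple[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Per-protein audit of which stage removed each group.

    The union of removed groups plus the final survivors equals the
    first stage's input, so no protein is lost silently.
    """
    rows = []
    for (prev_name, prev), (name, cur) in zip(stages, stages[1:]):
        removed = [k for k in prev.index if k not in set(cur.index)]
        for k in removed:
            rows.append((k, name, f"removed at stage {name!r}"))
    return pd.DataFrame(rows, columns=["accessions", "stage", "reason"])
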