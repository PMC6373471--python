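"""Reading and writing of study tables.

All on-disk formats are plain text in a canonical dialect: UTF-8,
tab-separated, one header row, ``.`` as the decimal separator and an
empty field (never ``0``) for a missing abundance.

In-memory containers are pandas objects with fixed schemas:

* **design** -- ``list[SampleRecord]``; each record is one MS run.
* **peptide table** -- DataFrame with columns ``sequence``,
  ``modifications``, ``charge``, ``score``, ``accessions``
  (";"-joined) followed by one abundance column per ``sample_id``.
* **protein table** -- DataFrame indexed by the ";"-joined accession
  group with columns ``gene_name``, ``n_unique_peptides`` followed by
  one abundance column per ``sample_id``.  The first accession of a
  group is the reporting anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "BAIT",
    "CONTROL",
    "LOCATION_TERMS",
    "PEPTIDE_META_COLUMNS",
    "PROTEIN_META_COLUMNS",
    "default_design",
    "read_design",
    "write_design",
    "read_peptide_table",
    "write_peptide_table",
    "read_protein_table",
    "write_protein_table",
    "read_exclusion_list",
    "write_exclusion_list",
    "read_annotation_table",
    "write_annotation_table",
    "infer_proteins",
    "normalize_totals",
    "sample_columns",
]

BAIT = "bait"
CONTROL = "control"
_GENOTYPES = (BAIT, CONTROL)

#: Controlled vocabulary of subcellular-location terms.
LOCATION_TERMS = frozenset({"plastid", "mitochondrion", "cytosol", "nucleus", "other"})

PEPTIDE_META_COLUMNS = ["sequence", "modifications", "charge", "score", "accessions"]
PROTEIN_META_COLUMNS = ["gene_name", "n_unique_peptides"]

#: Precursor charge states retained for quantitation.
ALLOWED_CHARGES = frozenset({2, 3, 4})

#: Default Mascot ion-score export cutoff.
DEFAULT_MIN_ION_SCORE = 20.0

#: Bait time points sampled in the reference design (Zeitgeber hours).
BAIT_TIMEPOINTS = (7.0, 11.0, 15.0, 19.0, 23.0, 27.0)
#: Wrap-around time point replicating the first one a day later.
WRAP_TIMEPOINT = 31.0
#: Control samples are singletons spread across the series.
CONTROL_TIMEPOINTS = (7.0, 11.0, 19.0, 23.0, 27.0)
REPLICATE_LABELS = ("A", "B", "C", "D", "E")


class StudyIOError(ValueError):
    """Raised for malformed or inconsistent study files."""


@dataclass(frozen=True)
class SampleRecord:
    """One mass-spectrometry run.

    Parameters
    ----------
    sample_id:
        Unique identifier within a design, e.g. ``"19E"``.
    genotype:
        ``"bait"`` for tagged-bait pulldowns, ``"control"`` for the
        untagged background pulldowns.
    zt:
        Zeitgeber time of harvest in hours since dawn.
    replicate:
        Replicate label (``A``-``E`` in the reference design).
    """

    sample_id: str
    genotype: str
    zt: float
    replicate: str

    def __post_init__(self) -> None:
        if self.genotype not in _GENOTYPES:
            raise StudyIOError(
                f"unknown genotype {self.genotype!r} for sample {self.sample_id!r};"
                f" expected one of {_GENOTYPES}"
            )
        if self.zt < 0:
            raise StudyIOError(f"negative Zeitgeber time for sample {self.sample_id!r}")


def default_design() -> list[SampleRecord]:
    """The reference bait/control time-course layout.

    Bait pulldowns in quintuplicate at ZT 7, 11, 15, 19, 23 and 27 h
    plus duplicate samples at the wrap-around point ZT 31 h (replicating
    ZT 7 of the next cycle); five singleton control pulldowns spread
    over the series, omitting ZT 15 and ZT 31.
    """
    records: list[SampleRecord] = []
    for zt in BAIT_TIMEPOINTS:
        for rep in REPLICATE_LABELS:
            records.append(SampleRecord(f"{int(zt)}{rep}", BAIT, zt, rep))
    for rep in REPLICATE_LABELS[:2]:
        records.append(SampleRecord(f"{int(WRAP_TIMEPOINT)}{rep}", BAIT, WRAP_TIMEPOINT, rep))
    for zt in CONTROL_TIMEPOINTS:
        records.append(SampleRecord(f"WT{int(zt)}", CONTROL, zt, "A"))
    return records


def sample_columns(design: Sequence[SampleRecord], genotype: str | None = None) -> list[str]:
    """Sample ids of a design, optionally restricted to one genotype."""
    return [s.sample_id for s in design if genotype is None or s.genotype == genotype]


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table with a header row."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_design(path: str | Path) -> list[SampleRecord]:
    """Read a sample-design table (columns sample_id, genotype, zt, replicate)."""
    df = _read_table(path)
    required = ["sample_id", "genotype", "zt", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyIOError(f"design {path}: missing column(s) {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            zt = float(row["zt"])
        except ValueError as exc:
            raise StudyIOError(f"design {path} line {line}: bad zt {row['zt']!r}") from exc
        sid = row["sample_id"].strip()
        if not sid:
            raise StudyIOError(f"design {path} line {line}: empty sample_id")
        if sid in seen:
            raise StudyIOError(f"design {path} line {line}: duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(SampleRecord(sid, row["genotype"].strip(), zt, row["replicate"].strip()))
    return records


def write_design(design: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "genotype": [s.genotype for s in design],
            "zt": [_fmt_num(s.zt) for s in design],
            "replicate": [s.replicate for s in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_abundances(df: pd.DataFrame, cols: Sequence[str], where: str) -> pd.DataFrame:
    out = {}
    for c in cols:
        vals = df[c].replace("", np.nan).astype(float)
        if (vals < 0).any():
            raise StudyIOError(f"{where}: negative abundance in column {c!r}")
        out[c] = vals
    return pd.DataFrame(out, index=df.index)


def read_peptide_table(
    path: str | Path,
    design: Sequence[SampleRecord],
    min_ion_score: float = DEFAULT_MIN_ION_SCORE,
) -> pd.DataFrame:
    """Read a peptide-level quantitation export.

    Rows with ion score below ``min_ion_score`` and precursor charges
    outside {2, 3, 4} are dropped, mirroring the export conventions of
    label-free quantitation software.
    """
    df = _read_table(path)
    missing_meta = [c for c in PEPTIDE_META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise StudyIOError(f"peptide table {path}: missing column(s) {missing_meta}")
    sample_ids = sample_columns(design)
    absent = [s for s in sample_ids if s not in df.columns]
    if absent:
        raise StudyIOError(
            f"peptide table {path}: no abundance column for designed sample(s) {absent}"
        )
    charge = df["charge"].astype(int)
    score = df["score"].astype(float)
    keep = charge.isin(sorted(ALLOWED_CHARGES)) & (score >= min_ion_score)
    df = df.loc[keep].reset_index(drop=True)
    meta = df[PEPTIDE_META_COLUMNS].copy()
    meta["charge"] = meta["charge"].astype(int)
    meta["score"] = meta["score"].astype(float)
    ab = _parse_abundances(df, sample_ids, f"peptide table {path}")
    return pd.concat([meta, ab], axis=1)


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_quant(table, PEPTIDE_META_COLUMNS, path, index=False)


def read_protein_table(path: str | Path, design: Sequence[SampleRecord]) -> pd.DataFrame:
    """Read a protein-level quantitation table (index: accession group)."""
    df = _read_table(path)
    required = ["accessions"] + PROTEIN_META_COLUMNS
    missing_meta = [c for c in required if c not in df.columns]
    if missing_meta:
        raise StudyIOError(f"protein table {path}: missing column(s) {missing_meta}")
    sample_ids = sample_columns(design)
    absent = [s for s in sample_ids if s not in df.columns]
    if absent:
        raise StudyIOError(
            f"protein table {path}: no abundance column for designed sample(s) {absent}"
        )
    out = df[PROTEIN_META_COLUMNS].copy()
    out["n_unique_peptides"] = out["n_unique_peptides"].astype(int)
    out = pd.concat([out, _parse_abundances(df, sample_ids, f"protein table {path}")], axis=1)
    out.index = pd.Index(df["accessions"], name="accessions")
    return out


def write_protein_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_quant(table, PROTEIN_META_COLUMNS, path, index=True)


def _fmt_num(x: float) -> str:
    if x != x:  # NaN -> empty field
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _write_quant(table: pd.DataFrame, meta: Sequence[str], path: str | Path, index: bool) -> None:
    df = table.copy()
    for c in df.columns:
        if c not in meta:
            df[c] = df[c].map(_fmt_num)
    df.to_csv(path, sep="\t", index=index)


def read_exclusion_list(path: str | Path, label: str | None = None) -> set[str]:
    """Read a one-accession-per-line exclusion list; ``#`` starts a comment."""
    accessions: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                accessions.add(entry.upper())
    return accessions


def write_exclusion_list(accessions: Iterable[str], path: str | Path, label: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if label:
            fh.write(f"# {label}\n")
        for acc in sorted({a.upper() for a in accessions}):
            fh.write(acc + "\n")


def read_annotation_table(path: str | Path, validate_locations: bool = True) -> dict[str, set[str]]:
    """Read accession -> comma-joined term annotations (e.g. locations)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise StudyIOError(f"annotation table {path}: expected two columns")
    acc_col, term_col = df.columns[:2]
    ann: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        terms = {t.strip() for t in row[term_col].split(",") if t.strip()}
        if validate_locations:
            bad = terms - LOCATION_TERMS
            if bad:
                raise StudyIOError(
                    f"annotation table {path}: unknown location term(s) {sorted(bad)}"
                )
        ann.setdefault(row[acc_col].strip().upper(), set()).update(terms)
    return ann


def write_annotation_table(
    ann: Mapping[str, Iterable[str]], path: str | Path, header: tuple[str, str] = ("accession", "terms")
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for acc in sorted(ann):
            fh.write(f"{acc}\t{','.join(sorted(ann[acc]))}\n")


# ---------------------------------------------------------------------------
# protein inference
# ---------------------------------------------------------------------------


def infer_proteins(peptides: pd.DataFrame, design: Sequence[SampleRecord]) -> pd.DataFrame:
    """Aggregate a peptide table to parsimonious protein groups.

    Accessions whose peptide sets are subsets of (or equal to) another
    accession's peptide set are merged into that accession's group, so
    shared peptides never inflate the protein list.  Group abundance is
    the per-sample sum of member-peptide abundances (missing treated as
    0 unless every member is missing, which stays missing);
    ``n_unique_peptides`` counts distinct peptide sequences mapping only
    within the group.  Each peptide contributes its abundance to exactly
    one group (that of its alphabetically first accession) so total
    signal is conserved.
    """
    sample_ids = sample_columns(design)
    if peptides.empty:
        empty = pd.DataFrame(columns=PROTEIN_META_COLUMNS + list(sample_ids))
        empty.index.name = "accessions"
        return empty

    pep_key = peptides["sequence"].astype(str) + "/" + peptides["modifications"].astype(str)
    acc_lists = [
        [a.strip().upper() for a in accs.split(";") if a.strip()]
        for accs in peptides["accessions"]
    ]
    acc_peps: dict[str, set[str]] = {}
    for key, accs in zip(pep_key, acc_lists):
        for acc in accs:
            acc_peps.setdefault(acc, set()).add(key)

    # Parsimony: merge accession B into A when peptides(B) <= peptides(A).
    # Equal sets form a single multi-accession group.  When several
    # strict supersets exist the largest (ties: alphabetical anchor)
    # absorbs the subset, deterministically.  Only accessions sharing a
    # peptide can be in a subset relation, so candidate supersets come
    # from the shared peptides' own accession lists.
    pep_accs: dict[str, set[str]] = {}
    for key, accs in zip(pep_key, acc_lists):
        pep_accs.setdefault(key, set()).update(accs)
    order = sorted(acc_peps, key=lambda a: (-len(acc_peps[a]), a))
    group_of: dict[str, str] = {}
    anchors: set[str] = set()
    for acc in order:
        peps = acc_peps[acc]
        candidates = set()
        for k in peps:
            candidates |= pep_accs[k]
        target = None
        for cand in sorted(candidates & anchors, key=lambda a: (-len(acc_peps[a]), a)):
            if cand != acc and peps <= acc_peps[cand]:
                target = cand
                break
        if target is None:
            anchors.add(acc)
            group_of[acc] = acc
        else:
            group_of[acc] = target

    members: dict[str, list[str]] = {a: [] for a in anchors}
    for acc in sorted(group_of):
        members[group_of[acc]].append(acc)
    # The anchor accession reports first; co-members follow alphabetically.
    group_key = {
        a: ";".join([a] + [m for m in members[a] if m != a]) for a in anchors
    }

    ab = peptides[sample_ids].to_numpy(dtype=float)
    anchors_sorted = sorted(anchors)
    anchor_pos = {a: i for i, a in enumerate(anchors_sorted)}
    n_groups = len(anchors_sorted)
    sums = np.zeros((n_groups, len(sample_ids)))
    any_present = np.zeros((n_groups, len(sample_ids)), dtype=bool)
    unique_keys: list[set[str]] = [set() for _ in range(n_groups)]
    for row, (key, accs) in enumerate(zip(pep_key, acc_lists)):
        if not accs:
            continue
        # abundance goes to exactly one group: that of the first accession
        g = anchor_pos[group_of[min(accs)]]
        present = ~np.isnan(ab[row])
        sums[g, present] += ab[row, present]
        any_present[g] |= present
        anchor = group_of[accs[0]]
        if all(group_of[a] == anchor for a in accs):
            unique_keys[anchor_pos[anchor]].add(key)
    values = np.where(any_present, sums, np.nan)

    out = pd.DataFrame(
        [["", len(unique_keys[anchor_pos[a]])] for a in anchors_sorted],
        columns=PROTEIN_META_COLUMNS,
        index=pd.Index([group_key[a] for a in anchors_sorted], name="accessions"),
    )
    out[sample_ids] = values
    out["n_unique_peptides"] = out["n_unique_peptides"].astype(int)
    out[sample_ids] = out[sample_ids].astype(float)
    return out


def normalize_totals(table: pd.DataFrame, design: Sequence[SampleRecord], mode: str = "raw") -> pd.DataFrame:
    """Per-sample total-intensity normalization.

    ``mode="raw"`` (the default) is the identity; ``mode="normalized"``
    rescales every sample so its column total equals the mean column
    total across samples.
    """
    if mode == "raw":
        return table.copy()
    if mode != "normalized":
        raise StudyIOError(f"unknown abundance mode {mode!r}")
    out = table.copy()
    sample_ids = [s for s in sample_columns(design) if s in table.columns]
    totals = {}
    for s in sample_ids:
        col = out[s].to_numpy(dtype=float)
        if np.all(np.isnan(col)):
            raise StudyIOError(f"cannot normalize: sample {s!r} has no quantified values")
        totals[s] = np.nansum(col)
    target = float(np.mean(list(totals.values())))
    for s in sample_ids:
        out[s] = out[s] * (target / totals[s])
    return out
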