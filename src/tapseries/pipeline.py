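"""End-to-end pipeline: read -> infer -> QC -> filters -> enrichment ->
rhythm -> summaries, with a single structured config and a
machine-readable run log.  Outputs are deterministic given config and
seed, and every table is written in the canonical tab-separated
dialect."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import enrichment as enr
from . import filters as flt
from . import io as sio
from . import qc as qcm
from . import report as rpt
from . import rhythm as rhy
from . import simulate as sim

__all__ = ["PipelineConfig", "SummaryTables", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with study defaults.

    File paths may be omitted, in which case the synthetic generator
    supplies the dataset (seeded by ``seed``).
    """

    design_path: str | None = None
    peptide_path: str | None = None
    protein_path: str | None = None
    exclusion_path: str | None = None
    annotation_path: str | None = None

    min_ion_score: float = sio.DEFAULT_MIN_ION_SCORE
    q_cut: float = 0.05
    weak_fold: float = 2.0
    high_fold: float = 4.0
    r_threshold: float = qcm.DEFAULT_R_THRESHOLD
    pc_sd_mult: float = qcm.DEFAULT_PC_SD_MULT
    periods: tuple[float, ...] = rhy.DEFAULT_PERIODS
    lag_step: float = rhy.DEFAULT_LAG_STEP
    min_peptides: int = 2
    abundance_mode: str = "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_ion_score", "q_cut", "weak_fold", "high_fold", "r_threshold",
                     "pc_sd_mult", "lag_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.abundance_mode not in ("raw", "normalized"):
            raise ValueError(f"unknown abundance mode {self.abundance_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "periods" in raw:
            raw["periods"] = tuple(float(p) for p in raw["periods"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["periods"] = list(self.periods)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SummaryTables:
    """Bundle of pipeline outputs."""

    candidates: pd.DataFrame
    ledger: pd.DataFrame
    phase_histogram: pd.Series
    heatmap_order: list[str]
    qc: pd.DataFrame
    rhythm: pd.DataFrame
    enrichment: pd.DataFrame
    log: dict


def _load_inputs(cfg: PipelineConfig):
    if cfg.design_path:
        design = sio.read_design(cfg.design_path)
    else:
        design = sio.default_design()
    truths = None
    if cfg.protein_path:
        table = sio.read_protein_table(cfg.protein_path, design)
    elif cfg.peptide_path:
        peptides = sio.read_peptide_table(cfg.peptide_path, design, cfg.min_ion_score)
        table = sio.infer_proteins(peptides, design)
    else:
        sim_cfg = sim.SimConfig(design=tuple(design), seed=cfg.seed)
        peptides, truths = sim.simulate_dataset(sim_cfg)
        table = sio.infer_proteins(peptides, design)
    excl = sio.read_exclusion_list(cfg.exclusion_path) if cfg.exclusion_path else set()
    ann = sio.read_annotation_table(cfg.annotation_path) if cfg.annotation_path else {}
    return design, table, excl, ann, truths


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> SummaryTables:
    """Execute the full analysis chain and optionally write outputs.

    Stage order: load -> abundance mode -> QC/outlier removal ->
    exclusion-list and compartment filters -> enrichment -> rhythm ->
    summaries.  Any stage error aborts with the stage name and cause.
    """
    log: dict = {"stages": [], "config": {**asdict(cfg), "periods": list(cfg.periods)}}

    def stage(name: str):
        log["stages"].append(name)
        return name

    try:
        name = stage("load")
        design, table, excl, ann, truths = _load_inputs(cfg)

        name = stage("abundance_mode")
        table = sio.normalize_totals(table, design, mode=cfg.abundance_mode)

        name = stage("qc")
        if len(table) >= 3 and len(sio.sample_columns(design, sio.BAIT)) >= 3:
            qc_report = qcm.qc_report(
                table, design, r_threshold=cfg.r_threshold, pc_sd_mult=cfg.pc_sd_mult
            )
            dropped = [s for s in qc_report.index[qc_report["flagged"]]]
        else:
            qc_report = pd.DataFrame(
                columns=["mean_r", "PC1", "PC2", "flagged", "reason"]
            )
            dropped = []
        design_kept = [s for s in design if s.sample_id not in set(dropped)]
        table = table[[c for c in table.columns if c not in set(dropped)]]
        log["qc_dropped_samples"] = dropped

        name = stage("filters")
        stages = [("quantified", table)]
        after_excl = flt.apply_exclusion_list(table, excl)
        stages.append(("without_tag_binders", after_excl))
        after_comp = flt.compartment_filter(after_excl, ann)
        stages.append(("without_organellar", after_comp))
        filtered = after_comp

        name = stage("enrichment")
        if len(filtered):
            enrichment = enr.enrich(
                filtered, design_kept, q_cut=cfg.q_cut,
                high_fold=cfg.high_fold, weak_fold=cfg.weak_fold,
            )
        else:
            enrichment = pd.DataFrame(
                columns=["max_zt", "bait_max_mean", "control_mean",
                         "fold_enrichment", "t_statistic", "p", "q", "tier"]
            )

        name = stage("rhythm")
        if len(filtered):
            rhythm = rhy.rhythm_analysis(
                filtered, design_kept, periods=cfg.periods, lag_step=cfg.lag_step
            )
        else:
            rhythm = pd.DataFrame(
                columns=["anova_F", "anova_p", "anova_q", "jtk_period", "jtk_lag",
                         "jtk_S", "jtk_tau", "jtk_p", "jtk_q", "peak_zt"]
            )

        name = stage("summaries")
        rhythm_sig = set(rhythm.index[(rhythm["jtk_q"] < cfg.q_cut).fillna(False)]) if len(rhythm) else set()
        ledger = flt.filter_ledger(stages, rhythm_sig, min_peptides=cfg.min_peptides)
        enriched_accs = enrichment.index[
            enrichment["tier"].isin([enr.TIER_HIGH, enr.TIER_WEAK])
        ].tolist() if len(enrichment) else []
        candidates = _candidate_table(filtered, enrichment, enriched_accs)
        if len(rhythm) and len(enrichment):
            hist = rpt.phase_histogram(rhythm, enrichment, design_kept, q_cut=cfg.q_cut)
        else:
            zts = sorted({s.zt for s in design_kept if s.genotype == sio.BAIT and s.zt != sio.WRAP_TIMEPOINT})
            hist = pd.Series(0, index=pd.Index(zts, name="zt"), dtype=int)
        order = (
            rpt.heatmap_order(filtered, design_kept, enriched_accs)
            if enriched_accs
            else []
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    log["n_candidates"] = len(candidates)
    log["ledger"] = ledger.to_dict(orient="records")
    result = SummaryTables(candidates, ledger, hist, order, qc_report, rhythm, enrichment, log)
    if outdir is not None:
        _write_outputs(result, filtered, truths, Path(outdir))
    return result


def _candidate_table(
    table: pd.DataFrame, enrichment: pd.DataFrame, enriched: Sequence[str]
) -> pd.DataFrame:
    cols = ["gene_name", "n_unique_peptides"]
    meta = table.loc[enriched, [c for c in cols if c in table.columns]] if len(enriched) else pd.DataFrame(columns=cols)
    out = pd.concat(
        [meta, enrichment.loc[enriched, ["p", "q", "fold_enrichment", "max_zt", "tier"]]],
        axis=1,
    ) if len(enriched) else pd.DataFrame(
        columns=cols + ["p", "q", "fold_enrichment", "max_zt", "tier"]
    )
    return out.sort_values("fold_enrichment", ascending=False) if len(out) else out


def _write_outputs(result: SummaryTables, table: pd.DataFrame, truths, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.candidates.to_csv(outdir / "candidates.tsv", sep="\t")
    result.ledger.to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    result.ledger.to_json(outdir / "ledger.json", orient="records", indent=2)
    result.phase_histogram.rename("count").to_csv(outdir / "phase_histogram.tsv", sep="\t")
    result.qc.to_csv(outdir / "qc_report.tsv", sep="\t")
    result.qc.reset_index().to_json(outdir / "qc_report.json", orient="records", indent=2)
    result.rhythm.to_csv(outdir / "rhythm.tsv", sep="\t")
    result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t")
    (outdir / "heatmap_order.txt").write_text("\n".join(result.heatmap_order) + "\n")
    sio.write_protein_table(table, outdir / "protein_table_filtered.tsv")
    if truths is not None:
        sim.write_truth_table(truths, outdir / "truth.tsv")
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True)
        fh.write("\n")
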