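"""Fold enrichment, Welch test, BH correction, tiers, FDR/power properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from tapseries import enrichment as enr
from tapseries import io as sio
from tapseries import simulate as sim

from conftest import make_protein_table


class TestFoldEnrichment:
    def test_equal_means_give_fold_one(self, design):
        row = {s.sample_id: 50.0 for s in design}
        table = make_protein_table(design, {"P1": row})
        fe = enr.fold_enrichment(table, design)
        assert fe.loc["P1", "fold_enrichment"] == pytest.approx(1.0)

    def test_wrap_time_point_excluded_from_argmax(self, design):
        row = {s.sample_id: (500.0 if s.zt == 31.0 else 10.0) for s in design}
        table = make_protein_table(design, {"P1": row})
        fe = enr.fold_enrichment(table, design)
        assert fe.loc["P1", "max_zt"] != 31.0

    def test_argmax_tie_breaks_to_earliest_zt(self, design):
        row = {s.sample_id: (90.0 if s.zt in (7.0, 27.0) else 10.0) for s in design}
        table = make_protein_table(design, {"P1": row})
        assert enr.fold_enrichment(table, design).loc["P1", "max_zt"] == 7.0

    def test_all_missing_controls_untestable(self, design):
        row = {s.sample_id: 50.0 for s in design if s.genotype == "bait"}
        table = make_protein_table(design, {"P1": row})
        res = enr.enrich(table, design)
        assert np.isnan(res.loc["P1", "fold_enrichment"])
        assert res.loc["P1", "tier"] == enr.TIER_UNTESTABLE

    def test_scale_equivariance(self, design):
        rng = np.random.default_rng(2)
        row = {s.sample_id: float(rng.uniform(10, 100)) for s in design}
        table = make_protein_table(design, {"P1": row})
        base = enr.fold_enrichment(table, design).loc["P1", "fold_enrichment"]
        # global rescale of the protein: fold unchanged
        all_scaled = table.copy()
        ids = sio.sample_columns(design)
        all_scaled[ids] = all_scaled[ids] * 3.0
        assert enr.fold_enrichment(all_scaled, design).loc["P1", "fold_enrichment"] == pytest.approx(base)
        # bait-only rescale: fold scales by the same factor
        bait_scaled = table.copy()
        bait_ids = sio.sample_columns(design, "bait")
        bait_scaled[bait_ids] = bait_scaled[bait_ids] * 3.0
        assert enr.fold_enrichment(bait_scaled, design).loc["P1", "fold_enrichment"] == pytest.approx(3.0 * base)


class TestWelchTest:
    def test_closed_form_example(self, tiny_design):
        """bait (1,2,3) vs control (4,5,6): Welch t = -3/sqrt(2/3) = -3.674,
        Welch-Satterthwaite df = 4, two-sided p = 0.021312 (closed form:
        2 * P(T_4 < -3.674), from the t distribution tail)."""
        table = make_protein_table(
            tiny_design,
            {"P1": {"BA": 1.0, "BB": 2.0, "BC": 3.0, "WA": 4.0, "WB": 5.0, "WC": 6.0}},
        )
        res = enr.enrichment_test(table, tiny_design)
        assert res.loc["P1", "t_statistic"] == pytest.approx(-3.6742346, rel=1e-6)
        assert res.loc["P1", "p"] == pytest.approx(0.0213116, rel=1e-4)

    def test_identical_groups(self, tiny_design):
        table = make_protein_table(
            tiny_design, {"P1": {k: 5.0 for k in ("BA", "BB", "BC", "WA", "WB", "WC")}}
        )
        res = enr.enrichment_test(table, tiny_design)
        assert res.loc["P1", "t_statistic"] == 0.0
        assert res.loc["P1", "p"] == 1.0

    def test_insufficient_replicates_untestable(self, tiny_design):
        table = make_protein_table(
            tiny_design, {"P1": {"BA": 5.0, "WA": 1.0, "WB": 2.0, "WC": 1.5}}
        )
        res = enr.enrichment_test(table, tiny_design)
        assert np.isnan(res.loc["P1", "p"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(enr.bh_adjust([0.03]), [0.03])

    def test_step_up_closed_form_triple(self):
        """(0.01, 0.02, 0.04) with m=3 -> (0.03, 0.03, 0.04)."""
        np.testing.assert_allclose(
            enr.bh_adjust([0.01, 0.02, 0.04], m=3), [0.03, 0.03, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(enr.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_statsmodels_when_m_is_count(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(enr.bh_adjust(p), expected, rtol=1e-12)

    def test_nan_passthrough_and_explicit_m(self):
        q = enr.bh_adjust([0.01, np.nan, 0.04], m=10)
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.1, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enr.bh_adjust([1.2])
        with pytest.raises(ValueError):
            enr.bh_adjust([0.1, 0.2], m=1)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        assert np.all(enr.bh_adjust(p) >= p - 1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_step_up_invariants(self, p):
        """For any p-vector: q in [p, 1], order-preserving, and matches
        the independent statsmodels implementation."""
        q = enr.bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], rtol=1e-9, atol=1e-12)


class TestAssignTier:
    @pytest.mark.parametrize(
        "q,fold,tier",
        [
            (0.01, 10.0, enr.TIER_HIGH),
            (0.01, 4.0, enr.TIER_HIGH),
            (0.01, 3.0, enr.TIER_WEAK),
            (0.01, 1.5, enr.TIER_NONE),
            (0.5, 10.0, enr.TIER_NONE),
            (np.nan, 10.0, enr.TIER_UNTESTABLE),
        ],
    )
    def test_tier_rules(self, q, fold, tier):
        assert enr.assign_tier(q, fold) == tier


class TestStatisticalProperties:
    def test_global_null_fdr_control(self):
        """Background-only simulation: the fraction of proteins reaching
        q < 0.05 stays within the nominal level plus Monte-Carlo error."""
        fracs = []
        for seed in (0, 1, 2):
            cfg = sim.SimConfig(n_per_class=(0, 0, 1000), seed=seed)
            peptides, _ = sim.simulate_dataset(cfg)
            table = sio.infer_proteins(peptides, list(cfg.design))
            res = enr.enrich(table, list(cfg.design))
            q = res["q"].dropna()
            fracs.append(float((q < 0.05).mean()))
        mean = float(np.mean(fracs))
        mc_se = float(np.std(fracs, ddof=1) / np.sqrt(len(fracs))) if len(fracs) > 1 else 0.0
        assert mean <= 0.05 + 2 * mc_se + 1e-12

    def test_planted_interactor_power(self):
        """Planted interactors (phi >= 4, sigma <= 0.3) are detected
        (q < 0.05, tier != none) in >= 90% of cases over seeded runs."""
        detected = total = 0
        for seed in range(10):
            cfg = sim.SimConfig(seed=seed)
            peptides, truths = sim.simulate_dataset(cfg)
            table = sio.infer_proteins(peptides, list(cfg.design))
            res = enr.enrich(table, list(cfg.design))
            for t in truths:
                if t.cls == sim.BACKGROUND:
                    continue
                total += 1
                row = res.loc[t.accession]
                if row["tier"] in (enr.TIER_HIGH, enr.TIER_WEAK):
                    detected += 1
        assert detected / total >= 0.90

    def test_raw_and_normalized_modes_tier_agreement(self, sim_default):
        """Total-signal normalization changes folds slightly but tier calls
        on the default thresholds agree almost everywhere."""
        cfg, _, _, table = sim_default
        design = list(cfg.design)
        raw = enr.enrich(table, design)["tier"]
        norm_table = sio.normalize_totals(table, design, mode="normalized")
        norm = enr.enrich(norm_table, design)["tier"]
        assert (raw == norm).mean() >= 0.95
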