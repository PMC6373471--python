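"""Rhythm detection: Kendall S, exact null DP vs enumeration, the
reference scan, arcsinh ANOVA and peak times."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tapseries import io as sio
from tapseries import rhythm as rhy
from tapseries import simulate as sim

from conftest import make_protein_table


def brute_force_null(ref):
    """Exact pmf of S by enumerating every ordering of distinct data."""
    n = len(ref)
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(n)):
        s, _ = rhy.kendall_s(np.array(perm, dtype=float), ref)
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}


class TestKendallS:
    def test_perfect_concordance(self):
        s, tau = rhy.kendall_s([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert (s, tau) == (6, 1.0)

    def test_single_swap_pair_enumeration(self):
        """data (1,3,2,4) vs reference (1,2,3,4): 5 concordant pairs,
        1 discordant -> S = 4, tau = 4/6."""
        s, tau = rhy.kendall_s([1.0, 3.0, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert s == 4
        assert tau == pytest.approx(4 / 6)

    def test_reference_tie_contributes_zero(self):
        """reference (1,1,2), data (5,3,9): the tied reference pair drops,
        the two remaining pairs are concordant -> S = 2."""
        s, tau = rhy.kendall_s([5.0, 3.0, 9.0], [1.0, 1.0, 2.0])
        assert s == 2
        assert tau == pytest.approx(1.0)

    def test_missing_values_dropped_pairwise(self):
        s, _ = rhy.kendall_s([1.0, np.nan, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        assert s == 3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            rhy.kendall_s([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=10),
        st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=10),
    )
    def test_antisymmetry_and_bounds(self, data, ref):
        """Reversing the data order flips S; |S| never exceeds the number
        of doubly untied pairs and |tau| <= 1."""
        n = min(len(data), len(ref))
        x = np.array(data[:n], dtype=float)
        r = np.array(ref[:n], dtype=float)
        s, tau = rhy.kendall_s(x, r)
        s_neg, tau_neg = rhy.kendall_s(-x, r)
        assert s_neg == -s
        assert tau_neg == pytest.approx(-tau)
        assert -1.0 <= tau <= 1.0


class TestExactNull:
    def test_three_distinct_values(self):
        """n=3, no ties: P(S=+-3) = 1/6, P(S=+-1) = 2/6 (all 3! orderings)."""
        s_vals, pmf = rhy.jtk_exact_null([1, 1, 1])
        dist = dict(zip(s_vals.tolist(), pmf.tolist()))
        assert dist[3] == pytest.approx(1 / 6)
        assert dist[-3] == pytest.approx(1 / 6)
        assert dist[1] == pytest.approx(2 / 6)
        assert dist[-1] == pytest.approx(2 / 6)

    @pytest.mark.parametrize("sizes", [(1, 1, 1, 1), (2, 2), (3, 1, 2), (5, 2)])
    def test_symmetry_and_total_mass(self, sizes):
        s_vals, pmf = rhy.jtk_exact_null(sizes)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)

    def test_dp_equals_enumeration_random_tie_patterns(self):
        """DP null equals brute-force enumeration for all series lengths
        <= 8 over 50 random tie patterns."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            ref = np.sort(rng.integers(0, 4, size=n)).astype(float)
            sizes = np.unique(ref, return_counts=True)[1]
            s_vals, pmf = rhy.jtk_exact_null(tuple(int(c) for c in sizes))
            bf = brute_force_null(ref)
            dp = {int(s): p for s, p in zip(s_vals, pmf) if p > 0}
            assert set(dp) == set(bf)
            for s in bf:
                assert dp[s] == pytest.approx(bf[s], abs=1e-12)


class TestArcsinhAnova:
    def test_identical_constants(self, design):
        table = make_protein_table(design, {"P1": {s.sample_id: 7.0 for s in design}})
        res = rhy.arcsinh_anova(table, design)
        assert res.loc["P1", "anova_F"] == 0.0
        assert res.loc["P1", "anova_p"] == 1.0

    def test_two_groups_equals_squared_t(self):
        """With exactly two groups, F equals the square of the
        pooled-variance t statistic."""
        recs = [sio.SampleRecord(f"7{r}", "bait", 7.0, r) for r in "ABC"]
        recs += [sio.SampleRecord(f"19{r}", "bait", 19.0, r) for r in "ABC"]
        vals = {"7A": 1.0, "7B": 2.0, "7C": 4.0, "19A": 5.0, "19B": 9.0, "19C": 6.0}
        table = make_protein_table(recs, {"P1": vals})
        res = rhy.arcsinh_anova(table, recs)
        a = np.arcsinh([1.0, 2.0, 4.0])
        b = np.arcsinh([5.0, 9.0, 6.0])
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.loc["P1", "anova_F"] == pytest.approx(t**2, rel=1e-9)
        assert res.loc["P1", "anova_p"] == pytest.approx(p, rel=1e-9)

    def test_degenerate_grouping_undefined(self, tiny_design):
        table = make_protein_table(tiny_design, {"P1": {"BA": 1.0, "BB": 2.0, "BC": 3.0}})
        res = rhy.arcsinh_anova(table, tiny_design)
        assert np.isnan(res.loc["P1", "anova_p"])


class TestJtkScan:
    def test_constant_series_never_significant(self, design):
        table = make_protein_table(design, {"P1": {s.sample_id: 3.0 for s in design}})
        res = rhy.jtk_scan(table, design)
        assert res.loc["P1", "jtk_p"] >= 0.5

    def test_noiseless_cosine_roundtrip(self, design):
        """A clean 24-h cosine peaking at ZT 7 sampled on the study design
        is recovered: period 24 (mean of tied optimal references), lag
        within one grid step of 7, perfect concordance."""
        row = {
            s.sample_id: (
                1000.0 * (1 + 0.8 * np.cos(2 * np.pi * (s.zt - 7) / 24))
                if s.genotype == "bait"
                else 1000.0
            )
            for s in design
        }
        table = make_protein_table(design, {"P1": row})
        res = rhy.jtk_scan(table, design)
        assert res.loc["P1", "jtk_period"] == pytest.approx(24.0)
        assert abs(res.loc["P1", "jtk_lag"] - 7.0) <= rhy.DEFAULT_LAG_STEP
        assert res.loc["P1", "jtk_tau"] == pytest.approx(1.0)
        assert res.loc["P1", "jtk_q"] < 1e-6

    def test_requires_four_distinct_time_points(self, tiny_design):
        table = make_protein_table(tiny_design, {"P1": {"BA": 1.0}})
        with pytest.raises(ValueError, match="4 distinct"):
            rhy.jtk_scan(table, tiny_design)

    def test_planted_mixture_fdr_and_power(self):
        """On default planted-truth mixtures the rhythm stage keeps the
        realized false-discovery proportion at q<0.05 below 0.1 while
        detecting the planted rhythmic interactors."""
        true_hits = false_hits = n_rhythmic = 0
        for seed in range(5):
            cfg = sim.SimConfig(seed=seed)
            peptides, truths = sim.simulate_dataset(cfg)
            table = sio.infer_proteins(peptides, list(cfg.design))
            res = rhy.jtk_scan(table, list(cfg.design))
            rhythmic = {t.accession for t in truths if t.cls == sim.RHYTHMIC}
            n_rhythmic += len(rhythmic)
            hits = set(res.index[(res["jtk_q"] < 0.05).fillna(False)])
            true_hits += len(hits & rhythmic)
            false_hits += len(hits - rhythmic)
        assert false_hits / max(true_hits + false_hits, 1) <= 0.1
        assert true_hits / n_rhythmic >= 0.9

    def test_phase_recovery_within_sampling_interval(self):
        """Planted peak phases (amplitude >= 0.5, sigma <= 0.2) are
        recovered by the rhythm stage within +-4 h in >= 90% of cases."""
        ok = tot = 0
        for seed in range(5):
            cfg = sim.SimConfig(n_per_class=(10, 0, 0), sigma=0.2, seed=seed)
            peptides, truths = sim.simulate_dataset(cfg)
            table = sio.infer_proteins(peptides, list(cfg.design))
            peaks = rhy.peak_time(table, list(cfg.design))
            for t in truths:
                tot += 1
                d = abs((peaks.loc[t.accession] - t.peak_phase + 12) % 24 - 12)
                ok += d <= 4.0
        assert ok / tot >= 0.9


class TestPeakTime:
    def test_monotone_series_peaks_last(self, design):
        row = {s.sample_id: s.zt * 10.0 if s.genotype == "bait" else 1.0 for s in design}
        row.update({s.sample_id: 1.0 for s in design if s.zt == 31.0})
        table = make_protein_table(design, {"P1": row})
        assert rhy.peak_time(table, design).loc["P1"] == 27.0

    def test_wrap_samples_pool_with_first_time_point(self, design):
        """High values only at ZT 31 fold onto ZT 7 (wrap-around)."""
        row = {s.sample_id: (900.0 if s.zt == 31.0 else 10.0) for s in design if s.genotype == "bait"}
        table = make_protein_table(design, {"P1": row})
        assert rhy.peak_time(table, design).loc["P1"] == 7.0

    def test_tie_breaks_to_earliest(self, design):
        row = {s.sample_id: (50.0 if s.zt in (11.0, 27.0) else 10.0) for s in design if s.genotype == "bait"}
        table = make_protein_table(design, {"P1": row})
        assert rhy.peak_time(table, design).loc["P1"] == 11.0
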