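"""Observed-vs-expected co-occurrence, CMH statistic, Bonferroni."""

import numpy as np
import pytest
import statsmodels.api as sm

from burstlink.cooccurrence import (
    ContingencyStratum,
    bonferroni,
    build_strata,
    cmh_test,
    cooccurrence_analysis,
    expected_cooccurrence,
)
from burstlink.burst import burst_summary
from burstlink.params import Condition, KineticsParams, NoiseParams, SimulationConfig
from burstlink.simulate import joint_burst_probability, simulate_dataset
from burstlink.studies import allele_cooccurrence_run
from burstlink.scenarios import power_coupling_config


class TestExpected:
    def test_product_rule(self):
        assert expected_cooccurrence(0.2, 0.1) == pytest.approx(0.02)
        assert expected_cooccurrence(0.0, 0.7) == 0.0
        assert expected_cooccurrence(1.0, 1.0) == 1.0

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            expected_cooccurrence(1.2, 0.5)


class TestBuildStrata:
    def test_direct_construction(self):
        s = build_strata({"r1": 20}, {"r1": 0.04}, {"r1": 100})
        assert s == [ContingencyStratum("r1", 20, 80, 4, 96)]

    def test_zero_observed_zero_expected(self):
        s = build_strata({"r1": 0}, {"r1": 0.0}, {"r1": 50})
        assert s == [ContingencyStratum("r1", 0, 50, 0, 50)]

    def test_replicate_order_preserved(self):
        s = build_strata({"a": 1, "b": 2}, {"a": 0.1, "b": 0.1}, {"a": 10, "b": 20})
        assert [x.replicate_id for x in s] == ["a", "b"]

    def test_empty_replicate_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no units"):
            s = build_strata({"a": 0, "b": 3}, {"a": 0.1, "b": 0.1}, {"a": 0, "b": 30})
        assert len(s) == 1


class TestCmh:
    def test_two_identical_strata_hand_value(self):
        """Hand evaluation: E = 15, V = 810000/212400 per stratum, so
        T = (2*5)^2 / (2*3.813...) = 13.1148."""
        s = [ContingencyStratum(r, 20, 10, 10, 20) for r in (1, 2)]
        stat, p = cmh_test(s)
        assert stat == pytest.approx(13.1148, abs=0.01)
        assert p == pytest.approx(2.93e-4, rel=0.05)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(0)
        tables = []
        strata = []
        for r in range(4):
            t = rng.integers(5, 60, size=(2, 2))
            tables.append(t)
            strata.append(ContingencyStratum(r, t[0, 0], t[0, 1], t[1, 0], t[1, 1]))
        ours = cmh_test(strata)
        ref = sm.stats.StratifiedTable(
            [np.asarray(t) for t in tables]
        ).test_null_odds(correction=False)
        assert ours[0] == pytest.approx(float(ref.statistic), rel=1e-10)
        assert ours[1] == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_symmetric_strata_give_zero(self):
        s = [ContingencyStratum(r, 7, 7, 7, 7) for r in range(3)]
        stat, p = cmh_test(s)
        assert stat == 0.0
        assert p == 1.0

    def test_single_stratum_reduces_to_one_table_statistic(self):
        s = [ContingencyStratum(0, 20, 10, 10, 20)]
        stat, _ = cmh_test(s)
        ref = sm.stats.StratifiedTable([np.array([[20, 10], [10, 20]])]).test_null_odds(
            correction=False
        )
        assert stat == pytest.approx(float(ref.statistic), rel=1e-10)

    def test_all_degenerate_strata_undefined(self):
        s = [ContingencyStratum(0, 0, 0, 0, 5)]
        stat, p = cmh_test(s)
        assert np.isnan(stat) and np.isnan(p)

    def test_continuity_correction_shrinks_statistic(self):
        s = [ContingencyStratum(0, 20, 10, 10, 20)]
        assert cmh_test(s, correction=True)[0] < cmh_test(s)[0]


class TestBonferroni:
    def test_scaling_and_capping(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5], m=4), [1.0])
        np.testing.assert_allclose(bonferroni([0.0], m=100), [0.0])

    def test_m_defaults_to_count_and_must_cover(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestAlleleLevelAnalysis:
    def test_coupled_ratio_matches_plackett_oracle(self):
        cfg = power_coupling_config(seed=0, n_cells_per_replicate=4000, n_replicates=3)
        out = allele_cooccurrence_run(cfg, seed=17)
        k = cfg.conditions[0].kinetics
        target = joint_burst_probability(k.p_e, k.p_g, k.psi) / (k.p_e * k.p_g)
        # extrinsic noise adds a little cell-level correlation on top
        assert out["ratio"] > 1.5
        assert out["ratio"] == pytest.approx(target, rel=0.15)
        assert out["p"] < 1e-6

    def test_null_ratio_near_one(self):
        from burstlink.scenarios import null_coupling_config

        cfg = null_coupling_config(seed=0, n_cells_per_replicate=5000, n_replicates=3)
        out = allele_cooccurrence_run(cfg, seed=23)
        assert out["ratio"] == pytest.approx(1.0, abs=0.1)

    def test_extrinsic_noise_inflates_cell_level_only_conditionally(self):
        """psi=1 with strong extrinsic noise: cell-level ratio > 1 (global
        activity couples loci across the cell) even though allele-level
        coupling conditional on that activity is absent."""
        cfg = SimulationConfig(
            conditions=(Condition("c", KineticsParams(p_e=0.2, p_g=0.2, psi=1.0)),),
            n_cells_per_replicate=8000,
            n_replicates=2,
            noise=NoiseParams(extrinsic_sigma=0.6),
            seed=31,
        )
        ds = simulate_dataset(cfg)
        q = burst_summary(ds, tau=2.0, ploidy=2)
        cell = cooccurrence_analysis(q.tss, ds.cells, "enh", "intron", level="cell")
        assert cell.ratio > 1.15
        assert cell.p_value < 0.01

    def test_biallelic_excess_under_extrinsic_noise(self):
        cfg = SimulationConfig(
            conditions=(Condition("c", KineticsParams(p_e=0.2, p_g=0.2, psi=1.0)),),
            n_cells_per_replicate=8000,
            n_replicates=2,
            noise=NoiseParams(extrinsic_sigma=0.6),
            seed=37,
        )
        ds = simulate_dataset(cfg)
        q = burst_summary(ds, tau=2.0, ploidy=2)
        res = cooccurrence_analysis(q.tss, ds.cells, "intron", "intron", level="cell")
        assert res.ratio > 1.2  # more two-burst cells than p_allele^2 predicts

    def test_stratified_vs_pooled_agree_under_identical_replicates(self):
        from burstlink.scenarios import null_coupling_config

        cfg = null_coupling_config(seed=0, n_cells_per_replicate=4000, n_replicates=3)
        ds = simulate_dataset(cfg, seed=41)
        q = burst_summary(ds, tau=2.0, ploidy=2)
        strat = cooccurrence_analysis(q.tss, ds.cells, "enh", "intron", level="allele")
        pooled_cells = ds.cells.assign(replicate_id=1)
        pooled = cooccurrence_analysis(q.tss, pooled_cells, "enh", "intron", level="allele")
        assert strat.ratio == pytest.approx(pooled.ratio, rel=0.02)
        assert strat.cmh_statistic == pytest.approx(pooled.cmh_statistic, abs=1.5)
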