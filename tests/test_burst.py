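"""TSS calling, single-molecule reference, and burst parameters."""

import numpy as np
import pandas as pd
import pytest

from burstlink.burst import (
    burst_fraction,
    burst_summary,
    call_tss,
    decompose_expression,
    mature_counts,
    single_molecule_reference,
)
from burstlink.errors import ReferenceError_
from burstlink.params import Condition, KineticsParams, NoiseParams, SimulationConfig
from burstlink.simulate import simulate_dataset


def spots_table(intensities, compartment="cytoplasmic", probe="p", cell=1):
    n = len(intensities)
    return pd.DataFrame(
        {
            "spot_id": np.arange(n),
            "cell_id": cell,
            "probe_id": probe,
            "channel": "ch",
            "x": 0.0,
            "y": 0.0,
            "z": 0.0,
            "intensity": np.asarray(intensities, dtype=float),
            "compartment": compartment,
        }
    )


class TestSingleMoleculeReference:
    def test_constant_input_returns_that_intensity(self):
        assert single_molecule_reference(spots_table([100.0] * 100)) == 100.0

    def test_robust_to_bright_outlier(self):
        vals = [100.0] * 50 + [1000.0]
        assert single_molecule_reference(spots_table(vals)) == 100.0

    def test_recovers_simulator_ground_truth(self, ideal_dataset):
        cfg, ds = ideal_dataset
        i1_true = cfg.single_molecule_intensity
        sub = ds.spots[ds.spots["probe_id"] == "exon"]
        assert single_molecule_reference(sub) == pytest.approx(i1_true, abs=0.05 * i1_true)

    def test_too_few_spots_raises_with_pooling_hint(self):
        with pytest.raises(ReferenceError_, match="pool"):
            single_molecule_reference(spots_table([100.0] * 5))

    def test_falls_back_to_nuclear_spots(self):
        nuc = spots_table([100.0] * 30, compartment="nuclear")
        assert single_molecule_reference(nuc) == 100.0


class TestCallTss:
    def test_burst_intensity_is_ratio_to_reference(self):
        spots = spots_table([500.0], compartment="nuclear")
        tss = call_tss(spots, i1=100.0, tau=2.0)
        assert len(tss) == 1
        assert tss["burst_intensity"].iloc[0] == pytest.approx(5.0)

    def test_sub_threshold_spot_not_called(self):
        spots = spots_table([150.0], compartment="nuclear")
        assert len(call_tss(spots, i1=100.0, tau=2.0)) == 0

    def test_ploidy_caps_calls_keeping_brightest(self):
        spots = spots_table([900.0, 500.0, 700.0], compartment="nuclear")
        tss = call_tss(spots, i1=100.0, tau=2.0, ploidy=2)
        assert len(tss) == 2
        assert sorted(tss["burst_intensity"]) == pytest.approx([7.0, 9.0])

    def test_cytoplasmic_spots_never_called(self):
        spots = spots_table([900.0], compartment="cytoplasmic")
        assert len(call_tss(spots, i1=100.0, tau=2.0)) == 0

    def test_calling_invariant_to_global_intensity_rescale(self, small_dataset):
        _, ds = small_dataset
        sub = ds.spots[ds.spots["probe_id"] == "intron"]
        i1 = single_molecule_reference(sub)
        tss1 = call_tss(sub, i1, tau=2.0)
        scaled = sub.assign(intensity=sub["intensity"] * 7.5)
        tss2 = call_tss(scaled, i1 * 7.5, tau=2.0)
        assert list(tss1["tss_id"]) == list(tss2["tss_id"])
        np.testing.assert_allclose(tss1["burst_intensity"], tss2["burst_intensity"])


class TestBurstFraction:
    def test_zero_and_full_occupancy(self, tiny_tables):
        cells, _ = tiny_tables
        empty = pd.DataFrame(columns=["tss_id", "cell_id", "probe_id", "burst_intensity"])
        assert burst_fraction(empty, cells).empty
        rows = [
            {"tss_id": i, "cell_id": c, "probe_id": "p", "burst_intensity": 3.0}
            for i, c in enumerate([1, 1, 2, 2, 3, 3])
        ]
        bf = burst_fraction(pd.DataFrame(rows), cells, ploidy=2)
        assert (bf["burst_fraction"] == 1.0).all()

    def test_recovers_ground_truth_activity_probability(self, ideal_dataset):
        """Burst fraction tracks p_g with a small, bounded negative bias from
        single-nascent alleles falling below the tau threshold."""
        cfg, ds = ideal_dataset
        p_g = cfg.conditions[0].kinetics.p_g
        res = burst_summary(ds, tau=2.0, ploidy=2)
        bf = res.summary.query("probe_id == 'intron'")["burst_fraction"]
        est = np.average(bf, weights=res.summary.query("probe_id == 'intron'")["n_cells"])
        assert est == pytest.approx(p_g, abs=0.02)
        # against the *realized* allele activity, calling can only lose
        # bursts, and at lambda_nascent=6 the near-threshold tail is < 0.01
        realized = ds.truth["gene_state"].mean()
        assert est <= realized + 1e-9
        assert realized - est < 0.01

    def test_per_cell_denominator_counts_cells_once(self, small_dataset):
        _, ds = small_dataset
        res_allele = burst_summary(ds, tau=2.0, ploidy=2)
        res_cell = burst_summary(ds, tau=2.0, ploidy=2, per_cell=True)
        a = res_allele.summary.set_index(["condition", "replicate_id", "probe_id"])
        c = res_cell.summary.set_index(["condition", "replicate_id", "probe_id"])
        assert (c["burst_fraction"] >= a["burst_fraction"] - 1e-12).all()
        assert (c["burst_fraction"] <= 2 * a["burst_fraction"] + 1e-12).all()


class TestDecomposeExpression:
    def test_worked_example(self):
        frac, mean = decompose_expression([0, 0, 6, 10], threshold=5)
        assert frac == 0.5
        assert mean == 8.0

    def test_all_zero_counts(self):
        frac, mean = decompose_expression([0, 0, 0], threshold=5)
        assert frac == 0.0
        assert np.isnan(mean)

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            decompose_expression([1, 2], threshold=0)


def test_halving_burst_probability_halves_who_expresses_not_how_much():
    """In the rare-large-burst regime, halving burst frequency halves the
    fraction of expressing cells while the expression level *among*
    expressing cells (mostly single-burst cells) barely moves; burst
    intensity is likewise untouched."""
    cfg = SimulationConfig(
        conditions=(
            Condition("WT", KineticsParams(p_g=0.3, f=0.1, b=15.0)),
            Condition("KO", KineticsParams(p_g=0.15, f=0.05, b=15.0)),
        ),
        n_cells_per_replicate=8000,
        n_replicates=1,
        noise=NoiseParams(extrinsic_sigma=0.0),
        seed=21,
    )
    ds = simulate_dataset(cfg)
    res = burst_summary(ds, tau=2.0, ploidy=2, count_probe="exon", expression_threshold=5)
    s = res.summary[res.summary["probe_id"] == "intron"].set_index("condition")
    assert s.loc["KO", "burst_fraction"] / s.loc["WT", "burst_fraction"] == pytest.approx(
        0.5, abs=0.05
    )
    assert s.loc["KO", "mean_burst_intensity"] / s.loc["WT", "mean_burst_intensity"] == (
        pytest.approx(1.0, abs=0.05)
    )
    assert s.loc["KO", "fraction_expressing"] / s.loc["WT", "fraction_expressing"] == (
        pytest.approx(0.5, abs=0.07)
    )
    # shared burst size: what an expressing cell makes is unchanged
    assert s.loc["KO", "mean_count_expressing"] == pytest.approx(
        s.loc["WT", "mean_count_expressing"], rel=0.10
    )


def test_burst_fraction_sensitivity_over_brightness_factor(ideal_dataset):
    """Raising tau can only lose dim true bursts: the estimate decreases
    monotonically in tau and stays within ~10% of truth over tau in
    [1.5, 3] at lambda_nascent=6."""
    cfg, ds = ideal_dataset
    p_g = cfg.conditions[0].kinetics.p_g
    n_alleles = 2 * len(ds.cells)
    sub = ds.spots[ds.spots["probe_id"] == "intron"]
    i1 = single_molecule_reference(sub)
    ests = []
    for tau in (1.5, 2.0, 2.5, 3.0):
        est = len(call_tss(sub, i1, tau=tau, ploidy=2)) / n_alleles
        ests.append(est)
        assert 0.88 * p_g < est < 1.05 * p_g, tau
    assert all(a >= b for a, b in zip(ests, ests[1:]))


def test_mean_burst_intensity_tracks_nascent_load(ideal_dataset):
    cfg, ds = ideal_dataset
    lam = cfg.conditions[0].kinetics.lambda_nascent
    res = burst_summary(ds, tau=2.0, ploidy=2)
    bi = res.summary.query("probe_id == 'intron'")["mean_burst_intensity"].mean()
    # conditional on calling, mean nascent count is ~1 + lambda
    assert bi == pytest.approx(1 + lam, rel=0.08)


def test_mature_counts_match_truth(ideal_dataset):
    _, ds = ideal_dataset
    counts = mature_counts(ds, "exon")
    truth_tot = ds.truth.groupby("cell_id")["mature_count"].sum()
    np.testing.assert_array_equal(
        counts.to_numpy(), truth_tot.reindex(counts.index, fill_value=0).to_numpy()
    )
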