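"""Distributional properties of the synthetic-data generator."""

import numpy as np
import pytest
from scipy import stats

from burstlink.errors import ConfigError
from burstlink.io import write_dataset
from burstlink.params import (
    Condition,
    GeometryParams,
    KineticsParams,
    NoiseParams,
    SimulationConfig,
)
from burstlink.simulate import joint_burst_probability, simulate_dataset


def _config(n=2000, reps=1, noise=NoiseParams(extrinsic_sigma=0.0), **kin):
    return SimulationConfig(
        conditions=(Condition("c", KineticsParams(**kin)),),
        n_cells_per_replicate=n,
        n_replicates=reps,
        noise=noise,
        seed=123,
    )


def test_all_off_state_produces_no_tss_spots():
    ds = simulate_dataset(_config(n=300, p_e=0.0, p_g=0.0, false_tss_rate=0.0))
    nuc = ds.spots[ds.spots["compartment"] == "nuclear"]
    assert len(nuc) == 0
    # cytoplasmic mature spots still present (Gamma-Poisson counts)
    cyto = ds.spots[
        (ds.spots["compartment"] == "cytoplasmic") & (ds.spots["probe_id"] == "exon")
    ]
    assert len(cyto) > 0
    assert ds.truth["mature_count"].sum() == len(cyto)


def test_fixed_seed_reproduces_files_byte_identically(tmp_path):
    cfg = _config(n=150, p_e=0.2, p_g=0.3)
    p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
    p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
    assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
    assert p1["spots"].read_bytes() == p2["spots"].read_bytes()


def test_gene_marginal_matches_binomial_oracle():
    p_g = 0.3
    cfg = _config(n=10_000, p_g=p_g, p_e=0.1)
    tr = simulate_dataset(cfg).truth
    n_alleles = len(tr)
    se = np.sqrt(p_g * (1 - p_g) / n_alleles)
    assert tr["gene_state"].mean() == pytest.approx(p_g, abs=3 * se)


@pytest.mark.parametrize("psi", [1.0, 4.0, 8.0])
def test_joint_state_frequencies_match_target_table(psi):
    """chi-square goodness of fit of (E,G) against the Plackett solution."""
    p_e, p_g = 0.25, 0.2
    cfg = _config(n=50_000, p_e=p_e, p_g=p_g, psi=psi)
    tr = simulate_dataset(cfg).truth
    e = tr["enhancer_state"].to_numpy()
    g = tr["gene_state"].to_numpy()
    n = len(tr)
    obs = np.array(
        [((e == 1) & (g == 1)).sum(), ((e == 1) & (g == 0)).sum(),
         ((e == 0) & (g == 1)).sum(), ((e == 0) & (g == 0)).sum()]
    )
    p11 = joint_burst_probability(p_e, p_g, psi)
    exp = n * np.array([p11, p_e - p11, p_g - p11, 1 - p_e - p_g + p11])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    assert stats.chi2.sf(chi2, df=3) > 0.01


def test_mature_counts_follow_gamma_poisson_moments():
    f, b = 2.0, 5.0
    cfg = _config(n=40_000, f=f, b=b)
    m = simulate_dataset(cfg).truth["mature_count"].to_numpy()
    mean, var = m.mean(), m.var(ddof=1)
    assert mean == pytest.approx(f * b, rel=0.03)
    assert var == pytest.approx(f * b * (1 + b), rel=0.06)


def test_extrinsic_noise_couples_cells_but_not_alleles():
    """Cell-level co-occurrence exceeds the product of marginals, while the
    allele-level odds ratio conditional on the extrinsic factor stays ~1."""
    cfg = SimulationConfig(
        conditions=(Condition("c", KineticsParams(p_e=0.25, p_g=0.25, psi=1.0)),),
        n_cells_per_replicate=30_000,
        n_replicates=1,
        noise=NoiseParams(extrinsic_sigma=0.6),
        seed=9,
    )
    tr = simulate_dataset(cfg).truth
    cell = tr.groupby("cell_id")[["enhancer_state", "gene_state"]].max()
    p_both = ((cell["enhancer_state"] == 1) & (cell["gene_state"] == 1)).mean()
    assert p_both > 1.1 * cell["enhancer_state"].mean() * cell["gene_state"].mean()

    # stratify alleles by the (known) extrinsic factor: within strata the
    # enhancer-gene odds ratio should be ~1
    tr = tr.copy()
    tr["bin"] = np.digitize(tr["extrinsic_factor"], np.quantile(tr["extrinsic_factor"], np.linspace(0, 1, 21)[1:-1]))
    import statsmodels.api as sm

    tables = []
    for _, grp in tr.groupby("bin"):
        t = np.array(
            [
                [((grp.enhancer_state == 1) & (grp.gene_state == 1)).sum(),
                 ((grp.enhancer_state == 1) & (grp.gene_state == 0)).sum()],
                [((grp.enhancer_state == 0) & (grp.gene_state == 1)).sum(),
                 ((grp.enhancer_state == 0) & (grp.gene_state == 0)).sum()],
            ]
        )
        if t.min() > 0:
            tables.append(t)
    st_or = sm.stats.StratifiedTable(tables).oddsratio_pooled
    assert st_or == pytest.approx(1.0, abs=0.12)


def test_trans_distances_dominate_cis_distances():
    cfg = _config(n=4000, p_e=0.5, p_g=0.5)
    tr = simulate_dataset(cfg).truth
    g = tr[["gene_x", "gene_y"]].to_numpy().reshape(-1, 2, 2)
    e = tr[["enh_x", "enh_y"]].to_numpy().reshape(-1, 2, 2)
    trans = np.hypot(*(g[:, 0] - g[:, 1]).T)
    cis = np.hypot(*(g - e).reshape(-1, 2).T)
    # stochastic dominance at every decile
    qs = np.linspace(0.05, 0.95, 10)
    assert (np.quantile(trans, qs) > np.quantile(cis, qs)).all()
    assert (trans > 1.0).mean() > 0.95


def test_detection_and_false_spot_knobs():
    base = _config(n=3000, p_g=0.4, p_e=0.0, false_tss_rate=0.0)
    full = simulate_dataset(base)
    half_cfg = SimulationConfig(
        conditions=(Condition("c", KineticsParams(p_g=0.4, p_e=0.0, detect_prob=0.5)),),
        n_cells_per_replicate=3000,
        n_replicates=1,
        noise=NoiseParams(extrinsic_sigma=0.0),
        seed=123,
    )
    half = simulate_dataset(half_cfg)

    def n_tss(ds):
        return len(ds.spots[(ds.spots["compartment"] == "nuclear")])

    assert n_tss(half) == pytest.approx(0.5 * n_tss(full), rel=0.1)

    noisy = SimulationConfig(
        conditions=(Condition("c", KineticsParams(p_e=0.0, p_g=0.0, false_tss_rate=0.5)),),
        n_cells_per_replicate=3000,
        n_replicates=1,
        seed=123,
    )
    ds = simulate_dataset(noisy)
    n_false = (ds.spots["compartment"] == "nuclear").sum()
    assert n_false == pytest.approx(0.5 * 3000, rel=0.15)


def test_infeasible_geometry_raises_config_error():
    cfg = SimulationConfig(
        geometry=GeometryParams(nucleus_radius=1.0, min_allele_separation=1.9),
        n_cells_per_replicate=10,
    )
    with pytest.raises(ConfigError):
        simulate_dataset(cfg)


def test_invalid_kinetics_rejected_at_validation():
    bad = SimulationConfig(conditions=(Condition("c", KineticsParams(p_e=1.2)),))
    msgs = bad.violations()
    assert any("p_e" in m for m in msgs)
    bad = SimulationConfig(conditions=(Condition("c", KineticsParams(psi=-2.0)),))
    assert any("psi" in m for m in bad.violations())
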