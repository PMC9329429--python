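"""Canonical simulated study designs.

These functions freeze the generative conditions used throughout the
analyses: a null-coupling calibration design, a strong-coupling design, the
burst-parameter dissection (gene burst probability halved at fixed nascent
load), a dose panel tying telegraph frequency to burst probability, and the
cohesin-loss design (coupling removed, enhancer bursting preserved or
elevated, promoter bursting reduced).  Centralising them keeps the numbered
analysis scripts, the test suite and the acceptance script on identical
conditions.
"""

from __future__ import annotations

from dataclasses import replace

from burstlink.params import (
    Condition,
    GeometryParams,
    KineticsParams,
    NoiseParams,
    ProbeSpec,
    SimulationConfig,
)


def _nascent_probes() -> tuple[ProbeSpec, ...]:
    """Probe layout of a burst co-occurrence experiment: no exon probe."""
    return (
        ProbeSpec("enh", "ch633", "enhancer"),
        ProbeSpec("intron", "ch561", "gene_intron"),
    )

__all__ = [
    "null_coupling_config",
    "power_coupling_config",
    "dissection_config",
    "dose_panel_config",
    "cohesin_panel_configs",
]


def null_coupling_config(
    seed: int = 0,
    n_cells_per_replicate: int = 10_000,
    n_replicates: int = 3,
) -> SimulationConfig:
    """Independent enhancer/gene bursting, no extrinsic noise.

    The type-I-error calibration design: psi=1 and extrinsic_sigma=0, so any
    detected allele-level coupling is a false positive.  Only the nascent
    probes (enhancer + intron) are imaged, as in a co-occurrence experiment.
    """
    return SimulationConfig(
        conditions=(Condition("null", KineticsParams(p_e=0.2, p_g=0.2, psi=1.0)),),
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates=n_replicates,
        noise=NoiseParams(extrinsic_sigma=0.0),
        probes=_nascent_probes(),
        seed=seed,
    )


def power_coupling_config(
    seed: int = 0,
    n_cells_per_replicate: int = 10_000,
    n_replicates: int = 3,
    psi: float = 8.0,
) -> SimulationConfig:
    """Strong allele-level coupling (psi=8) at moderate burst probabilities."""
    return SimulationConfig(
        conditions=(Condition("coupled", KineticsParams(p_e=0.15, p_g=0.10, psi=psi)),),
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates=n_replicates,
        probes=_nascent_probes(),
        seed=seed,
    )


def dissection_config(
    seed: int = 0,
    n_cells_per_replicate: int = 10_000,
    n_replicates: int = 1,
    p_g_wt: float = 0.3,
) -> SimulationConfig:
    """Two genotypes differing only in gene burst probability (halved in KO).

    lambda_nascent (hence burst intensity) is shared, so the design isolates
    a pure burst-frequency change: the KO/WT burst-fraction ratio should be
    0.5 while mean burst intensity is unchanged.
    """
    base = KineticsParams(p_g=p_g_wt)
    return SimulationConfig(
        conditions=(
            Condition("WT", base),
            Condition("KO", replace(base, p_g=p_g_wt / 2)),
        ),
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates=n_replicates,
        seed=seed,
    )


def dose_panel_config(
    seed: int = 0,
    n_cells_per_replicate: int = 2_000,
    n_replicates: int = 3,
    p_g_values: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4),
    genotypes: tuple[str, ...] = ("WT", "KO"),
    f_per_p: float = 10.0,
    b: float = 5.0,
) -> SimulationConfig:
    """Condition ladder with telegraph frequency tied to burst probability.

    Eight gene burst probabilities per genotype with ``f = f_per_p * p_g``
    and shared burst size b, emulating induction time points: mean mature
    count is then proportional to burst fraction, so the log-log regression
    of count on fraction has slope 1, with no genotype interaction when b
    is shared.
    """
    conditions = tuple(
        Condition(f"{g}_p{p:g}", KineticsParams(p_g=p, f=f_per_p * p, b=b))
        for g in genotypes
        for p in p_g_values
    )
    return SimulationConfig(
        conditions=conditions,
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates=n_replicates,
        seed=seed,
    )


def cohesin_panel_configs(
    seed: int = 0,
    n_cells_per_replicate: int = 2_500,
    n_replicates: int = 3,
    n_loci: int = 4,
    timepoints: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
) -> dict[str, SimulationConfig]:
    """Wild-type vs cohesin-loss designs over several loci and time points.

    WT: coupled bursting (psi=8), gene burst probability tracking the
    enhancer's.  KO: coupling lost (psi=1), enhancer burst probability
    slightly elevated, gene burst probability reduced and flat across the
    induction — enhancer bursts persist but no longer propagate.  Geometry
    is identical, so cis enhancer-gene distance distributions must be
    indistinguishable between genotypes.

    Returns one config per locus; conditions within a config are
    (genotype x timepoint).
    """
    geometry = GeometryParams()
    out: dict[str, SimulationConfig] = {}
    base_pe = (0.08, 0.12, 0.16, 0.20)
    for locus in range(n_loci):
        pe_wt = [base_pe[locus % len(base_pe)] * (0.5 + 0.5 * t) for t in timepoints]
        pg_wt = [0.8 * p for p in pe_wt]
        # KO promoter bursting: reduced and flat across the induction
        pg_ko = 0.3 * (sum(pg_wt) / len(pg_wt))
        conditions = []
        for it in range(len(timepoints)):
            conditions.append(
                Condition(f"WT_t{it}", KineticsParams(p_e=pe_wt[it], p_g=pg_wt[it], psi=8.0))
            )
            conditions.append(
                Condition(f"KO_t{it}", KineticsParams(p_e=1.2 * pe_wt[it], p_g=pg_ko, psi=1.0))
            )
        out[f"locus{locus + 1}"] = SimulationConfig(
            conditions=tuple(conditions),
            n_cells_per_replicate=n_cells_per_replicate,
            n_replicates=n_replicates,
            geometry=geometry,
            seed=seed + locus,
        )
    return out
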