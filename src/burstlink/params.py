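"""Generative parameters for the synthetic smRNA-FISH dataset.

All lengths are in micrometres; intensities are arbitrary units on the scale
of the single-molecule intensity ``single_molecule_intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from burstlink.errors import ConfigError

__all__ = [
    "KineticsParams",
    "GeometryParams",
    "NoiseParams",
    "ProbeSpec",
    "Condition",
    "SimulationConfig",
]


@dataclass(frozen=True)
class KineticsParams:
    """Allele-level bursting kinetics.

    Parameters
    ----------
    p_e, p_g
        Per-snapshot probability that the enhancer / gene allele carries an
        active transcription site (the generative burst fraction).
    psi
        Enhancer-gene coupling odds ratio on the same allele.  ``psi = 1``
        means the two burst independently; ``psi > 1`` means coordinated
        bursting; ``numpy.inf`` is the perfect-coupling limit.
    f
        Telegraph burst frequency in bursts per mRNA lifetime.  In the bursty
        steady-state limit mature counts are Gamma-Poisson with mean ``f*b``
        and variance ``f*b*(1+b)``.
    b
        Mean burst size (mRNA produced per burst).
    lambda_nascent
        Mean number of *extra* nascent transcripts at an active TSS; the
        nascent count is ``1 + Poisson(lambda_nascent)``.
    detect_prob
        Probability that a true TSS focus survives into the spot table.
    false_tss_rate
        Expected number of spurious bright nuclear spots per cell (summed
        over channels).
    """

    p_e: float = 0.2
    p_g: float = 0.2
    psi: float = 1.0
    f: float = 2.0
    b: float = 5.0
    lambda_nascent: float = 5.0
    detect_prob: float = 1.0
    false_tss_rate: float = 0.0

    def violations(self) -> list[str]:
        v = []
        if not 0.0 <= self.p_e <= 1.0:
            v.append(f"p_e must be in [0, 1], got {self.p_e}")
        if not 0.0 <= self.p_g <= 1.0:
            v.append(f"p_g must be in [0, 1], got {self.p_g}")
        if self.psi < 0:
            v.append(f"psi must be >= 0, got {self.psi}")
        if self.f <= 0:
            v.append(f"f must be > 0, got {self.f}")
        if self.b <= 0:
            v.append(f"b must be > 0, got {self.b}")
        if self.lambda_nascent < 0:
            v.append(f"lambda_nascent must be >= 0, got {self.lambda_nascent}")
        if not 0.0 < self.detect_prob <= 1.0:
            v.append(f"detect_prob must be in (0, 1], got {self.detect_prob}")
        if self.false_tss_rate < 0:
            v.append(f"false_tss_rate must be >= 0, got {self.false_tss_rate}")
        return v


@dataclass(frozen=True)
class GeometryParams:
    """3D nuclear geometry.

    Defaults are chosen so that two alleles placed uniformly in the nucleus
    with the minimum separation project to xy distances above 1 um in >95%
    of pairs, while the cis enhancer-promoter offset stays well below it.
    """

    nucleus_radius: float = 4.0
    min_allele_separation: float = 2.0
    cis_separation_mean: float = 0.25
    cis_separation_sd: float = 0.12
    localization_sigma: float = 0.05
    #: per-channel xy shift (um); differences between channels emulate the
    #: uncorrected chromatic aberration between microscope lines.
    chromatic_shift: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ch488": (0.0, 0.0),
            "ch561": (0.1, 0.0),
            "ch633": (0.0, 0.1),
        }
    )

    def violations(self) -> list[str]:
        v = []
        if self.nucleus_radius <= 0:
            v.append(f"nucleus_radius must be > 0, got {self.nucleus_radius}")
        if not 0 < self.min_allele_separation < 2 * self.nucleus_radius:
            v.append(
                "min_allele_separation must be in (0, 2*nucleus_radius), got "
                f"{self.min_allele_separation}"
            )
        for name in ("cis_separation_sd", "localization_sigma"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cis_separation_mean < 0:
            v.append(f"cis_separation_mean must be >= 0, got {self.cis_separation_mean}")
        return v


@dataclass(frozen=True)
class NoiseParams:
    intensity_cv: float = 0.2
    extrinsic_sigma: float = 0.4

    def violations(self) -> list[str]:
        v = []
        if self.intensity_cv < 0:
            v.append(f"intensity_cv must be >= 0, got {self.intensity_cv}")
        if self.extrinsic_sigma < 0:
            v.append(f"extrinsic_sigma must be >= 0, got {self.extrinsic_sigma}")
        return v


@dataclass(frozen=True)
class ProbeSpec:
    """One simulated probe set.

    role is one of ``enhancer`` (lights eRNA TSS foci), ``gene_intron``
    (nascent-only gene probe) or ``gene_exon`` (gene probe that also detects
    cytoplasmic mature transcripts).
    """

    probe_id: str
    channel: str
    role: str

    _ROLES = ("enhancer", "gene_intron", "gene_exon")

    def violations(self) -> list[str]:
        if self.role not in self._ROLES:
            return [f"probe {self.probe_id}: role must be one of {self._ROLES}, got {self.role!r}"]
        return []


@dataclass(frozen=True)
class Condition:
    label: str
    kinetics: KineticsParams = field(default_factory=KineticsParams)


def _default_probes() -> tuple[ProbeSpec, ...]:
    return (
        ProbeSpec("enh", "ch633", "enhancer"),
        ProbeSpec("intron", "ch561", "gene_intron"),
        ProbeSpec("exon", "ch488", "gene_exon"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    conditions: tuple[Condition, ...] = (Condition("default"),)
    n_cells_per_replicate: int = 1000
    n_replicates: int = 3
    ploidy: int = 2
    geometry: GeometryParams = field(default_factory=GeometryParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    probes: tuple[ProbeSpec, ...] = field(default_factory=_default_probes)
    single_molecule_intensity: float = 100.0
    #: mean cytoplasmic single-molecule spots per cell for probes whose
    #: mature transcripts are not modelled by the telegraph counts
    #: (enhancer eRNA, released introns); these anchor the per-channel
    #: single-molecule reference intensity.
    singles_mean: float = 3.0

    def violations(self) -> list[str]:
        from burstlink.simulate import joint_burst_probability  # cycle guard

        v = []
        if self.n_cells_per_replicate < 1:
            v.append("n_cells_per_replicate must be >= 1")
        if self.n_replicates < 1:
            v.append("n_replicates must be >= 1")
        if self.ploidy < 1:
            v.append(f"ploidy must be >= 1, got {self.ploidy}")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            v.append("condition labels must be unique")
        if len(self.conditions) == 0:
            v.append("at least one condition is required")
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            v.append("probe ids must be unique")
        for p in self.probes:
            v.extend(p.violations())
        v.extend(self.geometry.violations())
        v.extend(self.noise.violations())
        for c in self.conditions:
            for msg in c.kinetics.violations():
                v.append(f"condition {c.label!r}: {msg}")
            if not c.kinetics.violations():
                k = c.kinetics
                # Frechet-bound feasibility of the implied joint probability
                p11 = joint_burst_probability(k.p_e, k.p_g, k.psi)
                lo = max(0.0, k.p_e + k.p_g - 1.0)
                hi = min(k.p_e, k.p_g)
                if not (lo - 1e-12 <= p11 <= hi + 1e-12):
                    v.append(
                        f"condition {c.label!r}: implied joint probability "
                        f"{p11:.6g} outside Frechet bounds [{lo:.6g}, {hi:.6g}]"
                    )
        if self.single_molecule_intensity <= 0:
            v.append("single_molecule_intensity must be > 0")
        if self.singles_mean < 0:
            v.append("singles_mean must be >= 0")
        return v

    def validate(self) -> "SimulationConfig":
        v = self.violations()
        if v:
            raise ConfigError("; ".join(v))
        return self

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    @property
    def n_cells_total(self) -> int:
        return len(self.conditions) * self.n_replicates * self.n_cells_per_replicate

    def probe_by_role(self, role: str) -> ProbeSpec:
        for p in self.probes:
            if p.role == role:
                return p
        raise KeyError(f"no probe with role {role!r}")


def lognormal_mean(sigma: float) -> float:
    """Mean of LogNormal(0, sigma); the expected extrinsic activity factor."""
    return float(np.exp(0.5 * sigma**2))
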