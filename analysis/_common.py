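"""Shared demo design and paths for the numbered analysis scripts.

The demo dataset is one inducible locus imaged with enhancer, intron and
exon probes, two genotypes (WT: coupled bursting, psi=8; KO: coupling lost,
promoter bursting reduced) at two induction time points, three replicates.
"""

from pathlib import Path

from burstlink.params import Condition, KineticsParams, SimulationConfig

_ROOT = Path(__file__).resolve().parent.parent
#: small summary tables, kept with the repository
RESULTS = _ROOT / "results"
#: bulky regenerable artifacts (raw simulated tables, per-spot outputs)
SCRATCH = _ROOT / "scratch"
DATA_DIR = SCRATCH / "demo_dataset"


def demo_config(seed: int = 7, n_cells_per_replicate: int = 1200) -> SimulationConfig:
    # telegraph frequency tied to the promoter burst probability (f = 8*p_g)
    # so mature-count kinetics track the induction, burst size shared
    def kin(p_e, p_g, psi):
        return KineticsParams(p_e=p_e, p_g=p_g, psi=psi, f=8 * p_g, b=5.0)

    return SimulationConfig(
        conditions=(
            Condition("WT_t0", kin(0.15, 0.12, 8.0)),
            Condition("WT_t1", kin(0.3, 0.24, 8.0)),
            Condition("KO_t0", kin(0.18, 0.05, 1.0)),
            Condition("KO_t1", kin(0.36, 0.05, 1.0)),
        ),
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates=3,
        seed=seed,
    )
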