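import numpy as np
import pandas as pd
import pytest

from burstlink.params import Condition, KineticsParams, NoiseParams, SimulationConfig
from burstlink.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Modest simulated dataset reused by read-only tests."""
    cfg = SimulationConfig(
        conditions=(Condition("act", KineticsParams(p_e=0.3, p_g=0.3, psi=4.0)),),
        n_cells_per_replicate=600,
        n_replicates=2,
        seed=11,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def ideal_dataset():
    """Noise-free detection: detect_prob=1, no false spots, no extrinsic noise."""
    cfg = SimulationConfig(
        conditions=(
            Condition("on", KineticsParams(p_e=0.25, p_g=0.3, psi=1.0, lambda_nascent=6.0)),
        ),
        n_cells_per_replicate=1500,
        n_replicates=2,
        noise=NoiseParams(extrinsic_sigma=0.0),
        seed=5,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def tiny_tables():
    """Three cells, hand-written spots: exercises I/O without the simulator."""
    cells = pd.DataFrame(
        {
            "cell_id": [1, 2, 3],
            "replicate_id": [1, 1, 2],
            "condition": ["WT", "WT", "KO, treated"],
            "nx": [0.0, 30.0, 60.0],
            "ny": [0.0, 0.0, 0.0],
            "nz": [0.0, 0.0, 0.0],
            "nucleus_radius": [4.0, 4.0, 4.0],
        }
    )
    spots = pd.DataFrame(
        {
            "spot_id": [10, 11],
            "cell_id": [1, 1],
            "probe_id": ["intron", "intron"],
            "channel": ["ch561", "ch561"],
            "x": [0.123456789012, 1.0],
            "y": [0.0, 2.0],
            "z": [0.5, -0.5],
            "intensity": [523.25, 98.0],
            "compartment": ["nuclear", "cytoplasmic"],
        }
    )
    return cells, spots


def make_tss(rows):
    """TSS table from (tss_id, cell_id, probe_id, x, y[, z]) tuples."""
    recs = []
    for r in rows:
        tss_id, cell_id, probe, x, y = r[:5]
        z = r[5] if len(r) > 5 else 0.0
        recs.append(
            {
                "tss_id": tss_id,
                "cell_id": cell_id,
                "probe_id": probe,
                "x": float(x),
                "y": float(y),
                "z": float(z),
                "burst_intensity": 3.0,
                "allele_label": "unassigned",
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
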