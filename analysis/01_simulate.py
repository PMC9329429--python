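"""Simulate the demo smRNA-FISH dataset and write it as CSV tables.

Emulates a two-genotype, two-timepoint induction experiment on one locus:
wild-type alleles burst with enhancer-promoter coupling (odds ratio 8),
knockout alleles burst independently with reduced promoter activity.
Writes cells.csv / spots.csv / truth.csv under results/demo_dataset/.
"""

from _common import DATA_DIR, demo_config

from burstlink.io import write_dataset
from burstlink.simulate import simulate_dataset

if __name__ == "__main__":
    cfg = demo_config()
    ds = simulate_dataset(cfg)
    paths = write_dataset(ds, DATA_DIR)
    print(f"simulated {len(ds.cells)} cells, {len(ds.spots)} spots (seed {cfg.seed})")
    for name, p in paths.items():
        print(f"  {name}: {p}")
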