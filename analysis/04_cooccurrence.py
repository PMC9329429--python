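"""Observed-vs-expected burst co-occurrence at cell and allele level.

For each condition: does a cell (or an allele) with an enhancer burst carry
a gene burst more often than the product of the marginal burst fractions
predicts?  Replicates enter a Cochran-Mantel-Haenszel test as strata;
p-values are Bonferroni-adjusted.  In the demo design the WT conditions are
generated with coupling odds ratio 8 and the KO conditions without
coupling, so the ratio should exceed 1 only in WT.
"""

import numpy as np
import pandas as pd
from _common import DATA_DIR, RESULTS, SCRATCH

from burstlink.cooccurrence import bonferroni, cooccurrence_analysis
from burstlink.io import load_dataset_dir

if __name__ == "__main__":
    ds = load_dataset_dir(DATA_DIR)
    tss = pd.read_csv(SCRATCH / "tss.csv")
    rows = []
    for cond in sorted(ds.cells["condition"].unique()):
        sub = ds.subset_condition(cond)
        sub_tss = tss[tss["cell_id"].isin(sub.cells["cell_id"])]
        for level in ("cell", "allele"):
            res = cooccurrence_analysis(
                sub_tss, sub.cells, "enh", "intron", level=level, ploidy=2, threshold=1.0
            )
            rows.append(
                {
                    "condition": cond,
                    "level": level,
                    "observed": res.observed_freq,
                    "expected": res.expected_freq,
                    "ratio": res.ratio,
                    "cmh_stat": res.cmh_statistic,
                    "p": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.where(out["p"].notna(), bonferroni(out["p"].fillna(1.0)), np.nan)
    out.to_csv(RESULTS / "cooccurrence.csv", index=False)
    print(out.round(4).to_string(index=False))
    print(
        "\ncoupled (WT) conditions show observed/expected >> 1; KO conditions sit near 1"
        "\n(the mild residual excess there reflects extrinsic cell-to-cell activity,"
        "\nnot allele-level coupling)"
    )
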