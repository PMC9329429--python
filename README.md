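# burstlink

Transcriptional-burst analysis for single-molecule RNA-FISH (smRNA-FISH)
spot tables: burst calling, allele assignment of enhancer and promoter
bursts by nuclear distance, observed-vs-expected burst co-occurrence
statistics, moment-based burst-kinetics inference, and enhancer–promoter
burst-fraction coupling analysis — together with a synthetic diploid-cell
simulator that provides ground truth for every stage.

## The problem

Inducible genes are transcribed in bursts: an allele switches between an
inactive state and an active state during which a bright nascent-RNA focus
appears at the transcription start site (TSS).  smRNA-FISH snapshots
thousands of cells and, per cell, records every fluorescent spot (position,
intensity, probe, compartment).  From such tables one wants to know

* **burst fraction** — what fraction of alleles carry an active TSS focus,
* **burst intensity** — how many nascent transcripts the focus holds,
  measured as focus intensity over the single-molecule intensity *I₁*,
* whether **enhancer (eRNA) and promoter bursts co-occur** on the same
  allele more often than chance, given that a diploid nucleus holds two
  alleles and only distance can tell *cis* (same allele) from *trans*,
* the telegraph-model kinetics behind the mature-mRNA counts: with burst
  frequency *f* and mean burst size *b*, steady-state counts are
  Gamma–Poisson with mean `μ = f·b` and variance `σ² = f·b·(1+b)`, so the
  moment estimators are `b_m = σ²/μ` (the Fano factor, which estimates
  `b+1`) and `f_m = μ/(b_m − 1)` (a consistent estimator of `f`),
* whether the enhancer→promoter coupling survives a perturbation such as
  loss of the cohesin complex, tested as a genotype interaction in the
  regression of log₂ gene burst fraction on log₂ enhancer burst fraction.

The pipeline starts **downstream of spot detection**; its inputs are plain
CSV tables (`cells.csv`, `spots.csv`, optional `truth.csv`).  Because real
imaging data are far too large to ship, a first-class simulator
(`burstlink.simulate`) generates spot tables with the statistical structure
the analysis assumes — two-state allele bursting with a tunable
enhancer–gene coupling odds ratio ψ, extrinsic cell-to-cell activity,
Gamma–Poisson mature counts, 3D nuclear geometry with cis separations far
below trans separations, localization noise and uncorrected chromatic
shifts — plus per-allele ground truth.

## Worked example

The numbered scripts under `analysis/` run a complete demo study: one
inducible locus, enhancer + intron + exon probes, WT (coupling ψ=8) vs KO
(ψ=1, promoter bursting reduced) at two induction time points:

```bash
cd analysis
python 01_simulate.py        # 14,400 cells -> scratch/demo_dataset/*.csv
python 02_quantify_bursts.py
python 03_pair_alleles.py
python 04_cooccurrence.py
python 05_infer_kinetics.py
python 06_coupling_loss.py
```

`02_quantify_bursts.py` prints the mean burst fraction per condition
(allele denominator):

```
probe_id      enh    exon  intron
condition
KO_t0      0.1840  0.0515  0.0512
KO_t1      0.3929  0.0547  0.0544
WT_t0      0.1553  0.1293  0.1297
WT_t1      0.3128  0.2403  0.2410
```

— KO enhancers burst *more* than WT while KO promoters stay flat at ~0.05,
the signature of coupling loss.  `03_pair_alleles.py` reproduces the
distance logic: 4–5 % of same-probe (necessarily trans) burst pairs fall
below 1 µm against 64.9 % of enhancer–gene pairs, and the calibrated
same-allele threshold is 1.08 µm.  `04_cooccurrence.py` shows allele-level
observed/expected co-occurrence ratios of 3.24 (WT_t0, CMH p ≈ 1e-40) and
2.14 (WT_t1) versus ~1.2 in KO.  `05_infer_kinetics.py` recovers kinetics
from mature counts (e.g. WT_t1: μ=20.3, b_m=8.6, f_m=2.7) and finds
log₂ burst fraction vs log₂ f_m correlated at r = 0.999 across conditions.
`06_coupling_loss.py` fits the coupling regression: WT slope 1.01 vs KO
slope 0.61, interaction p = 1.5e-06, while the cis-distance distributions
stay KS-indistinguishable (D = 0.028) — the geometry is identical, only the
coupling changed.

A TOML-driven end-to-end run of the same machinery is available as a CLI:

```bash
burstlink validate --config pipeline.toml
burstlink run --config pipeline.toml --out out/
```

with per-stage subcommands (`simulate`, `quantify`, `pair`, `cooccur`,
`infer-moments`, `couple`, `distances`).

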