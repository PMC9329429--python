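# Methods

## Generative model (simulator)

The simulator emulates the output of a spot-detection pipeline on diploid
cells, not images.  Per cell *c*:

1. **Extrinsic activity** `a_c ~ LogNormal(0, σ_ext)` (default σ_ext = 0.4)
   multiplies burst probabilities and telegraph frequency.  This models
   global cell-to-cell variability that correlates different loci within a
   cell without any allele-level coupling.  Because probabilities are
   clipped to [0, 1], very active cells introduce a small saturation bias
   at high burst probabilities (negligible below p ≈ 0.5 at the default
   σ_ext).
2. **Allele states.**  Each of the `ploidy` (default 2) alleles draws a
   bivariate Bernoulli pair (enhancer state E, gene state G) with marginals
   `clip(p_e·a_c, 0, 1)`, `clip(p_g·a_c, 0, 1)` and coupling odds ratio ψ.
   The joint probability is the admissible root of the Plackett quadratic
   `(ψ−1)p₁₁² − [(ψ−1)(p_e+p_g)+1]p₁₁ + ψ·p_e·p_g = 0`; ψ = 1 gives
   independence, ψ → ∞ the Fréchet upper bound `min(p_e, p_g)`.
3. **Nascent foci.**  An active TSS carries `k = 1 + Poisson(λ_nascent)`
   transcripts (default λ = 5) and appears as a nuclear spot of intensity
   `k·I₁·(1 + ε)`, `ε ~ N(0, cv)` with cv = 0.2 and I₁ = 100 (arbitrary
   units).  The `1 +` floor encodes that an active site holds at least one
   transcript; the count distribution at active sites is not constrained
   by snapshot data, so 1 + Poisson is a modelling choice (tests cover
   λ ∈ {4, 5, 6}-scale settings through the studies).
4. **Mature mRNA.**  Per allele, counts are Gamma–Poisson:
   `m ~ Poisson(Gamma(shape = f·a_c, scale = b))` — the bursty steady-state
   limit of the telegraph model, exact for the moment formulas below.  The
   counts render as cytoplasmic single-molecule spots.
5. **Geometry.**  Alleles sit uniformly in a nuclear sphere (radius 4 µm)
   with pairwise separation ≥ 2 µm (rejection sampling); the enhancer locus
   is offset from the gene locus by `|N(0.25, 0.12)|` µm in a uniform
   direction.  Every spot position gets isotropic localization error
   (σ = 0.05 µm) and a per-channel xy chromatic shift (defaults ~0.1 µm
   between channels, *not* corrected downstream — the analysis must absorb
   it, as the imaging data it emulates were not corrected either).  With
   these defaults ~96.5 % of trans (allele–allele) pairs exceed 1 µm in xy
   while cis pairs concentrate near 0.27 µm.
6. **Detection.**  True TSS foci are dropped with probability
   `1 − detect_prob`; spurious bright nuclear spots appear at
   `false_tss_rate` per cell.  Defaults are 1.0 and 0.0: the generator's
   baseline emulates well-filtered detection output, and the two knobs are
   stress dials exercised explicitly in tests.

All draws come from a single seeded numpy PCG64 generator, so a (config,
seed) pair reproduces a dataset byte-for-byte.  We deliberately use one
vectorised stream rather than per-cell substreams: instantiating a
counter-based generator per cell costs more than the entire remaining
simulation at the 10⁴–10⁵-cell scales the calibration studies need, and no
analysis in this package relies on prefix stability of the cell sequence
under a change of n_cells.

## Burst calling and burst parameters

The single-molecule reference I₁ per probe is the median of cytoplasmic
spot intensities at or below their 90th percentile (nuclear spots as a
fallback when cytoplasmic spots are scarce, with a hard floor of 20 spots).
Trimming the top decile guards against aggregates; on symmetric intensity
noise it biases I₁ down by ~2–3 %, which cancels in every ratio-based
quantity the pipeline reports.

A nuclear spot is a TSS candidate when its intensity is ≥ τ·I₁ (default
τ = 2; a "burst" must outshine a single molecule).  Per cell and probe at
most `ploidy` brightest candidates are kept — extra candidates are capped,
never cause the cell to be discarded.  Burst intensity is intensity/I₁.
Burst fraction uses the allele denominator (`ploidy` × cells) by default,
with a per-cell option.  The threshold loses the dimmest true bursts
(nascent count 1, or 2 with unlucky noise); at λ = 5–6 this bias is below
0.01 in burst-fraction units and, being multiplicative and shared across
conditions, cancels in the WT/KO ratios the analyses compare.

Expression decomposition: fraction of cells with ≥ 5 transcripts (the
threshold is configurable) and mean count among exactly those cells.

## Allele assignment by distance

All TSS–TSS distances are xy-only; the axial coordinate is carried for
diagnostics but never used (axial localization is several-fold worse in
the data this emulates).  Same-probe pairs in a diploid cell are
necessarily trans, so their distance distribution calibrates the
same-allele threshold: the type-1 empirical q-quantile (order statistic
⌈qn⌉, default q = 0.05) is the distance below which a cross-probe pair is
same-allele with confidence ≥ 1−q.  Under the default geometry this
calibrates to ≈ 1.1–1.2 µm, consistent with the 1 µm rule-of-thumb the
field uses; with fewer than 20 trans pairs the configured default (1 µm)
is used with a warning.

Cross-probe pairs below the threshold are matched by iterated mutual
nearest neighbours (accept the closest remaining pair, remove both
members, repeat), with ties broken by distance then lexicographic ids —
deterministic and symmetric in the two probes.  On simulated data the
precision of cis assignment exceeds 1−q (measured ≈ 0.99 at q = 0.05).

## Co-occurrence statistics

Expected co-occurrence under independence is the product of the marginal
burst probabilities, estimated *within replicate* (replicate-level
marginal shifts must not masquerade as coupling).  Per replicate a 2×2
table compares the observed population against a same-size
pseudo-population whose co-occurrence count is the rounded expected count;
replicates pool through the Mantel–Haenszel chi-square
`T = [Σ(n₁₁−E)]²/ΣV` without continuity correction (switchable), p from
χ²(1).  A pooled exact binomial check is provided as a secondary
diagnostic.  Cell-level analysis uses cells as units (events: ≥ 1 burst of
each probe; with one probe, the bi-allelic variant compares cells with two
bursts against the squared allele-level probability).  Allele-level
analysis uses allele slots; observed co-occurrences are the cis-matched
pairs.  Bonferroni adjustment across tests.

Known limitation: a fraction of trans pairs (~3.5 % under the default
geometry, 1–4 % in the data this emulates) falls below the matching
threshold, so the allele-level observed count carries a small additive
contamination (+2–3 % on the ratio under independence).  The CMH test
absorbs this at the calibration sample sizes (measured type-I rate 3.5 %
at α = 0.05 over 200 runs of 3×10⁴ cells), but at very large pair counts a
KS comparison of matched-pair distance distributions between genotypes
becomes slightly anticonservative when the genotypes differ in their
cis/trans composition (coupling changes the share of true cis pairs).
This is a property of 1 µm-style assignment itself, not of the
implementation.

## Moment-based kinetics

`b_m = σ²/μ` and `f_m = μ/(b_m − 1)`, estimated on 1000 subsamples of 50
cells (without replacement within a subsample), aggregated by the median
of per-subsample estimates (ratio estimators at n = 50 are heavily
right-skewed; a mean-of-estimates variant is available).  Unbiased (n−1)
variance — material at n = 50.  Note that in the Gamma–Poisson limit b_m
estimates b+1, not b: the Fano factor over-counts the burst size by one
Poisson unit.  f_m remains consistent for f, which explains why inferred
frequency tracks the measured burst fraction while inferred "size" tracks
burst intensity only loosely.  Sub-Poissonian subsamples (b_m ≤ 1) yield
no frequency and are excluded from the aggregate; zero-count cells are
included (excluding them would bias μ up).

## Coupling and distance comparisons

Burst-fraction coupling: OLS of `log2(gene BF) ~ log2(enh BF) * genotype`,
with the interaction F-test (full vs additive model) as the headline
p-value; per-group slopes from the interaction model coincide exactly with
separate per-group regressions.  Zero fractions are excluded with their
count reported; a replicate covariate can be added (off by default,
matching the plain two-variable design).  Distance distributions compare
via the two-sided two-sample KS test with asymptotic p (exact optionally,
for small samples).  Domain-level coupling averages enhancer changes
within a (condition, domain), pairs them with the domain's gene change,
and reports per-condition Pearson correlations plus the same interaction
test.

## Study designs and problem sizes

The canonical designs live in `burstlink.scenarios`; sizes were chosen so
every distributional claim is tested well inside its tolerance: null and
power calibration use 10⁴ cells × 3 replicates × 200 runs (ψ = 1 with
σ_ext = 0, and ψ = 8 at p_e = 0.15, p_g = 0.10); threshold calibration uses
~5×10³ trans pairs; the dissection 10⁴ cells per genotype; the coupling-loss
design 4 loci × 4 time points × 2 genotypes × 3 replicates × 2500 cells.
The co-occurrence designs image only the nascent probes (enhancer +
intron), as a co-occurrence experiment would.

## What passing tests do and do not show

The simulator reproduces the statistical structure the analysis assumes —
it cannot certify performance on features it does not model: segmentation
errors, diffraction-limited spot merging at dense TSS clusters, probe
off-target binding, z-dependent detection efficiency, or non-steady-state
transcript dynamics during rapid induction.  Recovery results on synthetic
data bound the method's statistical behaviour, not its robustness to
imaging artefacts beyond the noise sources listed above.
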