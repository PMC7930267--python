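# Methods

## Scope and model

`metnorm` analyses matched primary-tumour (PT) / lymph-node-metastasis (LNM)
expression measured on an nCounter-style hybridization count panel. The
quantity of interest per gene *g* and patient *p* is the healthy-background
normalized log2 LNM/PT ratio

    normalized[g, p] = log2(LNM[g, p] / PT[g, p]) − log2(LN_FPKM[g] / BREAST_FPKM[g])

whose per-gene cohort median drives a threshold classification (no per-gene
hypothesis test — with 11 pairs the design favours effect-size thresholds
over p-values). The subtraction removes the physiological expression
difference between the two host tissues, measured once from healthy-tissue
RNA-seq FPKM; cancer counts and healthy FPKM are never mixed on one scale,
only their *ratios* are compared, which keeps the correction within-platform.

## Count normalization

* **Background**: per lane, threshold = mean + 2·SD of the negative-control
  counts (sample SD, n−1; the multiplier is configurable). Sub-threshold
  counts are *floored at* the threshold rather than background-subtracted:
  subtraction would create zeros/negatives and destroy downstream logs,
  while flooring is idempotent and monotone in the multiplier. Negative
  controls themselves are left untouched.
* **Housekeeping selection**: stability = coefficient of variation of log2
  counts across lanes, ascending, ties broken lexicographically. CV of logs
  was chosen as the simplest defensible stability criterion; the selected
  names are always reported, never assumed.
* **Global-mean scaling**: lane summary = geometric mean of the positive
  controls plus the selected housekeeping probes; factors equalize it to the
  across-lane geometric mean. Geometric was preferred over arithmetic for
  scale-equivariance (an arithmetic variant is a config switch). Note the
  exact invariance: multiplying one lane's entire table by *c* changes every
  normalized value by the single global constant c^(1/n_lanes) — between-lane
  structure, hence every ratio, is unchanged.
* **Low-expression filter**: mean over lanes of log2(max(count, 1)) < 6
  excludes the gene (strict inequality; a gene at exactly 6 is kept). The
  alternative reading log2(mean count) is available via
  `low_expression_stat="log2_mean"`; the mean-of-logs default matches a
  log2-first pipeline. The floor of 1 guards lanes whose background
  threshold is 0.

## Healthy filter, intersection, classification

Genes below log2 FPKM 5 in **both** healthy tissues are dropped (the "any"
reading is a config option); zero-FPKM genes are dropped with a warning
rather than pseudocounted, because a pseudocount would distort the healthy
ratio exactly where the filter boundary makes it matter. The analysis
universe is the count-filtered panel ∩ healthy-table genes, in panel order.

Classification (all strict inequalities; ties → unclassified):
enriched iff median normalized ratio > +1; depleted iff < −1; upregulated
iff enriched AND healthy ratio < 0 AND median **raw** matched ratio > 0;
downregulated mirrored. The "expression tendency" condition uses the raw
(unnormalized) matched-ratio median by default — the normalized median
alternative is exposed as `tendency="normalized"`. Medians use the
mean-of-middle-two convention for even cohort sizes (the default cohort has
11 pairs, so this only matters for other designs).

## Over-representation analysis

One-sided upper-tail hypergeometric test per gene set, restricted to sets
with ≥ 3 in-universe members and ≥ 1 query overlap; Benjamini–Hochberg
step-up adjustment across tested sets (zero-overlap sets are excluded from
the adjustment denominator by default — including them is a flag, documented
because it changes m). The default background is the analysed-gene universe
intersected with the union of collection members, the closest local
analogue of curated-pathway services that restrict their background to
annotated genes. The tail probability comes from `scipy.stats.hypergeom`;
tests verify it against exhaustive subset enumeration on small universes.
BH is implemented directly from the step-up definition and cross-checked
against statsmodels.

## IHC scoring and inference

Intensity dichotomization: none/weak → negative, moderate/strong → positive;
noninformative passes through. Specimen status per compartment = maximum
over informative cores (≤ 5 cores). Overall status = positive if either
compartment is positive, noninformative only if both are, negative
otherwise; this "either-positive" rule is the natural maximum over
compartments, and the behaviour when one compartment is noninformative
(other-negative → overall negative) is a deliberate choice.

The PT-vs-LNM comparison is an **unpaired** two-sided Fisher exact test on
specimen counts (group sizes differ once noninformative specimens drop
out); an exact McNemar mode is provided for strictly paired designs. The
Fisher p-value uses the probability-ordering rule — sum of probabilities of
all same-margin tables no more likely than the observed one, with a 1+1e−7
relative tie tolerance — implemented directly (the tie rule is part of the
contract) and verified exhaustively against exact rational enumeration for
every table with total ≤ 40, plus a cross-check against scipy.

Survival: Mantel–Haenszel log-rank (via lifelines, validated against a
hand-computed example, χ² ≈ 2.88), grouped by the metastasis's tumoral
staining status. Three-year overall survival administratively censors all
follow-up at 36 months — deaths after the horizon count as censored at 36.

## Synthetic cohort generator

Defaults encode the emulated study design: 11 matched pairs; a 730-gene
panel with 8 negative, 6 positive and 40 housekeeping controls; a 79-patient
IHC arm with 43 node-positive patients (metastasis specimens exist only for
these); and planted gene classes sized so the filters reproduce the
730 → 593 → 578 → 360 funnel (137 low-expression, 15 absent from the healthy
table, 218 below the FPKM floor; the analysed 360 split 3 up / 8
enriched-only / 33 down / 37 depleted-only / 279 null).

Endogenous counts are negative binomial, mean = lane factor × 2^base ×
2^(effect for LNM lanes), variance mean + φ·mean² with φ = 0.1 (moderate
overdispersion typical for hybridization counts); negative controls are
Poisson(5); positive controls follow a fixed four-fold geometric ladder ×
lane factor; lane factors are log-normal with SD 0.2 log2. Base log2 means
are N(9, 1) clipped to [8, 14] so that even a −3 log2 metastasis shift stays
clear of the expression filter; low-expression genes are planted well below
it. Planted effects: up/down genes get a ±3 log2 cancer effect with an
*opposing* ∓1.5 healthy ratio; the enriched-/depleted-only classes are
decoys with the same cancer effect but an *aligned* healthy ratio, so the
classification's opposite-direction requirement is exercised. Healthy FPKM
base levels are log-normal (log2 mean 8, SD 1.5) clipped above the filter
floor for retained classes and below it for the healthy-low class.

IHC positivity is a per-specimen latent Bernoulli (PT 0.70, LNM 0.35,
roughly the asymmetry the design targets), realised as five core
intensities with 10 % noninformative dropout; a latent-negative specimen
never draws a positive core, so the max rule recovers the latent status up
to dropout. Survival is exponential with baseline hazard 0.01/month,
multiplied by 4 for patients whose metastasis lost tumoral staining, with
exponential censoring (0.01/month) truncated at 120 months of follow-up.

Every output file draws from its own PRNG stream spawned from the master
seed (`numpy` SeedSequence), so identical configs give byte-identical
files. The null generator zeroes every planted effect (cancer effects,
healthy ratios of analysed genes, the PT/LNM positivity gap, the hazard
ratio) while keeping the filter classes, and is the basis of the
calibration tests.

### What the generator does and does not emulate

It reproduces the *structure* of the real inputs — code classes, lane
effects, count overdispersion, filtering funnel, matched pairing, core-level
IHC with dropout — but not batch/cartridge effects, probe-specific
hybridization efficiencies, FFPE degradation, correlated gene modules, or
inter-observer scoring noise. Passing recovery tests therefore shows the
*algorithms* are correct and calibrated under the stated noise model, not
that any particular biological result would replicate on real tissue.

## Problem sizes and numerical choices

Unit tests run on a scaled-down cohort (6 pairs, ~54 genes) for speed; the
acceptance checks use the full default cohort (11 pairs, 730 genes) and 200
seeded null cohorts for calibration. Exhaustive oracle checks cover all 2×2
tables with N ≤ 40 and all ORA configurations on universes ≤ 12. Tolerances:
normalizer geometric-mean equality to 1e−9 relative; the element-wise ratio
identity to 1e−12; exact-test agreement to 1e−9 relative.

## Known limitations

* The healthy correction assumes one FPKM value per tissue (no donor
  variance); real references carry sampling noise the medians inherit.
* The classification has no significance statement attached; it is a
  thresholding scheme by design.
* The background universe of the ORA step only approximates what curated
  web services use, so adjusted q-values are comparable within a run, not
  across tools.
* With 11 pairs the median-based calls are robust to ~5 discordant pairs
  but insensitive to subtle (< 1 log2 beyond background) shifts.
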