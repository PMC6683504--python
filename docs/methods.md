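# Methods

This note documents the models and procedures implemented in
`rdgenomics`, the assumptions behind them, the tunable parameters, and
what the synthetic-cohort generator does and does not emulate.

## Setting

The package analyzes molecular correlatives of a post-neoadjuvant
triple-negative breast cancer (TNBC) cohort: patients with residual
disease (RD) after neoadjuvant chemotherapy (NAC), profiled on a
~70-gene targeted DNA panel (somatic variants and per-gene copy number),
whole-transcriptome expression, slide-level lymphocyte percentages, and
disease-free / overall survival (DFS/OS) follow-up. Samples exist at up
to two timepoints per patient — diagnosis (pre-NAC biopsy) and surgery
(the RD specimen) — and only samples with tumor cellularity (purity)
of at least 60% enter molecular analyses; lower-purity samples are
flagged, never silently dropped.

## Copy-number state calling

Per-assay reference ranges are built from normal (leukocyte-derived)
genomes as mean ± k·SD of the normal copy-number estimates, with the
sample standard deviation (n−1 denominator; normal cohorts are small)
and k = 3 by default — the wide band absorbs noise from formalin-fixed
input. Calling precedence for a copy number c against a range [lo, hi]:

1. AMPLIFIED if c > 4.99 (a deliberately conservative threshold,
   checked before the range so extreme values never read as "gain");
2. GAIN if c > hi;
3. EXTENSIVE_LOSS if c < 0.5 (a hard floor below any plausible range);
4. LOSS if c < lo;
5. NORMAL otherwise. Range bounds are inclusive: a value equal to a
   bound is normal, which minimizes false aberration calls.

With lo ≥ 0.5 and hi ≤ 4.99 (any sane diploid range) the call is a
partition and monotone in c under the dosage order
EXTENSIVE_LOSS < LOSS < NORMAL < GAIN < AMPLIFIED; both properties are
tested.

## Purity correction

Tumor tissue is modeled as a two-component mixture: tumor cells at
fraction p (purity, in (0, 1]) and diploid, non-mutated normal cells at
1 − p. The corrections are

    VAF_tumor = min(VAF_obs / p, 1)
    CN_tumor  = max((CN_obs − 2(1 − p)) / p, 0)

Both are exact identities at p = 1, and CN = 2 is a fixed point at any
purity. The mixture forms are this package's choice; they are the
simplest inversions consistent with the two-component model. States are
called on corrected copy numbers so a contaminated loss still
registers. A practical caveat for users: in tumors whose true local
copy number is far from 2, VAF/p over-corrects (the mutant-allele
dosage depends on the copy state); the 25% subclonality cutoff below
was chosen in part to absorb that ambiguity, and no copy-number cap is
applied to the corrected VAF.

## LOH and the normal heterozygosity range

Loss of heterozygosity at TP53 is operationalized as upward skew of the
purity-corrected VAF beyond the upper bound of a normal heterozygosity
range built from heterozygous SNP calls in normal genomes (mean ± 3 SD;
[0.38, 0.59] by default when no normal SNP table is supplied). Downward
skew is not LOH here — it marks subclonality, which the risk
stratification treats separately. The upper bound is inclusive.

## Graduated TP53 risk stratification

Per patient, evidence is collapsed across timepoints: mutation presence
and the maximum corrected VAF union over both samples (TP53 calls are
stable between timepoints), while copy-number-derived evidence (copy
loss, LOH flag) comes from the surgery sample when both exist — the
analyses concern residual disease — falling back to the diagnosis
sample for pre-only patients. Strata:

- LOW — no TP53 mutation, or only a subclonal mutation (max corrected
  VAF < 0.25) with no compounding event;
- HIGH ("compound") — a mutation plus LOH or TP53/17p copy loss;
- MODERATE — a clonal mutation standing alone.

A subclonal VAF co-occurring with copy loss classifies HIGH: copy loss
itself depresses VAF, so treating such patients as low-risk would
contradict the compounding logic. The classifier is a partition, is
monotone in severity (adding a compounding event never lowers the
stratum), and recovers planted strata exactly on noise-free cohorts.
The TP53 gene on the panel proxies the 17p arm; no independent arm
model is used.

## Survival machinery

Kaplan–Meier product-limit curves, the k-group log-rank test, and
proportional-hazards hazard ratios with Wald CIs are provided by
lifelines; Cox models use the Efron tie approximation because
month-resolution times tie often. "Multivariate" survival analysis is a
Cox model with the cohort's covariates — age (continuous), nodal status
(positive vs negative), and RCB class (I/II vs III) — reported
alongside the univariate log-rank. All tests are two-tailed; α = 0.05
and FDR = 10% by default. A group with zero events makes an HR
non-identifiable; the result then carries an explicit marker and an
unbounded CI rather than a numeric artifact.

## Two-stage copy-number/recurrence screen

Stage 1 compares purity-corrected copy number per locus between
recurred and non-recurred patients by one-way ANOVA (equivalent to the
squared two-sample t for two groups). Stage-1 survivors (p < α₁ = 0.05)
are grouped by gain status (called state above normal) when the
recurred-group mean is higher, by loss status otherwise — the grouping
direction follows the sign of the stage-1 mean difference — and tested
for DFS by log-rank; a locus is positive only if also p < α₂ = 0.05.
No multiplicity correction is applied across loci, matching the
screen's exploratory framing, but a BH-adjusted stage-1 column is
emitted. Loci that cannot be tested (constant values, an empty
direction group, too few patients per recurrence class) carry explicit
skip diagnostics, and every stage-1 survivor receives either a stage-2
p-value or such a diagnostic. Under null cohorts the per-locus positive
rate is ≈ α₁·α₂ (both stages must fire), far below α₁; this is
simulated in the acceptance checks.

## Expression analyses

Counts are normalized as RPKM = count / (length_kb × library_millions);
matrices already in RPKM pass through. Differential expression runs on
log2(RPKM + 1) — the log stabilization is this package's declared
choice — with per-gene one-way ANOVA (or paired t when subject pairings
are given) and Benjamini–Hochberg adjustment; genes constant across all
samples get p = 1 and a flag. "Expressed"/"detected" means nonzero in
at least 20% of samples (configurable). The transcriptional-
amplification statistic is the fraction of significant genes
overexpressed in the focal group — a global, predominantly upward shift
(up-fraction near 1) is the recognized footprint of MYC hyperactivity.
The regional screen filters genes by cytoband string prefix (18q21.1 /
18q21.2 by default, the ~10 Mb window around SMAD4), keeps expressed
protein-coding genes, and reports those significantly up in the
gain group. Cytoband matching is string-prefix only; no coordinate
arithmetic is attempted. The panel-detection QC reports the fraction of
an immune gene panel detected at all, which is what limits
deconvolution methods on immune-depleted RD tissue.

## Synthetic-cohort generator

The generator emulates the cohort structure the analyses assume, with
event frequencies fixed at the cohort's: TP53 mutation 88%, PIK3CA 11%,
TP53 copy loss 29%, MYC amplification 24%, MCL1 21%, GATA3 11%, BRCA2
loss 68%, SMAD4-region gains 37% carrying a DFS hazard multiplier of
2.3, purity uniform on 0.60–1.00, and 18 matched diagnosis/surgery
pairs per 75 patients. Background arm gains on 1q/8q/10p are drawn at
50% per gene — those gains are nearly universal in this disease — and
10% of losses fall below 0.5 copies. LOH is drawn for 40% of clonally
mutated patients and subclonality for 15% of mutated patients; these
two rates are not printed anywhere and were chosen once so the expected
stratum split approximates the cohort's 14/21/40 of 75. True VAFs are
drawn in disjoint bands ([0.05, 0.20] subclonal, [0.30, 0.55] clonal,
[0.65, 0.95] LOH) so that noise-free recovery is exact by construction.

Observed values are mixtures: CN_obs = CN_true·p + 2(1 − p) plus
Gaussian measurement noise (SD 0.10), VAF_obs = VAF_true·p plus noise
(SD 0.02). Normal genomes are Gaussian(2, 0.15) per assay and
heterozygous SNP VAFs Gaussian(0.485, 0.035), so default ±3 SD ranges
approximate [1.55, 2.45] and [0.38, 0.59]. Setting `noise=False`
zeroes all measurement noise for exact end-to-end recovery tests.

Survival is exponential proportional hazards: patient hazard =
baseline × stratum multiplier × TP53-loss multiplier × screen-locus
multiplier, with baseline ln 2 / 48 per month (LOW-risk median DFS of
four years) and administrative censoring uniform on 24–72 months of
follow-up. OS is DFS plus an exponential post-recurrence survival
(median 18 months) for patients who recur, which guarantees
DFS ≤ OS. This is the simplest model satisfying the proportional-
hazards assumption the HR estimator makes, so planted multipliers equal
the marginal HRs being estimated.

Expression is log-normal (log2 means N(4, 1.5), within-group SD 0.5)
over the panel genes, the 18q21 region genes, and synthetic filler
genes (600 total by default; 20% of fillers silent); compound-TP53
samples get a global ×1.5 up-shift, MYC-amplified samples ×3 on MYC,
region-gain samples ×2 on SMAD2, and a quarter of filler genes are
down-shifted ×0.6 at surgery to emulate post-chemotherapy depletion.
Lymphocyte percentages are Gaussian (mean 20, SD 10) with a planted
post-NAC shift of −8 ± 10 percentage points.

One seeded generator drives everything through spawned per-module
substreams, so the same seed yields a byte-identical cohort.

What the generator does **not** emulate: genome-wide segment structure
(events are per-gene and independent apart from the planted arms),
FFPE artifacts, read-level noise, subclonal copy-number mixtures,
gene–gene expression correlation, and non-proportional hazards.
Passing tests therefore demonstrate that the estimators recover what
they assume, not that real RD cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

- Sample SD (n−1) everywhere a reference range is built; a zero-SD
  range collapses to a point and everything off it is called aberrant.
- t tests and ANOVA return (0, 1) when all values are identical, and a
  signed infinite statistic with p = 0 when group means differ with
  zero within-group variance.
- BH adjustment is the step-up q = cummin(p·m/i), capped at 1,
  monotone, and never below the input p.
- Matched-pair variant identity is (gene, protein change) when the
  protein change is recorded, else (gene, variant class).
- The per-patient timepoint-preference rule (surgery first) is a stated
  package choice; cohorts where pre and post disagree on copy state
  will classify by the surgery call.

## Problem sizes used in the acceptance computations

Null calibration uses 2000 log-rank replicates (n = 50 per group) and
500 screen replicates over 70 loci; hazard-multiplier recovery uses 50
seeds at n = 300 patients; screen-locus detection 50 seeds at n = 200;
noiseless recovery one 80-patient cohort and one 18-pair cohort; the
expression footprints one 75-patient cohort each. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances (±2
percentage points on a 5% rate at 2000 replicates; ~15% relative on an
HR at 50 × 300).

## Known limitations

- The purity corrections assume a diploid normal compartment and
  clonal, heterozygous-origin mutations; the VAF correction ignores the
  local copy state.
- LOH detection is one-sided (upward skew only) and gated by the het
  range; copy-neutral LOH with a VAF inside the band is missed.
- The screen tests loci marginally; correlated loci (same amplicon or
  arm) will co-fire.
- Expression DE assumes two groups; multi-group contrasts must be
  decomposed by the caller.
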