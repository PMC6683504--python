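# rdgenomics

Genomic correlates of recurrence in chemorefractory triple-negative
breast cancer (TNBC) residual disease.

About half of TNBC patients with residual disease (RD) after
neoadjuvant chemotherapy relapse within a few years, and no targeted
therapy exists for them. This package implements, as a tested and
reusable pipeline, the correlative analyses that link somatic genomics
of RD tumors to recurrence: reference-range-based somatic copy-number
and LOH calling from a ~70-gene panel, tumor-purity correction, a
graduated three-tier TP53-inactivation risk classifier, Kaplan–Meier /
log-rank / Cox survival association machinery, a two-stage copy-number
→ recurrence screen, and expression analyses (MYC-style transcriptional
amplification, an 18q21 regional screen, immune-panel detection QC).
A synthetic-cohort generator with the cohort's event frequencies makes
every stage testable without access to patient data.

It is written for computational biologists and biostatisticians working
with targeted-panel oncology cohorts.

## The core procedures

**Copy-number states.** Per-assay reference ranges from normal genomes,
mean ± 3·SD (sample SD). A corrected copy number c is called

    AMPLIFIED (c > 4.99) → GAIN (c > upper) → EXTENSIVE_LOSS (c < 0.5)
    → LOSS (c < lower) → NORMAL

with inclusive bounds, in that precedence.

**Purity correction.** With tumor purity p and a diploid contaminating
compartment: VAF* = min(VAF/p, 1) and CN* = max((CN − 2(1 − p))/p, 0).

**Graduated TP53 stratification.** Per patient, across timepoints:
LOW — no mutation or only a subclonal one (corrected VAF < 25%);
HIGH ("compound") — mutation + LOH (VAF* above the normal heterozygosity
band [0.38, 0.59]) or TP53 copy loss; MODERATE — a clonal mutation
alone. Strata are compared by three-way log-rank and pairwise hazard
ratios on DFS and OS.

**Two-stage screen.** Stage 1: per-locus ANOVA of corrected copy number,
recurred vs not. Stage 2: stage-1 survivors grouped by gain/loss status
(direction of the stage-1 mean difference) and tested on DFS by
log-rank. Positive = both p < 0.05.

Survival machinery is lifelines (Efron ties), classical tests are scipy,
and FDR control is Benjamini–Hochberg via statsmodels; each primitive is
verified against independent brute-force oracles in the test suite.

## Worked example

Run the full pipeline on a seeded synthetic 75-patient cohort:

```
rdgenomics all --out run1 --seed 1
```

which prints, stage by stage (abridged):

```
[simulate] {'tables': ['clinical.tsv', 'copynumber.tsv', 'expression.tsv',
            'normals.tsv', 'tp53_het_vafs.tsv', 'variants.tsv'], 'n_patients': 75, ...}
[call]     {'n_samples_called': 93, 'n_pairs': 18, 'n_row_diagnostics': 0, ...}
[stratify] {'strata_counts': {'HIGH': 34, 'MODERATE': 27, 'LOW': 14}, ...}
[survive]  {'n_contrasts': 3, 'stratum_counts': {'HIGH': 34, 'MODERATE': 27, 'LOW': 14}, ...}
[screen]   {'n_loci': 70, 'n_stage1_survivors': 2, 'positives': ['SMAD4'], ...}
[express]  {'n_de_significant': 501, 'up_fraction': 1.0,
            'n_region_expressed': 20, 'region_overexpressed': ['SMAD2'], ...}
```

Reading this: 93 samples (75 surgical + 18 matched diagnostic biopsies)
were called against the normal-derived reference ranges with no rows
rejected; patients stratify 14 / 27 / 34 into LOW / MODERATE / HIGH
TP53-inactivation risk; the two-stage screen over 70 loci flags only the
planted SMAD4 gain locus; differential expression between compound-TP53
tumors and the rest finds 501 genes at 10% FDR, **all** overexpressed in
the compound group (the transcriptional-amplification footprint of MYC
hyperactivity); and within 18q21 the only overexpressed protein-coding
gene in gain-bearing tumors is SMAD2. Result tables
(`called_states.tsv`, `strata.tsv`, `survival_contrasts.tsv`,
`screen_results.tsv`, `de_results.tsv`, `regional_screen.tsv`, ...) and
a run manifest with config/input hashes land in `run1/`.

The same flow is available as a library:

```python
from rdgenomics import CohortConfig, generate_cohort
from rdgenomics.calling import build_reference_range, call_sample
from rdgenomics.screens import cohort_frames, survival_by_copy_state

sim = generate_cohort(CohortConfig(n_patients=300, seed=7))
ranges = {g: build_reference_range(row, g) for g, row in sim.normals.iterrows()}
for s in sim.cohort.samples.values():
    call_sample(s, ranges)
cn, states, clin = cohort_frames(sim.cohort)
print(survival_by_copy_state(states, clin, "TP53", "loss_vs_not").dfs_hr)
```

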