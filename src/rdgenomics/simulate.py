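"""Synthetic cohort generator.

Emulates the data structure of a post-neoadjuvant TNBC trial correlative
so that every analysis stage is testable without external data: per-gene
copy numbers over the 70-locus panel mixed with normal contamination at
(1 - purity), TP53/PIK3CA point mutations with purity-diluted VAFs and
optional LOH skew, normal-genome reference tables, proportional-hazards
survival keyed to the true TP53 risk stratum and any planted screen
locus, matched diagnosis/surgery pairs with optional planted evolution
events, an expression matrix with a global multiplicative up-shift in
compound-TP53 samples, and slide-level lymphocyte percentages with a
planted post-chemotherapy depletion.

Default event frequencies are the cohort's: TP53 mutation 88%, PIK3CA
11%, TP53 copy loss 29%, MYC amplification 24%, MCL1 21%, GATA3 11%,
BRCA2 loss 68%, SMAD4-region gain 37%, purity 0.60-1.00.

Ground-truth labels are emitted alongside the tables (under a separate
``truth/`` directory on disk) and never feed the analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    ClinicalRecord,
    Cohort,
    CopyNumberProfile,
    ExpressionMatrix,
    RiskStratum,
    Timepoint,
    TumorSample,
    VariantCall,
    VariantClassification,
    write_cohort,
)
from .panel import PANEL_CYTOBANDS, PANEL_GENES, REGION_18Q21


class ConfigError(ValueError):
    """Inconsistent or out-of-range generator configuration."""


@dataclass
class ScreenLocusSpec:
    """A planted screen locus: gains at ``gain_freq`` carrying a
    proportional-hazards multiplier ``hazard`` on recurrence."""

    gene: str = "SMAD4"
    gain_freq: float = 0.37
    hazard: float = 2.3


@dataclass
class PairSpec:
    """Planted evolution events for one matched diagnosis/surgery pair."""

    acquired: list = field(default_factory=list)   # variant genes, post only
    lost: list = field(default_factory=list)       # variant genes, pre only
    amp_evolution: list = field(default_factory=list)   # genes amplified post only
    amp_extinction: list = field(default_factory=list)  # genes amplified pre only


@dataclass
class CohortConfig:
    n_patients: int = 75
    seed: int = 0
    n_normals: int = 24
    n_pairs: int = 18

    # mutation model
    mutation_freqs: dict = field(
        default_factory=lambda: {"TP53": 0.88, "PIK3CA": 0.11})
    tp53_loh_freq: float = 0.40        # among clonally mutated patients
    tp53_subclonal_freq: float = 0.15  # among mutated patients

    # copy-number event model
    tp53_loss_freq: float = 0.29
    amp_freqs: dict = field(
        default_factory=lambda: {"MYC": 0.24, "MCL1": 0.21, "GATA3": 0.11})
    loss_freqs: dict = field(
        default_factory=lambda: {"BRCA2": 0.68, "FLT3": 0.55, "RB1": 0.50})
    gain_freqs: dict = field(default_factory=dict)
    arm_gain_freq: float = 0.50        # background gains on 1q / 8q / 10p
    extensive_loss_frac: float = 0.10  # fraction of losses below 0.5 copies

    purity_range: tuple = (0.60, 1.00)

    # survival model (months)
    baseline_hazard: float = math.log(2) / 48.0
    stratum_hazard: dict = field(
        default_factory=lambda: {"LOW": 1.0, "MODERATE": 1.5, "HIGH": 2.5})
    tp53_loss_hazard: float = 1.0      # extra multiplier for copy-loss carriers
    screen_locus: Optional[ScreenLocusSpec] = field(
        default_factory=ScreenLocusSpec)
    followup_range: tuple = (24.0, 72.0)
    post_recurrence_median: float = 18.0

    # expression model
    n_expression_genes: int = 600
    expression_sigma: float = 0.5          # log2 within-group sd
    expression_upshift: float = 1.5        # global, compound-TP53 samples
    region_gene_upshift: float = 2.0       # SMAD2 in region-gain samples
    myc_expression_amp_factor: float = 3.0
    timepoint_down_frac: float = 0.25      # genes depleted post-chemotherapy
    timepoint_down_factor: float = 0.6
    silent_gene_frac: float = 0.20

    # lymphocytes (percentage points)
    lymphocyte_mean: float = 20.0
    lymphocyte_sd: float = 10.0
    depletion_mean: float = -8.0
    depletion_sd: float = 10.0

    # clinical covariates
    age_mean: float = 52.0
    age_sd: float = 11.0
    node_positive_frac: float = 0.5
    rcb3_frac: float = 0.4

    # measurement noise; noise=False zeroes all of it for exact
    # end-to-end ground-truth recovery
    noise: bool = True
    cn_noise_sd: float = 0.10
    vaf_noise_sd: float = 0.02
    normal_cn_sd: float = 0.15
    het_vaf_mean: float = 0.485
    het_vaf_sd: float = 0.035

    pair_specs: Optional[list] = None  # list[PairSpec], one per matched pair

    def validate(self) -> None:
        freqs = {
            "tp53_loh_freq": self.tp53_loh_freq,
            "tp53_subclonal_freq": self.tp53_subclonal_freq,
            "tp53_loss_freq": self.tp53_loss_freq,
            "arm_gain_freq": self.arm_gain_freq,
            "extensive_loss_frac": self.extensive_loss_frac,
            **{f"mutation_freqs[{g}]": v for g, v in self.mutation_freqs.items()},
            **{f"amp_freqs[{g}]": v for g, v in self.amp_freqs.items()},
            **{f"loss_freqs[{g}]": v for g, v in self.loss_freqs.items()},
            **{f"gain_freqs[{g}]": v for g, v in self.gain_freqs.items()},
        }
        for name, v in freqs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if "TP53" not in self.mutation_freqs:
            raise ConfigError("mutation_freqs must include TP53")
        if self.tp53_loss_freq > self.mutation_freqs["TP53"] + 0.1:
            raise ConfigError(
                "TP53 compound-loss frequency grossly exceeds the mutation "
                "frequency; the strata would be inconsistent")
        hazards = {"baseline_hazard": self.baseline_hazard,
                   "tp53_loss_hazard": self.tp53_loss_hazard,
                   **{f"stratum_hazard[{k}]": v
                      for k, v in self.stratum_hazard.items()}}
        if self.screen_locus is not None:
            hazards["screen_locus.hazard"] = self.screen_locus.hazard
            if self.screen_locus.gene not in PANEL_GENES:
                raise ConfigError(
                    f"screen locus {self.screen_locus.gene!r} is not on the panel")
        for name, v in hazards.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must satisfy 0 < lo <= hi <= 1, got {self.purity_range}")
        if not (1 <= self.n_pairs <= self.n_patients) and self.n_pairs != 0:
            raise ConfigError("n_pairs must lie in [0, n_patients]")
        if self.n_normals < 2:
            raise ConfigError("need >= 2 normal genomes for reference ranges")
        if self.pair_specs is not None:
            if len(self.pair_specs) > self.n_pairs:
                raise ConfigError("more pair specs than matched pairs")
            for spec in self.pair_specs:
                for gene in (list(spec.acquired) + list(spec.lost)
                             + list(spec.amp_evolution) + list(spec.amp_extinction)):
                    if gene not in PANEL_GENES:
                        raise ConfigError(
                            f"pair spec references off-panel gene {gene!r}")


_ARM_GAIN_PREFIXES = ("1q", "8q", "10p")

_TP53_CHANGES = ["p.R175H", "p.R248Q", "p.R273H", "p.Y220C", "p.R282W",
                 "p.G245S", "p.R213*", "p.R342*"]
_TP53_CLASSES = [VariantClassification.MISSENSE] * 6 + \
                [VariantClassification.NONSENSE] * 2
_PIK3CA_CHANGES = ["p.H1047R", "p.E545K", "p.E542K"]


@dataclass
class SimulatedCohort:
    cohort: Cohort
    normals: pd.DataFrame          # genes x normal genomes, copy number
    het_vafs: np.ndarray           # TP53 SNP heterozygous VAFs from normals
    expression: ExpressionMatrix
    truth: pd.DataFrame            # per-patient ground truth
    pair_truth: pd.DataFrame       # per-pair planted evolution counts
    config: CohortConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = write_cohort(self.cohort, outdir)
        normals_path = outdir / "normals.tsv"
        self.normals.to_csv(normals_path, sep="\t", index_label="gene")
        paths["normals"] = normals_path
        het_path = outdir / "tp53_het_vafs.tsv"
        pd.DataFrame({"vaf": self.het_vafs}).to_csv(het_path, sep="\t", index=False)
        paths["het_vafs"] = het_path
        expr_path = outdir / "expression.tsv"
        self.expression.to_tsv(expr_path)
        paths["expression"] = expr_path
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.to_csv(truth_dir / "patients.tsv", sep="\t", index=False)
        self.pair_truth.to_csv(truth_dir / "pairs.tsv", sep="\t", index=False)
        return paths


def _true_stratum(has_mut: bool, subclonal: bool, loh: bool, loss: bool) -> RiskStratum:
    if not has_mut:
        return RiskStratum.LOW
    if loh or loss:
        return RiskStratum.HIGH
    if subclonal:
        return RiskStratum.LOW
    return RiskStratum.MODERATE


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort; same config (seed included) gives a
    byte-identical cohort."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_gen = np.random.default_rng(streams[0])    # genomes
    rng_surv = np.random.default_rng(streams[1])   # survival
    rng_expr = np.random.default_rng(streams[2])   # expression
    rng_norm = np.random.default_rng(streams[3])   # normal genomes
    rng_clin = np.random.default_rng(streams[4])   # covariates / lymphocytes
    rng_obs = np.random.default_rng(streams[5])    # measurement noise

    noise = config.noise
    cn_noise = config.cn_noise_sd if noise else 0.0
    vaf_noise = config.vaf_noise_sd if noise else 0.0

    n = config.n_patients
    pids = [f"P{i + 1:03d}" for i in range(n)]
    paired = set(pids[:config.n_pairs])

    # --- normal genomes and het SNPs -----------------------------------
    normal_sd = config.normal_cn_sd if noise else 0.0
    normals = pd.DataFrame(
        rng_norm.normal(2.0, normal_sd, size=(len(PANEL_GENES), config.n_normals))
        if noise else np.full((len(PANEL_GENES), config.n_normals), 2.0),
        index=PANEL_GENES,
        columns=[f"N{j + 1:03d}" for j in range(config.n_normals)],
    ).clip(lower=0.0)
    het_sd = config.het_vaf_sd if noise else 0.0
    het_vafs = np.clip(
        rng_norm.normal(config.het_vaf_mean, het_sd, size=3 * config.n_normals),
        0.0, 1.0)

    # --- per-patient genomic truth -------------------------------------
    purity = rng_gen.uniform(*config.purity_range, size=n)
    truth_rows = []
    true_cn: dict[str, dict[str, float]] = {}
    true_variants: dict[str, list[VariantCall]] = {}

    for i, pid in enumerate(pids):
        has_mut = rng_gen.random() < config.mutation_freqs["TP53"]
        subclonal = has_mut and rng_gen.random() < config.tp53_subclonal_freq
        loh = (has_mut and not subclonal
               and rng_gen.random() < config.tp53_loh_freq)
        copy_loss = rng_gen.random() < config.tp53_loss_freq

        variants: list[VariantCall] = []
        tvaf = np.nan
        if has_mut:
            if subclonal:
                tvaf = rng_gen.uniform(0.05, 0.20)
            elif loh:
                tvaf = rng_gen.uniform(0.65, 0.95)
            else:
                tvaf = rng_gen.uniform(0.30, 0.55)
            k = rng_gen.integers(len(_TP53_CHANGES))
            variants.append(VariantCall("TP53", _TP53_CHANGES[k],
                                        _TP53_CLASSES[k], 0.0))
            variants[-1]._true_vaf = tvaf  # stashed; observed set later
        if rng_gen.random() < config.mutation_freqs.get("PIK3CA", 0.0):
            v = VariantCall("PIK3CA",
                            _PIK3CA_CHANGES[rng_gen.integers(len(_PIK3CA_CHANGES))],
                            VariantClassification.MISSENSE, 0.0)
            v._true_vaf = rng_gen.uniform(0.20, 0.50)
            variants.append(v)

        cn_map: dict[str, float] = {}
        screen_gain = False
        myc_amp = False
        gain_freqs = dict(config.gain_freqs)
        if config.screen_locus is not None:
            gain_freqs.setdefault(config.screen_locus.gene,
                                  config.screen_locus.gain_freq)
        for gene in PANEL_GENES:
            cn = 2.0
            band = PANEL_CYTOBANDS[gene]
            if gene in config.amp_freqs and rng_gen.random() < config.amp_freqs[gene]:
                cn = rng_gen.uniform(5.2, 8.0)
                if gene == "MYC":
                    myc_amp = True
            elif gene in gain_freqs and rng_gen.random() < gain_freqs[gene]:
                cn = rng_gen.uniform(2.8, 4.5)
                if (config.screen_locus is not None
                        and gene == config.screen_locus.gene):
                    screen_gain = True
            elif any(band.startswith(p) for p in _ARM_GAIN_PREFIXES) \
                    and rng_gen.random() < config.arm_gain_freq:
                cn = rng_gen.uniform(2.8, 4.2)
            elif gene == "TP53":
                if copy_loss:
                    cn = rng_gen.uniform(0.8, 1.3)
            elif gene in config.loss_freqs and rng_gen.random() < config.loss_freqs[gene]:
                if rng_gen.random() < config.extensive_loss_frac:
                    cn = rng_gen.uniform(0.15, 0.45)
                else:
                    cn = rng_gen.uniform(0.7, 1.3)
            cn_map[gene] = cn
        # TP53 sits on 17p, outside the arm-gain prefixes, but guard the
        # planted loss against any gain/amp override above
        if copy_loss:
            cn_map["TP53"] = min(cn_map["TP53"], rng_gen.uniform(0.8, 1.3))

        true_cn[pid] = cn_map
        true_variants[pid] = variants
        stratum = _true_stratum(has_mut, subclonal, loh, copy_loss)
        truth_rows.append({
            "patient_id": pid,
            "purity": purity[i],
            "tp53_mutation": has_mut,
            "tp53_true_vaf": tvaf,
            "tp53_subclonal": subclonal,
            "tp53_loh": loh,
            "tp53_copy_loss": copy_loss,
            "stratum": stratum.value,
            "compound": stratum is RiskStratum.HIGH,
            "myc_amp": myc_amp,
            "screen_gain": screen_gain,
            "paired": pid in paired,
        })

    truth = pd.DataFrame(truth_rows)

    # --- survival ------------------------------------------------------
    mult = truth["stratum"].map(config.stratum_hazard).to_numpy(dtype=float)
    mult = mult * np.where(truth["tp53_copy_loss"], config.tp53_loss_hazard, 1.0)
    if config.screen_locus is not None:
        mult = mult * np.where(truth["screen_gain"], config.screen_locus.hazard, 1.0)
    hazard = config.baseline_hazard * mult
    event_t = rng_surv.exponential(1.0 / hazard)
    censor_t = rng_surv.uniform(*config.followup_range, size=n)
    dfs_time = np.minimum(event_t, censor_t)
    dfs_event = event_t <= censor_t
    post_rec = rng_surv.exponential(
        config.post_recurrence_median / math.log(2), size=n)
    os_raw = np.where(dfs_event, event_t + post_rec, np.inf)
    os_time = np.minimum(os_raw, censor_t)
    os_event = os_raw <= censor_t
    truth["dfs_hazard_multiplier"] = mult

    age = rng_clin.normal(config.age_mean, config.age_sd, size=n).clip(25, 90)
    node = rng_clin.random(n) < config.node_positive_frac
    rcb3 = rng_clin.random(n) < config.rcb3_frac

    lymph_pre = rng_clin.normal(config.lymphocyte_mean, config.lymphocyte_sd,
                                size=n).clip(0.5, 80.0)
    lymph_post = (lymph_pre + rng_clin.normal(config.depletion_mean,
                                              config.depletion_sd, size=n)
                  ).clip(0.0, 100.0)

    # --- assemble cohort with observation noise ------------------------
    cohort = Cohort()
    pair_specs = list(config.pair_specs or [])
    pair_truth_rows = []

    def observe_sample(pid: str, i: int, tp: Timepoint,
                       cn_map: dict[str, float],
                       variants: list[VariantCall],
                       lymph: Optional[float]) -> TumorSample:
        p = purity[i]
        obs_cn = {}
        for gene, cn in cn_map.items():
            mixed = cn * p + 2.0 * (1.0 - p)
            obs_cn[gene] = max(mixed + (rng_obs.normal(0.0, cn_noise)
                                        if cn_noise else 0.0), 0.0)
        obs_variants = []
        for v in variants:
            obs_vaf = v._true_vaf * p
            if vaf_noise:
                obs_vaf += rng_obs.normal(0.0, vaf_noise)
            obs_variants.append(VariantCall(
                v.gene, v.protein_change, v.variant_class,
                float(np.clip(obs_vaf, 0.0, 1.0))))
        return TumorSample(
            patient_id=pid, timepoint=tp, purity=float(p),
            variants=obs_variants, cn=CopyNumberProfile(obs_cn),
            lymphocyte_pct=None if lymph is None else float(lymph))

    region_gain_patients = set()
    for i, pid in enumerate(pids):
        post_cn = dict(true_cn[pid])
        post_vars = list(true_variants[pid])
        if post_cn.get("SMAD4", 2.0) > 2.5:
            region_gain_patients.add(pid)

        if pid in paired:
            pre_cn = dict(true_cn[pid])
            pre_vars = list(true_variants[pid])
            j = pids.index(pid)
            spec = pair_specs[j] if j < len(pair_specs) else PairSpec()
            for gene in spec.acquired:
                v = VariantCall(gene, f"p.A{100 + j}V",
                                VariantClassification.MISSENSE, 0.0)
                v._true_vaf = 0.40
                post_vars = post_vars + [v]
            for gene in spec.lost:
                v = VariantCall(gene, f"p.G{200 + j}R",
                                VariantClassification.MISSENSE, 0.0)
                v._true_vaf = 0.40
                pre_vars = pre_vars + [v]
            for gene in spec.amp_evolution:
                pre_cn[gene] = 2.0
                post_cn[gene] = 6.0
            for gene in spec.amp_extinction:
                pre_cn[gene] = 6.0
                post_cn[gene] = 2.0
            cohort.add_sample(observe_sample(
                pid, i, Timepoint.DIAGNOSIS, pre_cn, pre_vars, lymph_pre[i]))
            pair_truth_rows.append({
                "patient_id": pid,
                "n_acquired": len(spec.acquired),
                "n_lost": len(spec.lost),
                "n_amp_evolution": len(spec.amp_evolution),
                "n_amp_extinction": len(spec.amp_extinction),
            })

        cohort.add_sample(observe_sample(
            pid, i, Timepoint.SURGERY, post_cn, post_vars, lymph_post[i]))
        cohort.clinical[pid] = ClinicalRecord(
            patient_id=pid,
            dfs_months=float(dfs_time[i]), dfs_event=bool(dfs_event[i]),
            os_months=float(os_time[i]), os_event=bool(os_event[i]),
            recurred=bool(dfs_event[i]), age=float(age[i]),
            node_positive=bool(node[i]),
            rcb_class="III" if rcb3[i] else "I_II")

    pair_truth = pd.DataFrame(
        pair_truth_rows,
        columns=["patient_id", "n_acquired", "n_lost",
                 "n_amp_evolution", "n_amp_extinction"])

    expression = _generate_expression(config, rng_expr, pids, paired, truth,
                                      region_gain_patients)
    truth["region_gain"] = truth["patient_id"].isin(region_gain_patients)

    return SimulatedCohort(
        cohort=cohort, normals=normals, het_vafs=het_vafs,
        expression=expression, truth=truth, pair_truth=pair_truth,
        config=config)


def _generate_expression(config: CohortConfig, rng: np.random.Generator,
                         pids: list, paired: set, truth: pd.DataFrame,
                         region_gain: set) -> ExpressionMatrix:
    """Log-normal RPKM matrix over panel + 18q21 + synthetic filler
    genes, with the planted group effects multiplied in."""
    genes = list(PANEL_GENES)
    meta_rows = {g: {"cytoband": PANEL_CYTOBANDS[g], "coding": True}
                 for g in genes}
    for g, (band, coding) in REGION_18Q21.items():
        if g not in meta_rows:
            genes.append(g)
            meta_rows[g] = {"cytoband": band, "coding": coding}
    n_filler = max(config.n_expression_genes - len(genes), 0)
    filler_bands = ["2q31.1", "3p21.3", "5q31.2", "7q22.1", "9q33.1",
                    "11q13.1", "12q24.1", "14q22.2", "16p12.1", "19q13.1"]
    for k in range(n_filler):
        g = f"SYN{k + 1:04d}"  # synthetic filler gene, no genomic meaning
        genes.append(g)
        meta_rows[g] = {"cytoband": filler_bands[k % len(filler_bands)],
                        "coding": True}
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta["length_bp"] = np.maximum(
        rng.lognormal(7.8, 0.6, size=len(genes)).astype(int), 200)

    samples, sample_pid, sample_tp = [], [], []
    for pid in pids:
        if pid in paired:
            samples.append(f"{pid}@DIAGNOSIS")
            sample_pid.append(pid)
            sample_tp.append("DIAGNOSIS")
        samples.append(f"{pid}@SURGERY")
        sample_pid.append(pid)
        sample_tp.append("SURGERY")

    base = rng.normal(4.0, 1.5, size=len(genes))          # log2 means
    silent = np.zeros(len(genes), dtype=bool)
    filler_mask = np.array([g.startswith("SYN") for g in genes])
    silent[filler_mask] = rng.random(filler_mask.sum()) < config.silent_gene_frac
    down_post = np.zeros(len(genes), dtype=bool)
    down_post[filler_mask] = rng.random(filler_mask.sum()) < config.timepoint_down_frac

    compound = set(truth.loc[truth["compound"], "patient_id"])
    myc_amp = set(truth.loc[truth["myc_amp"], "patient_id"])

    log2 = np.empty((len(genes), len(samples)))
    for j, (sid, pid, tp) in enumerate(zip(samples, sample_pid, sample_tp)):
        col = base + rng.normal(0.0, config.expression_sigma, size=len(genes))
        if pid in compound:
            col = col + math.log2(config.expression_upshift)
        if tp == "SURGERY":
            col = col + np.where(down_post,
                                 math.log2(config.timepoint_down_factor), 0.0)
        log2[:, j] = col

    values = np.power(2.0, log2)
    values[silent, :] = 0.0
    df = pd.DataFrame(values, index=genes, columns=samples)
    if "SMAD2" in df.index:
        gain_cols = [s for s, pid in zip(samples, sample_pid) if pid in region_gain]
        df.loc["SMAD2", gain_cols] *= config.region_gene_upshift
    if "MYC" in df.index:
        amp_cols = [s for s, pid in zip(samples, sample_pid) if pid in myc_amp]
        df.loc["MYC", amp_cols] *= config.myc_expression_amp_factor

    groups = pd.Series(sample_tp, index=samples, name="timepoint")
    return ExpressionMatrix(df, meta, is_counts=False, groups=groups)


def generate_matched_pairs(config: CohortConfig, n_pairs: int,
                           evolution_spec: Optional[list] = None
                           ) -> SimulatedCohort:
    """Cohort of fully matched pairs with planted acquisition and
    amplification evolution/extinction events (truth emitted alongside)."""
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    cfg_dict = asdict(config)
    # asdict flattens nested dataclasses; rebuild the typed fields
    cfg_dict["screen_locus"] = config.screen_locus
    cfg_dict["pair_specs"] = list(evolution_spec or [])
    cfg_dict["n_patients"] = n_pairs
    cfg_dict["n_pairs"] = n_pairs
    cfg = CohortConfig(**cfg_dict)
    return generate_cohort(cfg)


def expression_sample_groups(em: ExpressionMatrix,
                             timepoint: str = "SURGERY") -> pd.Series:
    """Map the matrix's per-timepoint columns back to patient ids,
    restricted to one timepoint."""
    cols = [c for c in em.samples if c.endswith(f"@{timepoint}")]
    return pd.Series({c: c.split("@")[0] for c in cols})
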