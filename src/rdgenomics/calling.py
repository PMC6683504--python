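"""Copy-number state calling, purity correction, LOH detection, and
matched-pair evolution summaries.

States are called against per-assay reference ranges built from normal
(leukocyte-derived) genomes as mean +/- k*SD with k = 3 by default; the
wide band absorbs noise from formalin-fixed input. Copy number above 4.99
is amplified regardless of the range — a deliberately conservative
threshold — and corrected copy number below 0.5 is extensive loss.
Reference-range bounds are inclusive: a value equal to a bound is normal.

Purity corrections assume a two-component mixture of tumor cells at
fraction ``purity`` with diploid, non-mutated normal cells:

    VAF_tumor = min(VAF_obs / purity, 1)
    CN_tumor  = max((CN_obs - 2 * (1 - purity)) / purity, 0)

LOH is operationalized as upward skew of the corrected VAF beyond the
upper bound of the normal heterozygosity range (38–59% by default);
downward skew instead marks subclonality, which the risk stratification
handles separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    CopyState,
    ReferenceRange,
    Timepoint,
    TumorSample,
    ValidationError,
    VariantCall,
)

AMPLIFICATION_THRESHOLD = 4.99
EXTENSIVE_LOSS_THRESHOLD = 0.5

#: Printed normal heterozygosity range for TP53 SNPs, used when no normal
#: SNP table is supplied to rebuild it.
DEFAULT_HET_RANGE = ReferenceRange(assay_id="TP53_het", mean=0.485, sd=0.035, k=3.0)


class InsufficientDataError(ValueError):
    """Too few normal observations to build a reference range."""


class CoverageError(KeyError):
    """A panel gene has no reference range."""


class PairingError(ValueError):
    """Matched-pair comparison given samples from different patients or
    the wrong timepoints."""


def build_reference_range(normal_values, assay_id: str = "", k: float = 3.0
                          ) -> ReferenceRange:
    """Reference interval mean +/- k * sample SD from normal genomes.

    The sample standard deviation (n-1 denominator) is used because
    normal cohorts are small.
    """
    values = np.asarray(list(normal_values), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 normal values to build a reference range, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("normal values must all be finite")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return ReferenceRange(assay_id=assay_id, mean=mean, sd=sd, k=k)


def call_copy_state(
    copy_number: float,
    rng: ReferenceRange,
    amp_threshold: float = AMPLIFICATION_THRESHOLD,
    extensive_loss_threshold: float = EXTENSIVE_LOSS_THRESHOLD,
) -> CopyState:
    """Assign the five-level copy state for one locus.

    Precedence: amplification (strictly > ``amp_threshold``) first, then
    gain above the reference range, extensive loss below the hard floor,
    range-based loss, and otherwise normal.
    """
    if not math.isfinite(copy_number) or copy_number < 0:
        raise ValidationError(f"copy number must be finite and >= 0, got {copy_number}")
    if copy_number > amp_threshold:
        return CopyState.AMPLIFIED
    if copy_number > rng.upper:
        return CopyState.GAIN
    if copy_number < extensive_loss_threshold:
        return CopyState.EXTENSIVE_LOSS
    if copy_number < rng.lower:
        return CopyState.LOSS
    return CopyState.NORMAL


def correct_vaf_for_purity(vaf: float, purity: float) -> float:
    if not (0.0 <= vaf <= 1.0):
        raise ValidationError(f"vaf must lie in [0, 1], got {vaf}")
    if not (0.0 < purity <= 1.0):
        raise ValidationError(f"purity must lie in (0, 1], got {purity}")
    return min(vaf / purity, 1.0)


def correct_cn_for_purity(cn_observed: float, purity: float) -> float:
    if not math.isfinite(cn_observed) or cn_observed < 0:
        raise ValidationError(f"copy number must be finite and >= 0, got {cn_observed}")
    if not (0.0 < purity <= 1.0):
        raise ValidationError(f"purity must lie in (0, 1], got {purity}")
    return max((cn_observed - 2.0 * (1.0 - purity)) / purity, 0.0)


def detect_loh(vaf_corrected: float, het_range: ReferenceRange = DEFAULT_HET_RANGE
               ) -> bool:
    """Allele-frequency skew above the normal heterozygosity range.

    The upper bound is inclusive: a VAF exactly at the bound is still
    within normal heterozygosity.
    """
    if not (0.0 <= vaf_corrected <= 1.0):
        raise ValidationError(f"vaf must lie in [0, 1], got {vaf_corrected}")
    return vaf_corrected > het_range.upper


def call_sample(
    sample: TumorSample,
    cn_ranges: dict[str, ReferenceRange],
    het_range: ReferenceRange = DEFAULT_HET_RANGE,
    amp_threshold: float = AMPLIFICATION_THRESHOLD,
    extensive_loss_threshold: float = EXTENSIVE_LOSS_THRESHOLD,
) -> TumorSample:
    """Purity-correct and call one sample in place; returns the sample.

    Every panel gene gets a corrected copy number and a state; every
    variant gets ``vaf_corrected``. States are called on corrected copy
    numbers so a heavily contaminated loss still registers.
    """
    missing = [g for g in sample.cn.copy_number if g not in cn_ranges]
    if missing:
        raise CoverageError(
            f"no reference range for panel gene(s): {', '.join(sorted(missing))}")
    corrected: dict[str, float] = {}
    states: dict[str, CopyState] = {}
    for gene, cn in sample.cn.copy_number.items():
        c = correct_cn_for_purity(cn, sample.purity)
        corrected[gene] = c
        states[gene] = call_copy_state(
            c, cn_ranges[gene], amp_threshold=amp_threshold,
            extensive_loss_threshold=extensive_loss_threshold)
    sample.cn.corrected = corrected
    sample.cn.states = states
    for v in sample.variants:
        v.vaf_corrected = correct_vaf_for_purity(v.vaf_observed, sample.purity)
    return sample


def tp53_loh_flags(sample: TumorSample,
                   het_range: ReferenceRange = DEFAULT_HET_RANGE) -> list[bool]:
    """Per-TP53-variant LOH flags for a called sample."""
    flags = []
    for v in sample.variants:
        if v.gene == "TP53":
            if v.vaf_corrected is None:
                raise ValidationError("sample must be called before LOH flagging")
            flags.append(detect_loh(v.vaf_corrected, het_range))
    return flags


@dataclass
class PairEvolution:
    """Summary of genomic change between a patient's diagnosis and
    surgery samples."""

    patient_id: str
    acquired: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    state_transitions: dict = field(default_factory=dict)  # gene -> (pre, post)
    n_amp_evolution: int = 0
    n_amp_extinction: int = 0

    @property
    def identical_mutation_profile(self) -> bool:
        return not self.acquired and not self.lost


def compare_matched_pair(pre: TumorSample, post: TumorSample) -> PairEvolution:
    """Acquired/lost variants and copy-state transitions between the
    pre-treatment and residual-disease samples of one patient.

    Variant identity is (gene, protein_change) when the protein change is
    recorded, else (gene, variant class). Amplification evolution counts
    genes moving into the amplified state; extinction counts genes
    leaving it.
    """
    if pre.patient_id != post.patient_id:
        raise PairingError(
            f"samples from different patients: {pre.patient_id!r} vs {post.patient_id!r}")
    if pre.timepoint is not Timepoint.DIAGNOSIS or post.timepoint is not Timepoint.SURGERY:
        raise PairingError("expected a (DIAGNOSIS, SURGERY) pair in that order")
    if not (pre.cn.called and post.cn.called):
        raise ValidationError("both samples must be called before pair comparison")

    pre_keys = {v.key for v in pre.variants}
    post_keys = {v.key for v in post.variants}
    ev = PairEvolution(
        patient_id=pre.patient_id,
        acquired=post_keys - pre_keys,
        lost=pre_keys - post_keys,
    )
    shared_genes = sorted(set(pre.cn.states) & set(post.cn.states))
    for gene in shared_genes:
        s_pre, s_post = pre.cn.states[gene], post.cn.states[gene]
        if s_pre is not s_post:
            ev.state_transitions[gene] = (s_pre, s_post)
        if s_post is CopyState.AMPLIFIED and s_pre is not CopyState.AMPLIFIED:
            ev.n_amp_evolution += 1
        if s_pre is CopyState.AMPLIFIED and s_post is not CopyState.AMPLIFIED:
            ev.n_amp_extinction += 1
    return ev


def variant_key(v: VariantCall) -> tuple:
    return v.key
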