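"""Graduated TP53 inactivation risk stratification.

TP53 disruption in triple-negative breast cancer spans a continuum: no
mutation, a subclonal point mutation, a clonal mutation, or a mutation
compounded by a second inactivating event (loss of heterozygosity or
17p/TP53 copy loss). Patients are collapsed across timepoints into one
evidence record and assigned one of three risk strata:

  LOW       no mutation, or only a subclonal mutation (corrected VAF
            below the 25% cutoff) without any compounding event;
  HIGH      a mutation plus LOH or copy loss ("compound" TP53 mutation);
  MODERATE  everything else (a clonal mutation standing alone).

A subclonal VAF co-occurring with copy loss still classifies HIGH: copy
loss itself depresses the VAF, so treating such patients as low-risk
would contradict the compounding logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .calling import DEFAULT_HET_RANGE, detect_loh
from .datamodel import (
    CopyState,
    ReferenceRange,
    RiskStratum,
    Timepoint,
    TumorSample,
    ValidationError,
)

SUBCLONAL_CUTOFF = 0.25
TP53 = "TP53"


class NoIncludedSamplesError(ValueError):
    """Patient has no sample passing the cellularity gate; an exclusion
    marker, not a stratum."""


@dataclass
class TP53Evidence:
    patient_id: str
    has_mutation: bool
    max_vaf_corrected: Optional[float]
    loh: bool
    copy_loss: bool
    subclonal_only: bool

    def __post_init__(self) -> None:
        if self.subclonal_only and not self.has_mutation:
            raise ValidationError("subclonal_only implies has_mutation")
        if self.has_mutation and self.max_vaf_corrected is None:
            raise ValidationError("a mutation requires a corrected VAF")


def collapse_patient_tp53(
    samples: Iterable[TumorSample],
    het_range: ReferenceRange = DEFAULT_HET_RANGE,
    subclonal_cutoff: float = SUBCLONAL_CUTOFF,
) -> TP53Evidence:
    """Aggregate a patient's called samples into one TP53 evidence record.

    Mutations union across timepoints (TP53 calls are stable between
    them) and the maximum corrected VAF is kept. Copy-number-derived
    evidence (copy loss, and the LOH flag) is taken from the surgery
    (residual-disease) sample when both timepoints exist, because the
    analyses concern residual disease; a pre-only patient falls back to
    the diagnosis sample.
    """
    samples = [s for s in samples if s.included]
    if not samples:
        raise NoIncludedSamplesError("no sample passes the cellularity gate")
    pids = {s.patient_id for s in samples}
    if len(pids) != 1:
        raise ValidationError(f"samples from multiple patients: {sorted(pids)}")
    for s in samples:
        if not s.cn.called:
            raise ValidationError("samples must be called before collapsing")

    by_tp = {s.timepoint: s for s in samples}
    preferred = by_tp.get(Timepoint.SURGERY, by_tp.get(Timepoint.DIAGNOSIS))

    tp53_vafs = [
        v.vaf_corrected
        for s in samples
        for v in s.variants
        if v.gene == TP53 and v.vaf_corrected is not None
    ]
    has_mutation = bool(tp53_vafs)
    max_vaf = max(tp53_vafs) if tp53_vafs else None

    copy_loss = (TP53 in preferred.cn.states
                 and preferred.cn.states[TP53] < CopyState.NORMAL)
    pref_vafs = [v.vaf_corrected for v in preferred.variants
                 if v.gene == TP53 and v.vaf_corrected is not None]
    loh = any(detect_loh(v, het_range) for v in pref_vafs)

    subclonal_only = has_mutation and max_vaf < subclonal_cutoff
    return TP53Evidence(
        patient_id=samples[0].patient_id,
        has_mutation=has_mutation,
        max_vaf_corrected=max_vaf,
        loh=loh,
        copy_loss=copy_loss,
        subclonal_only=subclonal_only,
    )


def classify_tp53(ev: TP53Evidence,
                  subclonal_cutoff: float = SUBCLONAL_CUTOFF) -> RiskStratum:
    """Assign the three-tier stratum from complete evidence."""
    if not ev.has_mutation:
        return RiskStratum.LOW
    if ev.loh or ev.copy_loss:
        return RiskStratum.HIGH
    if ev.max_vaf_corrected < subclonal_cutoff:
        return RiskStratum.LOW
    return RiskStratum.MODERATE


def compound_flag(stratum: RiskStratum) -> bool:
    """Compound TP53 mutation: a point mutation plus a second
    inactivating event, i.e. exactly the HIGH stratum."""
    return stratum is RiskStratum.HIGH


@dataclass
class OverlapCounts:
    a_only: int
    b_only: int
    intersection: int
    union: int
    intersection_pct_of_union: int


def overlap_counts(set_a: Iterable, set_b: Iterable) -> OverlapCounts:
    """Venn counts for two patient sets with the intersection expressed
    as an integer percentage of the union."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    union = len(a | b)
    pct = int(round(100.0 * inter / union)) if union else 0
    return OverlapCounts(
        a_only=len(a - b),
        b_only=len(b - a),
        intersection=inter,
        union=union,
        intersection_pct_of_union=pct,
    )
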