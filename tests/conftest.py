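import numpy as np
import pandas as pd
import pytest

from rdgenomics.calling import build_reference_range, call_sample
from rdgenomics.datamodel import (
    CopyNumberProfile,
    ReferenceRange,
    Timepoint,
    TumorSample,
    VariantCall,
    VariantClassification,
)


@pytest.fixture
def diploid_range() -> ReferenceRange:
    """The worked reference range: normals [1.8, 2.0, 2.2], k=3."""
    return build_reference_range([1.8, 2.0, 2.2], assay_id="gene", k=3.0)


@pytest.fixture
def het_range() -> ReferenceRange:
    """Normal TP53 heterozygosity band [0.38, 0.59]."""
    return ReferenceRange("TP53_het", mean=0.485, sd=0.035, k=3.0)


def make_sample(
    patient_id: str = "P001",
    timepoint: Timepoint = Timepoint.SURGERY,
    purity: float = 1.0,
    cn: dict | None = None,
    variants: list | None = None,
    lymphocyte_pct: float | None = None,
) -> TumorSample:
    return TumorSample(
        patient_id=patient_id,
        timepoint=timepoint,
        purity=purity,
        variants=variants or [],
        cn=CopyNumberProfile(dict(cn or {})),
        lymphocyte_pct=lymphocyte_pct,
    )


def tp53_variant(vaf: float, protein_change: str = "p.R175H") -> VariantCall:
    return VariantCall("TP53", protein_change,
                       VariantClassification.MISSENSE, vaf)


@pytest.fixture
def ranges_2genes() -> dict:
    rng = {"TP53": build_reference_range([1.8, 2.0, 2.2], "TP53"),
           "MYC": build_reference_range([1.8, 2.0, 2.2], "MYC")}
    return rng


def call_simple(sample: TumorSample, ranges: dict) -> TumorSample:
    missing = {g: build_reference_range([1.8, 2.0, 2.2], g)
               for g in sample.cn.copy_number if g not in ranges}
    return call_sample(sample, {**ranges, **missing})


@pytest.fixture
def small_clinical() -> pd.DataFrame:
    """Six patients, deterministic survival times."""
    return pd.DataFrame({
        "dfs_months": [3.0, 6.0, 9.0, 12.0, 24.0, 36.0],
        "dfs_event": [True, True, True, False, True, False],
        "os_months": [5.0, 8.0, 12.0, 12.0, 30.0, 36.0],
        "os_event": [True, True, True, False, True, False],
        "recurred": [True, True, True, False, True, False],
        "age": [50.0] * 6,
        "node_positive": [False] * 6,
        "rcb_class": ["I_II"] * 6,
    }, index=[f"P{i:03d}" for i in range(1, 7)])
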