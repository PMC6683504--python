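"""Domain types, validation, and tabular readers/writers.

The package's canonical interchange format is headered TSV: one table each
for variants, copy number, clinical records, and expression. Purity is a
fraction in (0, 1] internally; clinical tables carry it as a percentage and
it is converted on read. Samples below the 60% tumor-cellularity gate are
flagged as excluded rather than dropped, so pairing logic can still report
why a mate is missing.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

PURITY_INCLUSION_THRESHOLD = 0.60


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


class SchemaError(ValueError):
    """A required column is missing or a table is malformed."""


class UniquenessError(ValueError):
    """Duplicate (patient, timepoint) keys in a cohort table."""


class VariantClassification(enum.Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    INFRAME_INDEL = "INFRAME_INDEL"
    SPLICE = "SPLICE"
    OTHER = "OTHER"


class Timepoint(enum.Enum):
    DIAGNOSIS = "DIAGNOSIS"
    SURGERY = "SURGERY"


class CopyState(enum.Enum):
    """Ordered copy-number state; comparisons follow genomic dosage."""

    EXTENSIVE_LOSS = 0
    LOSS = 1
    NORMAL = 2
    GAIN = 3
    AMPLIFIED = 4

    def __lt__(self, other: "CopyState") -> bool:
        if not isinstance(other, CopyState):
            return NotImplemented
        return self.value < other.value

    def __le__(self, other: "CopyState") -> bool:
        if not isinstance(other, CopyState):
            return NotImplemented
        return self.value <= other.value

    def __gt__(self, other: "CopyState") -> bool:
        if not isinstance(other, CopyState):
            return NotImplemented
        return self.value > other.value

    def __ge__(self, other: "CopyState") -> bool:
        if not isinstance(other, CopyState):
            return NotImplemented
        return self.value >= other.value


class RiskStratum(enum.Enum):
    """Three-tier graduated TP53 inactivation risk class."""

    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass
class VariantCall:
    gene: str
    protein_change: Optional[str]
    variant_class: VariantClassification
    vaf_observed: float
    vaf_corrected: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("variant gene symbol must be non-empty")
        if not isinstance(self.variant_class, VariantClassification):
            raise ValidationError(
                f"variant_class must be a VariantClassification, got {self.variant_class!r}"
            )
        if not (0.0 <= self.vaf_observed <= 1.0):
            raise ValidationError(
                f"vaf_observed must lie in [0, 1], got {self.vaf_observed}"
            )
        if self.vaf_corrected is not None:
            if not (0.0 <= self.vaf_corrected <= 1.0):
                raise ValidationError(
                    f"vaf_corrected must lie in [0, 1], got {self.vaf_corrected}"
                )
            if self.vaf_corrected < self.vaf_observed - 1e-12:
                raise ValidationError(
                    "vaf_corrected cannot fall below vaf_observed for purity <= 1"
                )

    @property
    def key(self) -> tuple:
        """Identity for matched-pair comparison: (gene, protein change)
        when the protein change is known, else (gene, class)."""
        if self.protein_change:
            return (self.gene, self.protein_change)
        return (self.gene, self.variant_class.value)


@dataclass
class CopyNumberProfile:
    """Per-gene copy-number estimates, with corrected values and called
    states filled in by the calling step."""

    copy_number: dict[str, float]
    corrected: Optional[dict[str, float]] = None
    states: Optional[dict[str, CopyState]] = None

    def __post_init__(self) -> None:
        for gene, cn in self.copy_number.items():
            if not math.isfinite(cn) or cn < 0:
                raise ValidationError(
                    f"copy number for {gene} must be finite and >= 0, got {cn}"
                )

    @property
    def called(self) -> bool:
        return self.states is not None

    def state_of(self, gene: str) -> CopyState:
        if self.states is None:
            raise ValidationError("copy-number states requested before calling")
        return self.states[gene]


@dataclass
class TumorSample:
    patient_id: str
    timepoint: Timepoint
    purity: float
    variants: list[VariantCall] = field(default_factory=list)
    cn: CopyNumberProfile = field(default_factory=lambda: CopyNumberProfile({}))
    lymphocyte_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.timepoint, Timepoint):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(
                f"purity must be a fraction in (0, 1], got {self.purity}"
            )
        if self.lymphocyte_pct is not None and not (0.0 <= self.lymphocyte_pct <= 100.0):
            raise ValidationError(
                f"lymphocyte_pct must lie in [0, 100], got {self.lymphocyte_pct}"
            )

    @property
    def included(self) -> bool:
        """Whether the sample clears the 60% cellularity gate for
        molecular analyses."""
        return self.purity >= PURITY_INCLUSION_THRESHOLD


@dataclass
class ClinicalRecord:
    patient_id: str
    dfs_months: float
    dfs_event: bool
    os_months: float
    os_event: bool
    recurred: bool
    age: float
    node_positive: bool
    rcb_class: str  # "I_II" or "III"

    def __post_init__(self) -> None:
        if self.dfs_months < 0 or self.os_months < 0:
            raise ValidationError("survival times must be >= 0")
        if self.dfs_months > self.os_months + 1e-9:
            raise ValidationError(
                f"dfs_months ({self.dfs_months}) cannot exceed os_months ({self.os_months})"
            )
        if self.recurred and not self.dfs_event:
            raise ValidationError("recurred implies dfs_event")
        if self.rcb_class not in ("I_II", "III"):
            raise ValidationError(
                f"rcb_class must be 'I_II' or 'III', got {self.rcb_class!r}"
            )


@dataclass
class ReferenceRange:
    """Normal-derived interval mean +/- k*sd for one assay."""

    assay_id: str
    mean: float
    sd: float
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.k <= 0:
            raise ValidationError("k must be positive")
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise ValidationError("reference range parameters must be finite")

    @property
    def lower(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.k * self.sd

    def contains(self, value: float) -> bool:
        """Bounds are inclusive: values equal to a bound are within range."""
        return self.lower <= value <= self.upper


class ExpressionMatrix:
    """Genes x samples expression values with per-gene metadata.

    values : DataFrame, genes in rows, samples in columns, non-negative.
    meta   : DataFrame indexed like values with columns cytoband (str),
             coding (bool), length_bp (positive int).
    is_counts : True when the table holds raw read counts rather than RPKM.
    groups : optional per-sample labels (Series indexed by sample id).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        is_counts: bool = False,
        groups: Optional[pd.Series] = None,
    ):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValidationError("gene ids must be unique")
        if (values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = values.index.difference(meta.index)
        if len(missing):
            raise ValidationError(
                f"metadata missing for {len(missing)} genes, e.g. {missing[0]!r}"
            )
        for col in ("cytoband", "coding", "length_bp"):
            if col not in meta.columns:
                raise SchemaError(f"expression metadata missing column {col!r}")
        meta = meta.loc[values.index]
        if (meta["length_bp"] <= 0).any():
            raise ValidationError("gene lengths must be positive")
        self.values = values
        self.meta = meta.assign(coding=meta["coding"].astype(bool))
        self.is_counts = bool(is_counts)
        self.groups = groups

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        table = pd.concat([self.meta[["cytoband", "coding", "length_bp"]], self.values], axis=1)
        with open(path, "w") as fh:
            fh.write(f"# values: {'counts' if self.is_counts else 'rpkm'}\n")
            table.to_csv(fh, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        is_counts = False
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                is_counts = "counts" in first
            else:
                fh.seek(0)
            table = pd.read_csv(fh, sep="\t", index_col="gene")
        for col in ("cytoband", "coding", "length_bp"):
            if col not in table.columns:
                raise SchemaError(f"expression table missing column {col!r}")
        meta = table[["cytoband", "coding", "length_bp"]].copy()
        meta["coding"] = meta["coding"].astype(bool)
        meta["length_bp"] = meta["length_bp"].astype(int)
        values = table.drop(columns=["cytoband", "coding", "length_bp"])
        return cls(values, meta, is_counts=is_counts)


@dataclass
class Cohort:
    """In-memory cohort: tumor samples keyed by (patient, timepoint) plus
    per-patient clinical records."""

    samples: dict[tuple[str, Timepoint], TumorSample] = field(default_factory=dict)
    clinical: dict[str, ClinicalRecord] = field(default_factory=dict)

    def add_sample(self, sample: TumorSample) -> None:
        key = (sample.patient_id, sample.timepoint)
        if key in self.samples:
            raise UniquenessError(f"duplicate sample for {key}")
        self.samples[key] = sample

    @property
    def patients(self) -> list[str]:
        ids = {pid for pid, _ in self.samples} | set(self.clinical)
        return sorted(ids)

    def samples_of(self, patient_id: str, included_only: bool = False) -> list[TumorSample]:
        out = [s for (pid, _), s in self.samples.items() if pid == patient_id]
        if included_only:
            out = [s for s in out if s.included]
        return sorted(out, key=lambda s: s.timepoint.value)

    def get(self, patient_id: str, timepoint: Timepoint) -> Optional[TumorSample]:
        return self.samples.get((patient_id, timepoint))

    def matched_pairs(self) -> list[tuple[TumorSample, TumorSample]]:
        """All (diagnosis, surgery) pairs present for the same patient."""
        pairs = []
        for pid in self.patients:
            pre = self.get(pid, Timepoint.DIAGNOSIS)
            post = self.get(pid, Timepoint.SURGERY)
            if pre is not None and post is not None:
                pairs.append((pre, post))
        return pairs


@dataclass
class RowDiagnostic:
    table: str
    row: int
    message: str

    def __str__(self) -> str:
        return f"{self.table} row {self.row}: {self.message}"


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["patient_id", "timepoint", "gene", "protein_change", "variant_class", "vaf"]
CN_COLUMNS = ["patient_id", "timepoint", "gene", "copy_number"]
CLINICAL_COLUMNS = [
    "patient_id", "dfs_months", "dfs_event", "os_months", "os_event",
    "recurred", "age", "node_positive", "rcb_class", "purity_pct",
    "lymphocyte_pct_pre", "lymphocyte_pct_post",
]


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing required column(s): {', '.join(missing)}")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {value!r}")


def _parse_timepoint(value) -> Timepoint:
    s = str(value).strip().upper()
    try:
        return Timepoint[s]
    except KeyError:
        raise ValidationError(
            f"unknown timepoint label {value!r} (expected DIAGNOSIS or SURGERY)"
        ) from None


def read_cohort(
    variants_path: str | Path,
    cn_path: str | Path,
    clinical_path: str | Path,
) -> tuple[Cohort, list[RowDiagnostic]]:
    """Assemble a validated cohort from the three canonical tables.

    Rows that violate type invariants are rejected and reported in the
    returned diagnostics; structural problems (missing columns, duplicate
    sample keys) raise instead. Low-purity samples are constructed and
    flagged via ``TumorSample.included``, never silently dropped.
    """
    variants = pd.read_csv(variants_path, sep="\t", dtype={"patient_id": str},
                           float_precision="round_trip")
    cn = pd.read_csv(cn_path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    clinical = pd.read_csv(clinical_path, sep="\t", dtype={"patient_id": str},
                           float_precision="round_trip")
    _require_columns(variants, VARIANT_COLUMNS, "variants table")
    _require_columns(cn, CN_COLUMNS, "copy-number table")
    _require_columns(clinical, [c for c in CLINICAL_COLUMNS
                                if not c.startswith("lymphocyte")], "clinical table")

    diagnostics: list[RowDiagnostic] = []
    cohort = Cohort()

    purity: dict[str, float] = {}
    lymph: dict[tuple[str, Timepoint], float] = {}
    for i, row in clinical.iterrows():
        pid = str(row["patient_id"])
        try:
            rec = ClinicalRecord(
                patient_id=pid,
                dfs_months=float(row["dfs_months"]),
                dfs_event=_parse_bool(row["dfs_event"]),
                os_months=float(row["os_months"]),
                os_event=_parse_bool(row["os_event"]),
                recurred=_parse_bool(row["recurred"]),
                age=float(row["age"]),
                node_positive=_parse_bool(row["node_positive"]),
                rcb_class=str(row["rcb_class"]),
            )
        except (ValidationError, ValueError) as exc:
            diagnostics.append(RowDiagnostic("clinical", int(i), str(exc)))
            continue
        if pid in cohort.clinical:
            raise UniquenessError(f"duplicate clinical record for patient {pid}")
        cohort.clinical[pid] = rec
        p = float(row["purity_pct"]) / 100.0
        purity[pid] = p
        for col, tp in (("lymphocyte_pct_pre", Timepoint.DIAGNOSIS),
                        ("lymphocyte_pct_post", Timepoint.SURGERY)):
            if col in clinical.columns and pd.notna(row.get(col)):
                lymph[(pid, tp)] = float(row[col])

    # copy-number rows define the samples
    cn_by_sample: dict[tuple[str, Timepoint], dict[str, float]] = {}
    for i, row in cn.iterrows():
        pid = str(row["patient_id"])
        try:
            tp = _parse_timepoint(row["timepoint"])
            value = float(row["copy_number"])
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"copy number must be finite and >= 0, got {value}")
        except ValidationError as exc:
            diagnostics.append(RowDiagnostic("copynumber", int(i), str(exc)))
            continue
        key = (pid, tp)
        gene = str(row["gene"])
        if gene in cn_by_sample.get(key, {}):
            raise UniquenessError(
                f"duplicate copy-number entry for gene {gene} in sample {key}"
            )
        cn_by_sample.setdefault(key, {})[gene] = value

    variants_by_sample: dict[tuple[str, Timepoint], list[VariantCall]] = {}
    for i, row in variants.iterrows():
        pid = str(row["patient_id"])
        try:
            tp = _parse_timepoint(row["timepoint"])
            pc = row.get("protein_change")
            pc = None if pd.isna(pc) or str(pc) == "" else str(pc)
            call = VariantCall(
                gene=str(row["gene"]),
                protein_change=pc,
                variant_class=VariantClassification[str(row["variant_class"]).upper()],
                vaf_observed=float(row["vaf"]),
            )
        except (ValidationError, KeyError) as exc:
            msg = str(exc) if isinstance(exc, ValidationError) else f"unknown variant_class {exc}"
            diagnostics.append(RowDiagnostic("variants", int(i), msg))
            continue
        variants_by_sample.setdefault((pid, tp), []).append(call)

    sample_keys = set(cn_by_sample) | set(variants_by_sample)
    for key in sorted(sample_keys, key=lambda k: (k[0], k[1].value)):
        pid, tp = key
        if pid not in purity:
            diagnostics.append(RowDiagnostic(
                "copynumber", -1,
                f"sample {key} has no clinical record supplying purity; skipped"))
            continue
        try:
            sample = TumorSample(
                patient_id=pid,
                timepoint=tp,
                purity=purity[pid],
                variants=variants_by_sample.get(key, []),
                cn=CopyNumberProfile(cn_by_sample.get(key, {})),
                lymphocyte_pct=lymph.get(key),
            )
        except ValidationError as exc:
            diagnostics.append(RowDiagnostic("cohort", -1, f"sample {key}: {exc}"))
            continue
        cohort.add_sample(sample)

    return cohort, diagnostics


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical variants/copynumber/clinical tables.

    Rows are sorted on (patient, timepoint, gene) so repeated writes of
    the same cohort are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    vrows, crows = [], []
    for (pid, tp), sample in sorted(cohort.samples.items(),
                                    key=lambda kv: (kv[0][0], kv[0][1].value)):
        for v in sorted(sample.variants, key=lambda v: (v.gene, v.protein_change or "")):
            vrows.append({
                "patient_id": pid, "timepoint": tp.value, "gene": v.gene,
                "protein_change": v.protein_change or "",
                "variant_class": v.variant_class.value, "vaf": v.vaf_observed,
            })
        for gene in sorted(sample.cn.copy_number):
            crows.append({
                "patient_id": pid, "timepoint": tp.value, "gene": gene,
                "copy_number": sample.cn.copy_number[gene],
            })

    lrows = []
    for pid in sorted(cohort.clinical):
        rec = cohort.clinical[pid]
        samples = {s.timepoint: s for s in cohort.samples_of(pid)}
        any_sample = next(iter(samples.values()), None)
        pre = samples.get(Timepoint.DIAGNOSIS)
        post = samples.get(Timepoint.SURGERY)
        lrows.append({
            "patient_id": pid,
            "dfs_months": rec.dfs_months, "dfs_event": int(rec.dfs_event),
            "os_months": rec.os_months, "os_event": int(rec.os_event),
            "recurred": int(rec.recurred), "age": rec.age,
            "node_positive": int(rec.node_positive), "rcb_class": rec.rcb_class,
            "purity_pct": round(any_sample.purity * 100.0, 6) if any_sample else "",
            "lymphocyte_pct_pre": "" if pre is None or pre.lymphocyte_pct is None
                                  else pre.lymphocyte_pct,
            "lymphocyte_pct_post": "" if post is None or post.lymphocyte_pct is None
                                   else post.lymphocyte_pct,
        })

    paths = {}
    for name, rows, cols in (
        ("variants", vrows, VARIANT_COLUMNS[:5] + ["vaf"]),
        ("copynumber", crows, CN_COLUMNS),
        ("clinical", lrows, CLINICAL_COLUMNS),
    ):
        cols = {"variants": ["patient_id", "timepoint", "gene", "protein_change",
                             "variant_class", "vaf"],
                "copynumber": CN_COLUMNS,
                "clinical": CLINICAL_COLUMNS}[name]
        df = pd.DataFrame(rows, columns=cols)
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def read_variants_vcf(path: str | Path, sample_id: Optional[str] = None
                      ) -> tuple[list[VariantCall], int]:
    """Optional VCF v4.2 subset reader.

    One VariantCall per PASS record; the gene symbol is taken from the
    INFO ``GENE`` key and the allele frequency from the sample FORMAT
    ``AF`` (when ``sample_id`` is given) or the INFO ``AF``. Non-PASS
    records are skipped and counted. Returns (calls, n_skipped).
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot parse VCF header: {exc}") from exc

    calls: list[VariantCall] = []
    n_skipped = 0
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_skipped += 1
                continue
            if sample_id is not None and sample_id in rec.samples \
                    and rec.samples[sample_id].get("AF") is not None:
                af = rec.samples[sample_id]["AF"]
            elif "AF" in rec.info:
                af = rec.info["AF"]
            else:
                raise SchemaError(
                    f"record {rec.chrom}:{rec.pos} carries no AF in FORMAT or INFO")
            if isinstance(af, tuple):
                af = af[0]
            header_info = vcf.header.info
            gene = rec.info.get("GENE") if "GENE" in header_info else None
            if gene is None:
                raise SchemaError(
                    f"record {rec.chrom}:{rec.pos} carries no GENE key in INFO")
            if isinstance(gene, tuple):
                gene = gene[0]
            vc = rec.info.get("VC") if "VC" in header_info else None
            if isinstance(vc, tuple):
                vc = vc[0]
            try:
                variant_class = VariantClassification[str(vc).upper()] if vc \
                    else VariantClassification.OTHER
            except KeyError:
                variant_class = VariantClassification.OTHER
            pc = rec.info.get("PC") if "PC" in header_info else None
            if isinstance(pc, tuple):
                pc = pc[0]
            calls.append(VariantCall(
                gene=str(gene), protein_change=pc, variant_class=variant_class,
                vaf_observed=float(af)))
    return calls, n_skipped
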