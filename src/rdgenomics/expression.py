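"""Expression-side computations.

RPKM normalization, two-group differential expression on log2(RPKM + 1),
the transcriptional-amplification statistic (fraction of significant
genes overexpressed in a focal group — the footprint of MYC
hyperactivity is an up-fraction near 1), the 18q21 regional screen,
conditional single-gene contrasts, and the immune-panel detection QC.

"Expressed" and "detected" both mean nonzero in at least a configurable
fraction of samples (20% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ExpressionMatrix, ValidationError
from .stats import FDR_DEFAULT, bh_fdr, t_test

EXPRESSED_FRACTION = 0.20


def rpkm(
    counts: pd.DataFrame,
    gene_length_bp: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count / (length_kb * library_size_millions). When
    ``library_sizes`` is omitted, per-sample column sums are used.
    """
    counts = counts.astype(float)
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValidationError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValidationError("library sizes must be positive for every sample")
    length_kb = lengths / 1_000.0
    lib_m = library_sizes / 1_000_000.0
    return counts.div(length_kb, axis=0).div(lib_m, axis=1)


def ensure_rpkm(em: ExpressionMatrix) -> ExpressionMatrix:
    """Return an RPKM-valued matrix, normalizing when the table holds
    raw counts."""
    if not em.is_counts:
        return em
    values = rpkm(em.values, em.meta["length_bp"])
    return ExpressionMatrix(values, em.meta, is_counts=False, groups=em.groups)


def _align_groups(values: pd.DataFrame, group_labels: pd.Series
                  ) -> tuple[pd.DataFrame, pd.Series, list]:
    labels = pd.Series(group_labels)
    labels = labels.reindex(values.columns).dropna()
    values = values[labels.index]
    uniq = sorted(map(str, labels.unique()))
    return values, labels.astype(str), uniq


@dataclass
class DEResults:
    """Per-gene differential-expression table plus the contrast metadata."""

    table: pd.DataFrame  # columns: direction, p, q, significant, constant
    focal_group: str
    reference_group: str
    fdr: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def differential_expression(
    em: ExpressionMatrix,
    group_labels: pd.Series,
    focal_group: Optional[str] = None,
    paired_ids: Optional[pd.Series] = None,
    fdr: float = FDR_DEFAULT,
    log_transform: bool = True,
) -> DEResults:
    """Two-group differential expression with BH adjustment.

    Unpaired contrasts use one-way ANOVA per gene (equivalent to the
    squared two-sample t); when ``paired_ids`` maps samples to subject
    ids, a paired t test runs over complete pairs instead. Values are
    log2(x + 1)-stabilized by default. ``direction`` is +1 when the gene
    is up in the focal group (the lexicographically first label when not
    named). Genes constant across all samples get p = 1 and a flag.
    """
    em = ensure_rpkm(em)
    values, labels, uniq = _align_groups(em.values, group_labels)
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {uniq}")
    focal = str(focal_group) if focal_group is not None else uniq[0]
    if focal not in uniq:
        raise ValidationError(f"focal group {focal!r} not among labels {uniq}")
    other = [u for u in uniq if u != focal][0]

    x = values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    a = x[:, (labels == focal).to_numpy()]
    b = x[:, (labels == other).to_numpy()]

    if paired_ids is not None:
        ids = pd.Series(paired_ids).reindex(labels.index)
        a_ids = ids[labels == focal]
        b_ids = ids[labels == other]
        common = a_ids[a_ids.isin(b_ids)].dropna()
        if common.size < 2:
            raise ValidationError("paired mode requires >= 2 complete pairs")
        a_cols = [list(a_ids).index(i) for i in common]
        b_cols = [list(b_ids).index(i) for i in common]
        a, b = a[:, a_cols], b[:, b_cols]
        if a.shape[1] != b.shape[1]:
            raise ValidationError("paired mode requires complete pairs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.ttest_rel(a, b, axis=1)
    else:
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValidationError("need >= 2 samples per group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.f_oneway(a, b, axis=1)

    p = np.asarray(p, dtype=float)
    constant = np.array([np.allclose(row, row[0]) for row in x])
    p = np.where(np.isfinite(p), p, 1.0)
    p[constant] = 1.0
    direction = np.sign(a.mean(axis=1) - b.mean(axis=1)).astype(int)
    q = bh_fdr(p)
    table = pd.DataFrame({
        "direction": direction,
        "p": p,
        "q": q,
        "significant": (q <= fdr) & ~constant,
        "constant": constant,
    }, index=values.index)
    return DEResults(table=table, focal_group=focal, reference_group=other, fdr=fdr)


def transcriptional_amplification(de: DEResults) -> tuple[int, Optional[float]]:
    """(number of significant genes, fraction of them up in the focal
    group). The up-fraction is None when nothing is significant."""
    sig = de.table[de.table["significant"]]
    n = int(len(sig))
    if n == 0:
        return 0, None
    return n, float((sig["direction"] > 0).mean())


@dataclass
class RegionalScreenResult:
    region_genes: list
    expressed: list
    overexpressed: list
    de: Optional[DEResults] = None
    warning: Optional[str] = None


def regional_screen(
    em: ExpressionMatrix,
    cytoband_prefixes: Sequence[str],
    group_labels: pd.Series,
    focal_group: Optional[str] = None,
    coding_only: bool = True,
    expressed_fraction: float = EXPRESSED_FRACTION,
    fdr: float = FDR_DEFAULT,
) -> RegionalScreenResult:
    """Differential overexpression restricted to a cytoband region.

    Genes are selected by string-prefix match of their cytoband against
    ``cytoband_prefixes``, filtered to those expressed (nonzero in at
    least ``expressed_fraction`` of samples) and, optionally, to
    protein-coding genes; the survivors are tested by
    :func:`differential_expression` and the overexpressed subset is
    significant AND up in the focal (gain) group.
    """
    em = ensure_rpkm(em)
    bands = em.meta["cytoband"].astype(str)
    in_region = bands.map(lambda b: any(b.startswith(p) for p in cytoband_prefixes))
    region_genes = list(em.genes[in_region])
    if not region_genes:
        return RegionalScreenResult(
            [], [], [], warning="no genes annotated to the requested region")

    sub = em.values.loc[region_genes]
    detected = (sub > 0).mean(axis=1) >= expressed_fraction
    expressed = list(sub.index[detected])
    candidates = expressed
    if coding_only:
        coding = em.meta.loc[candidates, "coding"].astype(bool)
        candidates = list(pd.Index(candidates)[coding.to_numpy()])
    if len(candidates) == 0:
        return RegionalScreenResult(region_genes, expressed, [],
                                    warning="no expressed (coding) genes in region")
    region_em = ExpressionMatrix(
        em.values.loc[candidates], em.meta.loc[candidates], is_counts=False)
    de = differential_expression(region_em, group_labels,
                                 focal_group=focal_group, fdr=fdr)
    over = de.table[(de.table["significant"]) & (de.table["direction"] > 0)]
    return RegionalScreenResult(region_genes, expressed, list(over.index), de=de)


@dataclass
class GroupExpressionResult:
    gene: str
    statistic: Optional[float]
    p: Optional[float]
    n_focal: int
    n_other: int
    mean_focal: Optional[float] = None
    mean_other: Optional[float] = None
    skip_reason: Optional[str] = None


def expression_by_group(
    em: ExpressionMatrix,
    gene: str,
    group_labels: pd.Series,
    focal_group: Optional[str] = None,
    exclude_samples: Optional[Iterable] = None,
) -> GroupExpressionResult:
    """Two-group Student t test on a single gene's expression, with an
    optional sample-exclusion set applied first (the conditional
    analysis, e.g. re-testing after removing amplified samples)."""
    em = ensure_rpkm(em)
    if gene not in em.genes:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    values, labels, uniq = _align_groups(em.values, group_labels)
    if exclude_samples is not None:
        keep = ~labels.index.isin(list(exclude_samples))
        values, labels = values.loc[:, keep], labels[keep]
        uniq = sorted(labels.unique())
    if len(uniq) != 2:
        return GroupExpressionResult(
            gene, None, None,
            n_focal=0, n_other=0,
            skip_reason=f"need exactly two groups after exclusion, have {uniq}")
    focal = str(focal_group) if focal_group is not None else uniq[0]
    other = [u for u in uniq if u != focal][0]
    a = values.loc[gene, (labels == focal).to_numpy()].to_numpy(dtype=float)
    b = values.loc[gene, (labels == other).to_numpy()].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        return GroupExpressionResult(
            gene, None, None, n_focal=a.size, n_other=b.size,
            skip_reason="a group was emptied below n = 2 by the exclusion")
    stat, p = t_test(a, b)
    return GroupExpressionResult(gene, stat, p, n_focal=a.size, n_other=b.size,
                                 mean_focal=float(a.mean()),
                                 mean_other=float(b.mean()))


def panel_detection_fraction(
    em: ExpressionMatrix,
    gene_panel: Sequence[str],
    detected_fraction: float = EXPRESSED_FRACTION,
) -> float:
    """Fraction of a gene panel detected in the matrix (detection =
    nonzero in at least ``detected_fraction`` of samples)."""
    panel = list(dict.fromkeys(gene_panel))
    if not panel:
        raise ValidationError("gene panel must be non-empty")
    em = ensure_rpkm(em)
    present = [g for g in panel if g in em.genes]
    if not present:
        return 0.0
    detected = (em.values.loc[present] > 0).mean(axis=1) >= detected_fraction
    return float(detected.sum() / len(panel))
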