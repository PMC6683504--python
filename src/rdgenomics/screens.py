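"""Cohort-level screening procedures over called samples.

The centerpiece is the two-stage copy-number/recurrence screen: stage 1
compares absolute (purity-corrected) copy number per locus between
patients whose disease recurred and those recurrence-free by one-way
ANOVA; stage-1 survivors are grouped by gain or loss status — the
direction chosen by the sign of the stage-1 mean difference — and tested
for time-to-recurrence (DFS) by log-rank. A locus is positive only if it
passes both stages. No multiplicity correction is applied across loci,
matching the exploratory framing, but a BH-adjusted stage-1 column is
emitted for users who want one.

Also here: single-gene copy-state survival contrasts (e.g. TP53 loss vs
not, MYC amplification vs not), the three-way risk-stratum survival
analysis, and the lymphocyte-depletion tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import Cohort, CopyState, RiskStratum, Timepoint
from .stats import (
    HazardRatioResult,
    LogRankResult,
    bh_fdr,
    hazard_ratio,
    logrank_test,
    t_test,
)


def cohort_frames(cohort: Cohort, prefer: Timepoint = Timepoint.SURGERY
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One row per analyzable patient: corrected copy number, called
    state, and clinical covariates.

    The preferred timepoint (surgery/residual disease by default) is
    used when a patient has both; only samples passing the cellularity
    gate contribute.
    """
    other = (Timepoint.DIAGNOSIS if prefer is Timepoint.SURGERY
             else Timepoint.SURGERY)
    cn_rows, state_rows, index = [], [], []
    for pid in cohort.patients:
        sample = cohort.get(pid, prefer) or cohort.get(pid, other)
        if sample is None or not sample.included or not sample.cn.called:
            continue
        if pid not in cohort.clinical:
            continue
        index.append(pid)
        cn_rows.append(sample.cn.corrected)
        state_rows.append(sample.cn.states)
    cn = pd.DataFrame(cn_rows, index=index)
    states = pd.DataFrame(state_rows, index=index)
    clin = pd.DataFrame(
        [{
            "dfs_months": r.dfs_months, "dfs_event": r.dfs_event,
            "os_months": r.os_months, "os_event": r.os_event,
            "recurred": r.recurred, "age": r.age,
            "node_positive": r.node_positive, "rcb_class": r.rcb_class,
        } for pid, r in ((p, cohort.clinical[p]) for p in index)],
        index=index)
    return cn, states, clin


@dataclass
class ScreenResult:
    gene: str
    stage1_p: Optional[float]
    direction: Optional[str]  # "gain" or "loss" for stage-1 survivors
    stage2_logrank_p: Optional[float]
    positive: bool
    n_group: Optional[int] = None
    n_rest: Optional[int] = None
    skip_reason: Optional[str] = None


def cnv_recurrence_screen(
    cn: pd.DataFrame,
    states: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
) -> list[ScreenResult]:
    """Two-stage copy-number/recurrence screen over every panel locus.

    ``cn`` holds purity-corrected copy numbers (patients x genes),
    ``states`` the called CopyState per cell, ``clinical`` must carry
    recurred, dfs_months and dfs_event. Returns one result per locus;
    loci that cannot be tested carry a skip diagnostic instead of a p.
    """
    recurred = clinical["recurred"].astype(bool)
    n_rec, n_non = int(recurred.sum()), int((~recurred).sum())
    results: list[ScreenResult] = []

    if n_rec < 2 or n_non < 2:
        reason = (f"recurrence classes too small for stage 1 "
                  f"(recurred={n_rec}, non-recurred={n_non})")
        return [ScreenResult(g, None, None, None, False, skip_reason=reason)
                for g in cn.columns]

    rec_vals = cn.loc[recurred].to_numpy(dtype=float)
    non_vals = cn.loc[~recurred].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, stage1_p = sps.f_oneway(rec_vals, non_vals, axis=0)
    mean_diff = rec_vals.mean(axis=0) - non_vals.mean(axis=0)

    for j, gene in enumerate(cn.columns):
        if len(np.unique(cn[gene].to_numpy())) < 2:
            results.append(ScreenResult(
                gene, None, None, None, False,
                skip_reason="constant copy number across cohort"))
            continue
        p1 = float(stage1_p[j])
        if not np.isfinite(p1):
            results.append(ScreenResult(
                gene, None, None, None, False,
                skip_reason="stage-1 ANOVA undefined (no within-class variance)"))
            continue
        if p1 >= alpha1:
            results.append(ScreenResult(gene, p1, None, None, False))
            continue
        direction = "gain" if mean_diff[j] > 0 else "loss"
        gene_states = states[gene]
        if direction == "gain":
            in_group = gene_states.map(lambda s: s > CopyState.NORMAL)
        else:
            in_group = gene_states.map(lambda s: s < CopyState.NORMAL)
        n_g, n_r = int(in_group.sum()), int((~in_group).sum())
        if n_g == 0 or n_r == 0:
            results.append(ScreenResult(
                gene, p1, direction, None, False, n_group=n_g, n_rest=n_r,
                skip_reason=f"empty {direction} group at stage 2"))
            continue
        lr = logrank_test(clinical["dfs_months"], clinical["dfs_event"],
                          in_group.astype(int))
        results.append(ScreenResult(
            gene, p1, direction, lr.p, positive=(lr.p < alpha2),
            n_group=n_g, n_rest=n_r))
    return results


def screen_results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular form with a BH-adjusted stage-1 column alongside."""
    df = pd.DataFrame([{
        "gene": r.gene, "stage1_p": r.stage1_p, "direction": r.direction,
        "stage2_logrank_p": r.stage2_logrank_p, "positive": r.positive,
        "n_group": r.n_group, "n_rest": r.n_rest, "skip_reason": r.skip_reason,
    } for r in results])
    tested = df["stage1_p"].notna()
    q = pd.Series(np.nan, index=df.index)
    if tested.any():
        q[tested] = bh_fdr(df.loc[tested, "stage1_p"].to_numpy())
    df["stage1_q_bh"] = q
    return df


SPLITS = {
    "loss_vs_not": lambda s: s < CopyState.NORMAL,
    "gain_vs_not": lambda s: s > CopyState.NORMAL,
    "amplified_vs_not": lambda s: s is CopyState.AMPLIFIED,
}


@dataclass
class SurvivalContrast:
    label: str
    n_group: int
    n_rest: int
    dfs_logrank: Optional[LogRankResult] = None
    dfs_hr: Optional[HazardRatioResult] = None
    os_logrank: Optional[LogRankResult] = None
    os_hr: Optional[HazardRatioResult] = None
    error: Optional[str] = None


def survival_by_copy_state(
    states: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str,
    split: str,
    covariates: Optional[pd.DataFrame] = None,
) -> SurvivalContrast:
    """DFS and OS contrast for one gene under a copy-state split
    (loss_vs_not, gain_vs_not, or amplified_vs_not)."""
    if gene not in states.columns:
        raise KeyError(f"gene {gene!r} not on panel")
    if split not in SPLITS:
        raise ValueError(f"unknown split {split!r}; use one of {sorted(SPLITS)}")
    in_group = states[gene].map(SPLITS[split])
    n_g, n_r = int(in_group.sum()), int((~in_group).sum())
    label = f"{gene}:{split}"
    if n_g == 0 or n_r == 0:
        return SurvivalContrast(label, n_g, n_r,
                                error=f"empty group under split {split}")
    out = SurvivalContrast(label, n_g, n_r)
    ind = in_group.astype(int)
    out.dfs_logrank = logrank_test(clinical["dfs_months"], clinical["dfs_event"], ind)
    out.os_logrank = logrank_test(clinical["os_months"], clinical["os_event"], ind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out.dfs_hr = hazard_ratio(clinical["dfs_months"], clinical["dfs_event"],
                                  ind, covariates=covariates)
        out.os_hr = hazard_ratio(clinical["os_months"], clinical["os_event"],
                                 ind, covariates=covariates)
    return out


@dataclass
class StratumSurvival:
    counts: dict
    omnibus_dfs: LogRankResult
    omnibus_os: LogRankResult
    high_vs_rest_dfs: HazardRatioResult
    high_vs_rest_os: HazardRatioResult
    pairwise_dfs: dict = field(default_factory=dict)
    median_dfs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def survival_by_stratum(clinical: pd.DataFrame, strata: pd.Series
                        ) -> StratumSurvival:
    """Omnibus three-way log-rank across the TP53 risk strata plus the
    HIGH-versus-rest hazard contrast, on DFS and OS."""
    strata = strata.reindex(clinical.index)
    if strata.isna().any():
        raise ValueError("every patient needs a risk stratum")
    labels = strata.map(lambda s: s.value if isinstance(s, RiskStratum) else str(s))
    counts = labels.value_counts().to_dict()
    warns = []
    present = [s.value for s in RiskStratum if counts.get(s.value, 0) > 0]
    if len(present) < len(RiskStratum):
        missing = [s.value for s in RiskStratum if s.value not in present]
        warns.append(f"empty stratum/strata {missing}; omnibus df reduced "
                     f"to {len(present) - 1}")

    omnibus_dfs = logrank_test(clinical["dfs_months"], clinical["dfs_event"], labels)
    omnibus_os = logrank_test(clinical["os_months"], clinical["os_event"], labels)
    high = (labels == RiskStratum.HIGH.value).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hr_dfs = hazard_ratio(clinical["dfs_months"], clinical["dfs_event"], high)
        hr_os = hazard_ratio(clinical["os_months"], clinical["os_event"], high)

    pairwise = {}
    from .stats import kaplan_meier
    medians = {}
    for name in present:
        mask = labels == name
        medians[name] = kaplan_meier(clinical.loc[mask, "dfs_months"],
                                     clinical.loc[mask, "dfs_event"]).median
    for a, b in (("MODERATE", "LOW"), ("HIGH", "LOW"), ("HIGH", "MODERATE")):
        if counts.get(a, 0) and counts.get(b, 0):
            mask = labels.isin([a, b])
            ind = (labels[mask] == a).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pairwise[(a, b)] = hazard_ratio(
                    clinical.loc[mask, "dfs_months"],
                    clinical.loc[mask, "dfs_event"], ind)
    return StratumSurvival(
        counts=counts, omnibus_dfs=omnibus_dfs, omnibus_os=omnibus_os,
        high_vs_rest_dfs=hr_dfs, high_vs_rest_os=hr_os,
        pairwise_dfs=pairwise, median_dfs=medians, warnings=warns)


@dataclass
class PairedTestResult:
    statistic: Optional[float]
    p: Optional[float]
    n: int
    skip_reason: Optional[str] = None


@dataclass
class LymphocyteDepletionResult:
    unpaired: PairedTestResult
    paired: PairedTestResult
    paired_non_relapsers: PairedTestResult
    paired_relapsers: PairedTestResult
    n_pre: int = 0
    n_post: int = 0


def lymphocyte_depletion(cohort: Cohort) -> LymphocyteDepletionResult:
    """Pre- versus post-chemotherapy total lymphocyte percentage.

    Unpaired t over all samples with a lymphocyte score, paired t over
    matched pairs, and paired t within non-relapsers and relapsers
    separately. Lymphocyte scoring is slide-level, so the cellularity
    gate does not apply here. Subgroups with < 2 pairs are skipped with
    a diagnostic.
    """
    pre_vals, post_vals = {}, {}
    for (pid, tp), s in cohort.samples.items():
        if s.lymphocyte_pct is None:
            continue
        (pre_vals if tp is Timepoint.DIAGNOSIS else post_vals)[pid] = s.lymphocyte_pct

    pre = np.array(list(pre_vals.values()), dtype=float)
    post = np.array(list(post_vals.values()), dtype=float)
    if pre.size >= 2 and post.size >= 2:
        stat, p = t_test(pre, post)
        unpaired = PairedTestResult(stat, p, n=pre.size + post.size)
    else:
        unpaired = PairedTestResult(None, None, n=pre.size + post.size,
                                    skip_reason="fewer than 2 samples per timepoint")

    def paired_subset(pids) -> PairedTestResult:
        pids = [p_ for p_ in pids if p_ in pre_vals and p_ in post_vals]
        if len(pids) < 2:
            return PairedTestResult(None, None, n=len(pids),
                                    skip_reason="fewer than 2 matched pairs")
        a = np.array([pre_vals[p_] for p_ in pids])
        b = np.array([post_vals[p_] for p_ in pids])
        stat, p = t_test(a, b, paired=True)
        return PairedTestResult(stat, p, n=len(pids))

    all_pids = set(pre_vals) & set(post_vals)
    relapsers = {p_ for p_ in all_pids
                 if p_ in cohort.clinical and cohort.clinical[p_].recurred}
    non_relapsers = {p_ for p_ in all_pids
                     if p_ in cohort.clinical and not cohort.clinical[p_].recurred}
    return LymphocyteDepletionResult(
        unpaired=unpaired,
        paired=paired_subset(sorted(all_pids)),
        paired_non_relapsers=paired_subset(sorted(non_relapsers)),
        paired_relapsers=paired_subset(sorted(relapsers)),
        n_pre=pre.size, n_post=post.size,
    )
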