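"""Survival and hypothesis-testing primitives shared by the analyses.

Kaplan-Meier estimation, the log-rank test, and proportional-hazards
hazard ratios are provided by lifelines (Cox models use the Efron
approximation for the frequent month-resolution ties); the classical
tests come from scipy and Benjamini-Hochberg adjustment from
statsmodels. This module pins down the conventions the rest of the
package relies on: all tests two-tailed, alpha 0.05, FDR 10%, and the
degenerate-input behavior documented on each function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
FDR_DEFAULT = 0.10


class DegreesOfFreedomError(ValueError):
    """Fewer than two non-empty groups supplied to a k-group test."""


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with right censoring."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size == 0:
            raise ValueError("empty survival curve")
        if not np.isclose(s[0], 1.0):
            raise ValueError("survival must start at 1.0")
        if np.any(np.diff(s) > 1e-12) or np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise ValueError("survival must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t) by step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    @property
    def median(self) -> float:
        """Smallest time with S(t) <= 0.5, inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class HazardRatioResult:
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    n_exposed: int
    n_unexposed: int
    covariate_effects: dict = field(default_factory=dict)
    non_identifiable: bool = False


def _check_survival_inputs(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.size == 0 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d arrays, n >= 1")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and >= 0")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    t, e = _check_survival_inputs(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).ffill()
    # leading row is S(0-) = 1; a genuine event step at t = 0 keeps its
    # own row so the estimate still drops there
    times_l, surv_l = [0.0], [1.0]
    risk_l, ev_l = [float(t.size)], [0.0]
    for time_i, row in table.iterrows():
        if time_i == 0 and row["observed"] == 0:
            continue  # lifelines' synthetic start row
        times_l.append(float(time_i))
        surv_l.append(float(surv.loc[time_i]))
        risk_l.append(float(row["at_risk"]))
        ev_l.append(float(row["observed"]))
    return SurvivalCurve(
        times=np.array(times_l), survival=np.array(surv_l),
        at_risk=np.array(risk_l), n_events=np.array(ev_l),
    )


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test (observed minus expected events over shared
    event times, chi-square reference)."""
    t, e = _check_survival_inputs(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group_labels must match times in length")
    n_groups = len(np.unique(g))
    if n_groups < 2:
        raise DegreesOfFreedomError(
            f"log-rank requires >= 2 non-empty groups, got {n_groups}")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(statistic=float(res.test_statistic),
                         df=n_groups - 1, p=float(res.p_value))


def hazard_ratio(
    times,
    events,
    group_indicator,
    covariates: Optional[pd.DataFrame] = None,
    alpha: float = ALPHA,
) -> HazardRatioResult:
    """Proportional-hazards HR of a binary exposure with Wald CI.

    When ``covariates`` is given (age continuous; node and RCB status as
    0/1 indicators) the adjusted HR is returned along with the covariate
    effects. A group with zero events makes the HR non-identifiable: the
    result carries ``non_identifiable=True`` with an unbounded CI.
    """
    t, e = _check_survival_inputs(times, events)
    x = np.asarray(group_indicator, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group_indicator must be binary 0/1")
    n_exp, n_unexp = int((x == 1).sum()), int((x == 0).sum())
    for grp in (0.0, 1.0):
        mask = x == grp
        if mask.sum() == 0 or e[mask].sum() == 0:
            warnings.warn(
                "a group has no events; hazard ratio is non-identifiable",
                RuntimeWarning, stacklevel=2)
            return HazardRatioResult(
                hr=float("nan"), ci_lower=0.0, ci_upper=float("inf"),
                p=float("nan"), n_exposed=n_exp, n_unexposed=n_unexp,
                non_identifiable=True)

    df = pd.DataFrame({"time": t, "event": e.astype(int), "exposed": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    row = summary.loc["exposed"]
    effects = {}
    if covariates is not None:
        for name in cov.columns:
            r = summary.loc[name]
            effects[name] = {
                "hr": float(np.exp(r["coef"])),
                "ci": (float(np.exp(r["coef lower 95%"])),
                       float(np.exp(r["coef upper 95%"]))),
                "p": float(r["p"]),
            }
    return HazardRatioResult(
        hr=float(np.exp(row["coef"])),
        ci_lower=float(np.exp(row["coef lower 95%"])),
        ci_upper=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        n_exposed=n_exp,
        n_unexposed=n_unexp,
        covariate_effects=effects,
    )


def t_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-tailed Student t test.

    Zero variance with equal means returns (0, 1) by convention; zero
    variance with different means returns (inf-signed statistic, 0).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        if a.size < 2:
            raise ValueError("paired test requires n >= 2 pairs")
        d = a - b
        if np.allclose(d.std(), 0.0):
            if np.allclose(d.mean(), 0.0):
                return 0.0, 1.0
            return float(np.sign(d.mean()) * np.inf), 0.0
        res = sps.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test requires n >= 2 per group")
    if np.allclose(a.std(), 0.0) and np.allclose(b.std(), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F test across k >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("ANOVA requires >= 2 groups, each non-empty")
    total_n = sum(a.size for a in arrays)
    if total_n <= len(arrays):
        raise ValueError("ANOVA requires total n > number of groups")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled.std(), 0.0):
        return 0.0, 1.0
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if np.allclose(within, 0.0):
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_overlap(set_hits: int, set_total: int,
                   background_hits: int, background_total: int
                   ) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 overlap table; returns the
    sample odds ratio and p."""
    for v in (set_hits, set_total, background_hits, background_total):
        if int(v) != v or v < 0:
            raise ValueError("counts must be non-negative integers")
    if set_hits > set_total or background_hits > background_total:
        raise ValueError("hits cannot exceed totals")
    table = [[set_hits, set_total - set_hits],
             [background_hits, background_total - background_hits]]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
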