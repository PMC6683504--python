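"""Stage orchestration: simulate -> call -> stratify -> survive ->
screen -> express, with a run manifest.

Each stage reads the canonical tables from the run directory and writes
its result tables back; the manifest records the config hash, seed,
package version, input-table hashes, and stage timings. Re-running with
the same inputs reproduces identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    DEFAULT_HET_RANGE,
    build_reference_range,
    call_sample,
    compare_matched_pair,
)
from .datamodel import Cohort, ReferenceRange, RiskStratum, read_cohort
from .expression import (
    differential_expression,
    regional_screen,
    transcriptional_amplification,
)
from .screens import (
    cnv_recurrence_screen,
    cohort_frames,
    lymphocyte_depletion,
    screen_results_frame,
    survival_by_copy_state,
    survival_by_stratum,
)
from .simulate import CohortConfig, ScreenLocusSpec, generate_cohort
from .tp53 import classify_tp53, collapse_patient_tp53, compound_flag
from .datamodel import ExpressionMatrix


class MissingInputError(FileNotFoundError):
    """An upstream table required by a stage is absent."""


@dataclasses.dataclass
class AnalysisParams:
    """Analysis thresholds, surfaced in config with the published
    defaults."""

    k: float = 3.0
    amp_threshold: float = 4.99
    extensive_loss_threshold: float = 0.5
    subclonal_cutoff: float = 0.25
    alpha1: float = 0.05
    alpha2: float = 0.05
    fdr: float = 0.10
    expressed_fraction: float = 0.20
    region_prefixes: tuple = ("18q21.1", "18q21.2")


def load_config(path: str | Path) -> tuple[CohortConfig, AnalysisParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    if "screen_locus" in cohort_raw and cohort_raw["screen_locus"] is not None:
        cohort_raw["screen_locus"] = ScreenLocusSpec(**cohort_raw["screen_locus"])
    for key in ("purity_range", "followup_range"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort_cfg = CohortConfig(**cohort_raw)
    params = AnalysisParams(**raw.get("analysis", {}))
    return cohort_cfg, params


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(outdir: Path, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise MissingInputError(
            "missing upstream table(s): " + ", ".join(missing)
            + " — run the producing stage first")


def _load_called_cohort(outdir: Path, params: AnalysisParams
                        ) -> tuple[Cohort, dict, ReferenceRange]:
    _require(outdir, "variants.tsv", "copynumber.tsv", "clinical.tsv",
             "normals.tsv")
    cohort, diagnostics = read_cohort(
        outdir / "variants.tsv", outdir / "copynumber.tsv",
        outdir / "clinical.tsv")
    normals = pd.read_csv(outdir / "normals.tsv", sep="\t", index_col="gene")
    ranges = {gene: build_reference_range(row.to_numpy(), assay_id=gene,
                                          k=params.k)
              for gene, row in normals.iterrows()}
    het_path = outdir / "tp53_het_vafs.tsv"
    if het_path.exists():
        vafs = pd.read_csv(het_path, sep="\t")["vaf"].to_numpy()
        het_range = (build_reference_range(vafs, assay_id="TP53_het", k=params.k)
                     if len(vafs) >= 2 and np.std(vafs) > 0 else DEFAULT_HET_RANGE)
    else:
        het_range = DEFAULT_HET_RANGE
    for sample in cohort.samples.values():
        if sample.included:
            call_sample(sample, ranges, het_range,
                        amp_threshold=params.amp_threshold,
                        extensive_loss_threshold=params.extensive_loss_threshold)
    return cohort, {"diagnostics": [str(d) for d in diagnostics],
                    "het_range": (het_range.lower, het_range.upper)}, het_range


def stage_simulate(config: CohortConfig, outdir: Path) -> dict:
    sim = generate_cohort(config)
    paths = sim.write(outdir)
    return {"tables": sorted(p.name for p in paths.values()),
            "n_patients": config.n_patients}


def stage_call(outdir: Path, params: AnalysisParams) -> dict:
    cohort, info, _ = _load_called_cohort(outdir, params)
    rows = []
    for (pid, tp), s in sorted(cohort.samples.items(),
                               key=lambda kv: (kv[0][0], kv[0][1].value)):
        if not s.cn.called:
            continue
        for gene in sorted(s.cn.copy_number):
            rows.append({
                "patient_id": pid, "timepoint": tp.value, "gene": gene,
                "copy_number": s.cn.copy_number[gene],
                "copy_number_corrected": s.cn.corrected[gene],
                "state": s.cn.states[gene].name,
            })
    pd.DataFrame(rows).to_csv(outdir / "called_states.tsv", sep="\t", index=False)

    pair_rows = []
    for pre, post in cohort.matched_pairs():
        if not (pre.included and post.included):
            continue
        ev = compare_matched_pair(pre, post)
        pair_rows.append({
            "patient_id": ev.patient_id,
            "n_acquired": len(ev.acquired), "n_lost": len(ev.lost),
            "acquired": ";".join(sorted(f"{g}:{c}" for g, c in ev.acquired)),
            "lost": ";".join(sorted(f"{g}:{c}" for g, c in ev.lost)),
            "n_state_transitions": len(ev.state_transitions),
            "n_amp_evolution": ev.n_amp_evolution,
            "n_amp_extinction": ev.n_amp_extinction,
            "identical_mutation_profile": ev.identical_mutation_profile,
        })
    pd.DataFrame(pair_rows, columns=[
        "patient_id", "n_acquired", "n_lost", "acquired", "lost",
        "n_state_transitions", "n_amp_evolution", "n_amp_extinction",
        "identical_mutation_profile",
    ]).to_csv(outdir / "pair_evolution.tsv", sep="\t", index=False)
    return {"n_samples_called": sum(s.cn.called for s in cohort.samples.values()),
            "n_pairs": len(pair_rows),
            "n_row_diagnostics": len(info["diagnostics"])}


def stage_stratify(outdir: Path, params: AnalysisParams) -> dict:
    cohort, _, het_range = _load_called_cohort(outdir, params)
    rows = []
    for pid in cohort.patients:
        samples = cohort.samples_of(pid, included_only=True)
        if not samples:
            rows.append({"patient_id": pid, "stratum": "EXCLUDED",
                         "has_mutation": "", "max_vaf_corrected": "",
                         "loh": "", "copy_loss": "", "compound_flag": ""})
            continue
        ev = collapse_patient_tp53(samples, het_range,
                                   subclonal_cutoff=params.subclonal_cutoff)
        stratum = classify_tp53(ev, subclonal_cutoff=params.subclonal_cutoff)
        rows.append({
            "patient_id": pid, "stratum": stratum.value,
            "has_mutation": int(ev.has_mutation),
            "max_vaf_corrected": "" if ev.max_vaf_corrected is None
                                 else ev.max_vaf_corrected,
            "loh": int(ev.loh), "copy_loss": int(ev.copy_loss),
            "compound_flag": int(compound_flag(stratum)),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "strata.tsv", sep="\t", index=False)
    counts = df["stratum"].value_counts().to_dict()
    return {"strata_counts": counts}


def _hr_cols(prefix: str, contrast) -> dict:
    def fmt(hr):
        if hr is None:
            return {f"{prefix}_hr": "", f"{prefix}_ci_lower": "",
                    f"{prefix}_ci_upper": "", f"{prefix}_hr_p": ""}
        return {f"{prefix}_hr": hr.hr, f"{prefix}_ci_lower": hr.ci_lower,
                f"{prefix}_ci_upper": hr.ci_upper, f"{prefix}_hr_p": hr.p}
    out = {}
    lr = getattr(contrast, f"{prefix}_logrank")
    out[f"{prefix}_logrank_p"] = "" if lr is None else lr.p
    out.update(fmt(getattr(contrast, f"{prefix}_hr")))
    return out


def stage_survive(outdir: Path, params: AnalysisParams) -> dict:
    _require(outdir, "strata.tsv")
    cohort, _, het_range = _load_called_cohort(outdir, params)
    cn, states, clin = cohort_frames(cohort)
    strata_tbl = pd.read_csv(outdir / "strata.tsv", sep="\t",
                             index_col="patient_id")
    strata = strata_tbl.loc[strata_tbl["stratum"] != "EXCLUDED", "stratum"]
    strata = strata.map(lambda s: RiskStratum(s))
    common = clin.index.intersection(strata.index)
    clin, states = clin.loc[common], states.loc[common]
    strata = strata.loc[common]

    covariates = pd.DataFrame({
        "age": clin["age"].to_numpy(dtype=float),
        "node_positive": clin["node_positive"].astype(int).to_numpy(),
        "rcb_iii": (clin["rcb_class"] == "III").astype(int).to_numpy(),
    })

    rows = []
    for gene, split in (("TP53", "loss_vs_not"), ("MYC", "amplified_vs_not")):
        uni = survival_by_copy_state(states, clin, gene, split)
        adj = survival_by_copy_state(states, clin, gene, split,
                                     covariates=covariates)
        row = {"comparison": uni.label, "n_group": uni.n_group,
               "n_rest": uni.n_rest, "error": uni.error or ""}
        if uni.error is None:
            row.update(_hr_cols("dfs", uni))
            row.update(_hr_cols("os", uni))
            if adj.dfs_hr is not None:
                row["dfs_hr_adjusted"] = adj.dfs_hr.hr
                row["os_hr_adjusted"] = adj.os_hr.hr
        rows.append(row)

    strat = survival_by_stratum(clin, strata)
    rows.append({
        "comparison": "stratum:omnibus",
        "n_group": strat.counts.get("HIGH", 0),
        "n_rest": sum(strat.counts.values()) - strat.counts.get("HIGH", 0),
        "dfs_logrank_p": strat.omnibus_dfs.p,
        "os_logrank_p": strat.omnibus_os.p,
        "dfs_hr": strat.high_vs_rest_dfs.hr,
        "dfs_ci_lower": strat.high_vs_rest_dfs.ci_lower,
        "dfs_ci_upper": strat.high_vs_rest_dfs.ci_upper,
        "dfs_hr_p": strat.high_vs_rest_dfs.p,
        "os_hr": strat.high_vs_rest_os.hr,
        "os_ci_lower": strat.high_vs_rest_os.ci_lower,
        "os_ci_upper": strat.high_vs_rest_os.ci_upper,
        "os_hr_p": strat.high_vs_rest_os.p,
        "error": "; ".join(strat.warnings),
    })
    pd.DataFrame(rows).to_csv(outdir / "survival_contrasts.tsv",
                              sep="\t", index=False)

    lym = lymphocyte_depletion(cohort)
    lrows = []
    for name, res in (("unpaired_pre_vs_post", lym.unpaired),
                      ("paired", lym.paired),
                      ("paired_non_relapsers", lym.paired_non_relapsers),
                      ("paired_relapsers", lym.paired_relapsers)):
        lrows.append({"test": name, "n": res.n,
                      "statistic": "" if res.statistic is None else res.statistic,
                      "p": "" if res.p is None else res.p,
                      "skip_reason": res.skip_reason or ""})
    pd.DataFrame(lrows).to_csv(outdir / "lymphocytes.tsv", sep="\t", index=False)
    return {"n_contrasts": len(rows),
            "stratum_counts": strat.counts}


def stage_screen(outdir: Path, params: AnalysisParams) -> dict:
    cohort, _, _ = _load_called_cohort(outdir, params)
    cn, states, clin = cohort_frames(cohort)
    results = cnv_recurrence_screen(cn, states, clin,
                                    alpha1=params.alpha1, alpha2=params.alpha2)
    df = screen_results_frame(results)
    df.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
    return {"n_loci": len(df),
            "n_stage1_survivors": int((df["direction"].notna()).sum()),
            "positives": sorted(df.loc[df["positive"], "gene"])}


def stage_express(outdir: Path, params: AnalysisParams) -> dict:
    _require(outdir, "expression.tsv", "strata.tsv")
    em = ExpressionMatrix.read_tsv(outdir / "expression.tsv")
    strata = pd.read_csv(outdir / "strata.tsv", sep="\t",
                         index_col="patient_id")["stratum"]
    surgery_cols = [c for c in em.samples if str(c).endswith("@SURGERY")]
    pid_of = {c: str(c).split("@")[0] for c in surgery_cols}
    labels = pd.Series({
        c: "compound" if strata.get(pid_of[c]) == "HIGH" else "other"
        for c in surgery_cols})
    sub = ExpressionMatrix(em.values[surgery_cols], em.meta,
                           is_counts=em.is_counts)
    de = differential_expression(sub, labels, focal_group="compound",
                                 fdr=params.fdr)
    de.table.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")
    n_sig, up_frac = transcriptional_amplification(de)

    # the regional screen is conditioned on 18q gain status, taken from
    # the called SMAD4 state of the surgical (or only) sample
    _require(outdir, "called_states.tsv")
    called = pd.read_csv(outdir / "called_states.tsv", sep="\t")
    smad4 = called[called["gene"] == "SMAD4"]
    smad4 = smad4.sort_values("timepoint").drop_duplicates(
        "patient_id", keep="last")  # SURGERY sorts after DIAGNOSIS
    gain_pids = set(smad4.loc[smad4["state"].isin(["GAIN", "AMPLIFIED"]),
                              "patient_id"].astype(str))
    gain_labels = pd.Series({
        c: "gain" if pid_of[c] in gain_pids else "other"
        for c in surgery_cols})
    reg = regional_screen(sub, params.region_prefixes, gain_labels,
                          focal_group="gain", coding_only=True,
                          expressed_fraction=params.expressed_fraction,
                          fdr=params.fdr)
    pd.DataFrame({
        "gene": reg.region_genes,
        "expressed": [g in reg.expressed for g in reg.region_genes],
        "overexpressed": [g in reg.overexpressed for g in reg.region_genes],
    }).to_csv(outdir / "regional_screen.tsv", sep="\t", index=False)
    return {"n_de_significant": n_sig,
            "up_fraction": up_frac,
            "n_region_expressed": len(reg.expressed),
            "region_overexpressed": reg.overexpressed}


STAGES = ("simulate", "call", "stratify", "survive", "screen", "express")


def run_pipeline(
    output_dir: str | Path,
    config_path: Optional[str | Path] = None,
    seed: Optional[int] = None,
    stages: Optional[list] = None,
) -> dict:
    """Execute the configured stages in order and write a manifest."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config_path is not None:
        config, params = load_config(config_path)
        config_hash = _hash_file(Path(config_path))
    else:
        config, params = CohortConfig(), AnalysisParams()
        config_hash = "defaults"
    if seed is not None:
        config.seed = int(seed)

    stages = list(STAGES) if stages is None else list(stages)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "stages": {},
    }
    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            info = stage_simulate(config, outdir)
        elif stage == "call":
            info = stage_call(outdir, params)
        elif stage == "stratify":
            info = stage_stratify(outdir, params)
        elif stage == "survive":
            info = stage_survive(outdir, params)
        elif stage == "screen":
            info = stage_screen(outdir, params)
        elif stage == "express":
            info = stage_express(outdir, params)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = info

    manifest["input_hashes"] = {
        p.name: _hash_file(p)
        for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
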