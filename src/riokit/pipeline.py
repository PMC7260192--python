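"""Cohort orchestration: run every assay module over a synthetic cohort,
assemble the per-patient biomarker table and reproduce the trial's
association analyses.

The association report mirrors the analyses a window trial reports:
Fisher exact tests of biomarker class against detected HR mechanism,
Mann-Whitney comparisons of continuous scores between classes, a Wilcoxon
signed-rank test of on-treatment change, and exact binomial confidence
intervals for response proportions. Every statistic in the report carries
the table or group sizes it was computed from.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ctdna as ctdna_mod
from . import genomics, ihc, methyl, stats
from .synth import Cohort, CohortConfig, generate_cohort

__all__ = ["PatientRecord", "assemble", "records_frame", "associations", "run"]

logger = logging.getLogger("riokit")

GERMLINE_MECHANISMS = ("brca1_2_germline", "palb2_germline")


@dataclass
class PatientRecord:
    patient_id: str
    control: bool = False
    brca_germline: bool | None = None
    palb2_germline: bool | None = None
    mechanism: str | None = None
    mechanism_detected: bool | None = None
    hrdetect: genomics.HrdetectResult | None = None
    rad51_baseline: ihc.Rad51Result | None = None
    rad51_eot: ihc.Rad51Result | None = None
    ki67_responder: bool | None = None
    ki67_relative_fall: float | None = None
    cparp: ihc.CparpResult | None = None
    cdr: ctdna_mod.CdrResult | None = None
    methylation: dict[str, methyl.SampleMethylationResult] = field(default_factory=dict)


def _patient_cdr(droplets: pd.DataFrame, pid: str) -> ctdna_mod.CdrResult | None:
    pdf = droplets[droplets["patient"] == pid]
    if pdf.empty:
        return None
    quants: dict[str, list[ctdna_mod.TimepointQuant]] = {"baseline": [], "EOT": []}
    for (mutation, timepoint), mdf in pdf.groupby(["mutation", "timepoint"], sort=True):
        wells = [ctdna_mod.DropletWell(int(r.positive), int(r.total)) for r in mdf.itertuples()]
        quants[timepoint].append(
            ctdna_mod.TimepointQuant(
                mutation_id=str(mutation), timepoint=timepoint, wells=wells,
                plasma_ml_equivalent=float(mdf["plasma_ml"].iloc[0]),
            )
        )
    if not quants["baseline"] or not quants["EOT"]:
        return ctdna_mod.CdrResult({}, {}, None, evaluable=False, suppressed=False)
    return ctdna_mod.cdr15(quants["baseline"], quants["EOT"])


def _patient_rad51(fields_df: pd.DataFrame) -> ihc.Rad51Result | None:
    if fields_df.empty:
        return None
    fields = [
        ihc.FociFieldCounts(
            field_id=str(r.field), tumour_cells=int(r.tumour_cells),
            gmnn_positive=int(r.gmnn_pos), rad51_positive=int(r.rad51_pos),
            scorer_id=str(r.scorer),
        )
        for r in fields_df.itertuples()
    ]
    return ihc.rad51_score(fields)


def assemble(
    cohort: Cohort,
    model: genomics.HrdetectModel | None = None,
    methyl_min_passed_reads: int = 100,
) -> list[PatientRecord]:
    """Run every assay module over the cohort's raw data bundles.

    Germline annotations come from the cohort truth table (in the trial
    these are clinical inputs, not assay outputs); methylation status is
    measured from the bisulfite reads; everything else is derived from raw
    counts. Missing assays leave the corresponding field None; nothing is
    imputed."""
    if model is None:
        model = genomics.synthetic_default_model()
    ids = cohort.patient_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient identifiers in cohort")
    features_by_pid = cohort.features_truth.set_index("patient") if not cohort.features_truth.empty else None
    records: list[PatientRecord] = []
    for pid in ids:
        truth_row = cohort.truth.set_index("patient_id").loc[pid]
        rec = PatientRecord(patient_id=pid)
        rec.brca_germline = truth_row["mechanism"] == "brca1_2_germline"
        rec.palb2_germline = truth_row["mechanism"] == "palb2_germline"

        rec.cdr = _patient_cdr(cohort.droplets, pid)

        for amp_name, amp in cohort.amplicons.items():
            reads = cohort.methyl_reads.get((pid, amp_name))
            if reads is None:
                continue
            calls = [
                methyl.process_read(seq, amp, read_id=rid) for rid, seq in reads
            ]
            rec.methylation[amp_name] = methyl.summarize_sample(
                calls, sample_id=pid, amplicon_name=amp_name,
                min_passed_reads=methyl_min_passed_reads,
            )

        pfields = cohort.ihc_fields[cohort.ihc_fields["sample"] == pid]
        rec.rad51_baseline = _patient_rad51(pfields[pfields["timepoint"] == "baseline"])
        rec.rad51_eot = _patient_rad51(pfields[pfields["timepoint"] == "EOT"])

        ki = cohort.ki67[cohort.ki67["sample"] == pid].set_index("timepoint")
        if {"baseline", "EOT"} <= set(ki.index):
            baseline = ihc.Ki67Measurement(
                "baseline", int(ki.loc["baseline", "cells_counted"]),
                float(ki.loc["baseline", "positive_fraction"]),
            )
            eot = ihc.Ki67Measurement(
                "EOT", int(ki.loc["EOT", "cells_counted"]),
                float(ki.loc["EOT", "positive_fraction"]),
            )
            rec.ki67_responder, rec.ki67_relative_fall = ihc.ki67_response(baseline, eot)

        cp = cohort.cparp[
            (cohort.cparp["sample"] == pid) & (cohort.cparp["timepoint"] == "EOT")
        ]
        if not cp.empty:
            rec.cparp = ihc.cparp_score(
                int(cp["cells_counted"].iloc[0]), int(cp["positive_count"].iloc[0])
            )

        if features_by_pid is not None and pid in features_by_pid.index:
            sub_exp, _ = genomics.fit_exposures(
                cohort.sub_catalog, cohort.sub_counts.loc[pid].to_numpy()
            )
            rearr_exp, _ = genomics.fit_exposures(
                cohort.rearr_catalog, cohort.rearr_counts.loc[pid].to_numpy()
            )
            feat_row = features_by_pid.loc[pid]
            features = genomics.HrFeatureVector(
                sub_sig3_exposure=sub_exp["SBS3"],
                sub_sig8_exposure=sub_exp["SBS8"],
                rearr_sig3_exposure=rearr_exp["RS3"],
                rearr_sig5_exposure=rearr_exp["RS5"],
                del_microhomology_proportion=float(feat_row["del_microhomology_proportion"]),
                hrd_loh_index=genomics.hrd_loh_index(cohort.segments[pid]),
            )
            rec.hrdetect = genomics.hrdetect_score(features, model)

        methylation_positive = any(
            r.sample_positive for r in rec.methylation.values() if r.sample_positive
        )
        rec.mechanism_detected = bool(
            rec.brca_germline or rec.palb2_germline or methylation_positive
        )
        if rec.brca_germline:
            rec.mechanism = "brca1_2_germline"
        elif rec.palb2_germline:
            rec.mechanism = "palb2_germline"
        elif rec.methylation.get("BRCA1") and rec.methylation["BRCA1"].sample_positive:
            rec.mechanism = "brca1_methylation"
        elif rec.methylation.get("RAD51C") and rec.methylation["RAD51C"].sample_positive:
            rec.mechanism = "rad51c_methylation"
        else:
            rec.mechanism = "none"
        records.append(rec)
    return records


def records_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the per-patient biomarker table."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "control": r.control,
            "brca_germline": r.brca_germline,
            "palb2_germline": r.palb2_germline,
            "mechanism": r.mechanism,
            "mechanism_detected": r.mechanism_detected,
            "hrdetect_score": r.hrdetect.score if r.hrdetect else None,
            "hrdetect_positive": r.hrdetect.positive if r.hrdetect else None,
            "rad51_score_baseline": r.rad51_baseline.rad51_score if r.rad51_baseline else None,
            "rad51_score_eot": r.rad51_eot.rad51_score if r.rad51_eot else None,
            "rad51_deficient": r.rad51_eot.hr_deficient if r.rad51_eot and r.rad51_eot.valid else None,
            "ki67_responder": r.ki67_responder,
            "ki67_relative_fall": r.ki67_relative_fall,
            "cparp_percent": r.cparp.positive_percent if r.cparp else None,
            "cdr15": r.cdr.cdr15 if r.cdr and r.cdr.evaluable else None,
            "cdr_evaluable": r.cdr.evaluable if r.cdr else False,
            "cdr_suppressed": r.cdr.suppressed if r.cdr and r.cdr.evaluable else None,
            "brca1_methylated": (
                r.methylation["BRCA1"].sample_positive if "BRCA1" in r.methylation else None
            ),
            "rad51c_methylated": (
                r.methylation["RAD51C"].sample_positive if "RAD51C" in r.methylation else None
            ),
        })
    return pd.DataFrame(rows)


def _fisher_entry(df: pd.DataFrame, row_col: str, col_col: str) -> dict[str, Any]:
    sub = df[[row_col, col_col]].dropna()
    if sub.empty or sub[row_col].nunique() < 2 or sub[col_col].nunique() < 2:
        return {"skipped": True, "reason": "degenerate classes", "n": int(len(sub))}
    a = int(((sub[row_col]) & (sub[col_col])).sum())
    b = int(((sub[row_col]) & (~sub[col_col].astype(bool))).sum())
    c = int(((~sub[row_col].astype(bool)) & (sub[col_col])).sum())
    d = int(((~sub[row_col].astype(bool)) & (~sub[col_col].astype(bool))).sum())
    p = stats.fisher_exact_two_sided(stats.ContingencyTable2x2(a, b, c, d))
    return {"table": [[a, b], [c, d]], "p_value": p, "n": a + b + c + d, "skipped": False}


def _mw_entry(df: pd.DataFrame, value_col: str, group_col: str) -> dict[str, Any]:
    sub = df[[value_col, group_col]].dropna()
    groups = sub[group_col].unique()
    if len(groups) != 2:
        return {"skipped": True, "reason": "need exactly 2 groups", "n": int(len(sub))}
    x = sub.loc[sub[group_col] == groups[0], value_col].to_numpy(dtype=float)
    y = sub.loc[sub[group_col] == groups[1], value_col].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        return {"skipped": True, "reason": "fewer than 2 per class", "n": int(len(sub))}
    res = stats.mann_whitney_u(x, y)
    return {
        "groups": {str(groups[0]): len(x), str(groups[1]): len(y)},
        "U": res.statistic, "p_value": res.p_value, "method": res.method,
        "skipped": False,
    }


def associations(records: Sequence[PatientRecord] | pd.DataFrame) -> dict[str, Any]:
    """Association report over the assembled per-patient table."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    report: dict[str, Any] = {}
    report["hrdetect_vs_mechanism"] = _fisher_entry(df, "hrdetect_positive", "mechanism_detected")
    report["rad51_vs_mechanism"] = _fisher_entry(df, "rad51_deficient", "mechanism_detected")
    report["hrdetect_score_by_rad51"] = _mw_entry(df, "hrdetect_score", "rad51_deficient")
    report["cdr15_by_germline"] = _mw_entry(df, "cdr15", "brca_germline")
    report["cdr15_by_rad51"] = _mw_entry(df, "cdr15", "rad51_deficient")
    report["cdr15_by_hrdetect"] = _mw_entry(df, "cdr15", "hrdetect_positive")

    paired = df[["rad51_score_baseline", "rad51_score_eot"]].dropna()
    diffs = (paired["rad51_score_eot"] - paired["rad51_score_baseline"]).to_numpy()
    diffs = diffs[diffs != 0]
    if len(diffs) >= 2:
        res = stats.wilcoxon_signed_rank(diffs)
        report["rad51_change_baseline_to_eot"] = {
            "n_pairs": int(len(diffs)), "W": res.statistic,
            "p_value": res.p_value, "method": res.method, "skipped": False,
        }
    else:
        report["rad51_change_baseline_to_eot"] = {
            "skipped": True, "reason": "fewer than 2 nonzero paired differences",
        }

    proportions = {}
    for name, col in (
        ("ki67_response", "ki67_responder"),
        ("hrdetect_positive", "hrdetect_positive"),
        ("rad51_deficient", "rad51_deficient"),
        ("cdr_suppressed", "cdr_suppressed"),
    ):
        sub = df[col].dropna()
        if len(sub) == 0:
            proportions[name] = {"skipped": True, "reason": "no evaluable patients"}
            continue
        k, n = int(sub.sum()), int(len(sub))
        lo, hi = stats.clopper_pearson(k, n, 0.95)
        proportions[name] = {
            "successes": k, "n": n, "proportion_percent": 100.0 * k / n,
            "ci95_percent": [100.0 * lo, 100.0 * hi], "skipped": False,
        }
    report["proportions"] = proportions
    return report


STAGES = ("simulate", "ctdna", "methyl", "ihc", "genomics", "stats")


def run(
    config: CohortConfig | str | Path,
    outdir: str | Path,
    stages: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """End-to-end pipeline: simulate, score every assay, write artifacts.

    Returns the association report; writes the cohort raw data, the
    per-patient biomarker CSV and the report JSON under ``outdir``."""
    if not isinstance(config, CohortConfig):
        import yaml

        with open(config) as fh:
            payload = yaml.safe_load(fh) or {}
        config = CohortConfig(**payload)
    if seed is not None:
        config.seed = seed
    stages = tuple(stages) if stages else STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    cohort = generate_cohort(config)
    logger.info("simulate: %d patients in %.1fs", config.n_patients, time.time() - t0)
    if "simulate" in stages:
        cohort.write(out / "cohort")

    report: dict[str, Any] = {}
    t0 = time.time()
    records = assemble(cohort)
    df = records_frame(records)
    logger.info("assemble: %d records in %.1fs", len(records), time.time() - t0)

    if "ctdna" in stages:
        ctdna_mod.cdr_table(cohort.droplets).to_csv(out / "cdr15.csv", index=False)
    if "methyl" in stages:
        df[["patient_id", "brca1_methylated", "rad51c_methylated"]].to_csv(
            out / "methylation.csv", index=False
        )
    if "ihc" in stages:
        df[[
            "patient_id", "rad51_score_baseline", "rad51_score_eot",
            "rad51_deficient", "ki67_responder", "cparp_percent",
        ]].to_csv(out / "ihc_scores.csv", index=False)
    if "genomics" in stages:
        df[["patient_id", "hrdetect_score", "hrdetect_positive"]].to_csv(
            out / "hrdetect.csv", index=False
        )
    df.to_csv(out / "patients.csv", index=False)
    if "stats" in stages:
        report = associations(df)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
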