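"""Seeded synthetic cohort generator.

Generates a window-trial-like cohort in which a latent per-patient
homologous-recombination (HR) deficiency status, with an associated causal
mechanism (BRCA1/2 germline, BRCA1 promoter methylation, PALB2 germline,
RAD51C promoter methylation, or none detected), drives every raw data
stream the downstream pipeline consumes:

* per-well ddPCR droplet counts for 1-3 tracked mutations at baseline and
  end of treatment (HR-deficient tumours suppress ctDNA: low CDR15);
* merged bisulfite amplicon reads over synthetic BRCA1/RAD51C promoter
  amplicons (methylation-mechanism patients carry a methylated fraction);
* per-field RAD51/geminin IHC counts at baseline and end of treatment, two
  scorers, plus Ki67 and cleaved-PARP counts;
* mutation-count vectors drawn from a fixed synthetic signature catalog and
  allele-specific copy-number segments whose HRD-LOH index matches the
  latent feature value.

All randomness flows from one root seed through named per-patient,
per-assay substreams, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctdna import DropletWell
from .genomics import (
    GRCH37_CHROMOSOME_LENGTHS,
    SYNTHETIC_FEATURE_DESIGN,
    CopyNumberSegment,
    SignatureCatalog,
)
from .methyl import BRCA1_PRIMERS, RAD51C_PRIMERS, AmpliconReference

__all__ = [
    "CohortConfig",
    "PatientTruth",
    "Cohort",
    "generate_cohort",
    "simulate_ddpcr_wells",
    "simulate_bisulfite_reads",
    "default_amplicons",
    "default_catalogs",
    "MECHANISMS",
]

MECHANISMS = (
    "brca1_2_germline",
    "brca1_methylation",
    "palb2_germline",
    "rad51c_methylation",
    "none",
)

# substream codes so each (patient, assay) pair gets an independent stream
_STREAMS = {
    "latent": 0,
    "ddpcr": 1,
    "methyl": 2,
    "ihc": 3,
    "signatures": 4,
    "segments": 5,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the trial population this package models: 69% HR
    deficiency prevalence, ~74% of HR-deficient tumours with a detectable
    mechanism, CDR15 well below 0.25 for HR-deficient tumours, RAD51 scores
    separated around the 20% cutoff, and a 12% Ki67 response rate."""

    n_patients: int = 50
    prevalence_hrd: float = 0.69
    # mechanism probabilities conditional on HR deficiency
    prevalence_mechanisms: Mapping[str, float] = field(
        default_factory=lambda: {
            "brca1_2_germline": 0.40,
            "brca1_methylation": 0.20,
            "palb2_germline": 0.05,
            "rad51c_methylation": 0.08,
            "none": 0.27,
        }
    )
    ctdna_baseline_log10_mean: float = 1.5  # log10 copies/ml
    ctdna_baseline_log10_sd: float = 1.0
    cdr_hrd_beta_params: tuple[float, float] = (1.0, 6.0)
    cdr_hrp_beta_params: tuple[float, float] = (6.0, 2.0)
    methyl_read_count: int = 400
    conversion_error_rate: float = 0.002
    seq_error_rate: float = 0.002
    ihc_field_cell_mean: float = 80.0
    rad51_score_hrd_mean: float = 8.0  # percent, end of treatment
    rad51_score_hrp_mean: float = 45.0
    rad51_score_sd: float = 5.0
    rad51_baseline_score_mean: float = 5.0  # pre-treatment: little DNA damage
    ki67_response_rate: float = 0.12
    background_methyl_fraction: float = 0.01
    methylated_fraction_range: tuple[float, float] = (0.3, 0.8)
    n_wells: int = 2
    droplets_per_well: int = 15000
    droplet_volume_nl: float = 0.85
    plasma_ml: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        for name in (
            "prevalence_hrd", "conversion_error_rate", "seq_error_rate",
            "background_methyl_fraction", "ki67_response_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        probs = dict(self.prevalence_mechanisms)
        unknown = set(probs) - set(MECHANISMS)
        if unknown:
            raise ConfigError(f"prevalence_mechanisms has unknown mechanisms: {sorted(unknown)}")
        if any(p < 0 for p in probs.values()):
            raise ConfigError("prevalence_mechanisms probabilities must be nonnegative")
        if sum(probs.values()) > 1 + 1e-9:
            raise ConfigError("prevalence_mechanisms probabilities must sum to <= 1")
        for name in ("methyl_read_count", "n_wells", "droplets_per_well"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("ihc_field_cell_mean", "plasma_ml", "droplet_volume_nl"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("cdr_hrd_beta_params", "cdr_hrp_beta_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} shape parameters must be positive")


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    hr_deficient: bool
    mechanism: str
    true_cdr: float
    true_methyl_fraction: float
    true_rad51_score: float


@dataclass
class Cohort:
    """All raw data bundles for one synthetic cohort, keyed by patient."""

    config: CohortConfig
    truth: pd.DataFrame
    droplets: pd.DataFrame
    amplicons: dict[str, AmpliconReference]
    methyl_reads: dict[tuple[str, str], list[tuple[str, str]]]
    ihc_fields: pd.DataFrame
    ki67: pd.DataFrame
    cparp: pd.DataFrame
    sub_catalog: SignatureCatalog
    rearr_catalog: SignatureCatalog
    sub_counts: pd.DataFrame
    rearr_counts: pd.DataFrame
    features_truth: pd.DataFrame
    segments: dict[str, list[CopyNumberSegment]]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.truth["patient_id"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_json(out / "truth.json", orient="records", indent=2)
        self.droplets.to_csv(out / "droplets.csv", index=False)
        self.ihc_fields.to_csv(out / "ihc_fields.csv", index=False)
        self.ki67.to_csv(out / "ki67.csv", index=False)
        self.cparp.to_csv(out / "cparp.csv", index=False)
        self.sub_counts.to_csv(out / "sub_counts.tsv", sep="\t")
        self.rearr_counts.to_csv(out / "rearr_counts.tsv", sep="\t")
        self.features_truth.to_csv(out / "features_truth.csv", index=False)
        self.sub_catalog.to_tsv(out / "sub_catalog.tsv")
        self.rearr_catalog.to_tsv(out / "rearr_catalog.tsv")
        seg_rows = [
            {"patient": pid, "chrom": s.chrom, "start": s.start, "end": s.end,
             "major_cn": s.major_cn, "minor_cn": s.minor_cn}
            for pid, segs in self.segments.items() for s in segs
        ]
        pd.DataFrame(seg_rows).to_csv(out / "segments.tsv", sep="\t", index=False)
        with open(out / "amplicons.fasta", "w") as fh:
            for amp in self.amplicons.values():
                fh.write(f">{amp.name}\n{amp.sequence}\n")
        sidecar = {
            amp.name: {"excluded_sites": list(amp.excluded_sites),
                       "primers": list(amp.primers)}
            for amp in self.amplicons.values()
        }
        with open(out / "amplicons.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for (pid, amp_name), reads in self.methyl_reads.items():
            with open(reads_dir / f"{pid}_{amp_name}.fastq", "w") as fh:
                for rid, seq in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _rng(seed: int, patient_index: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, patient_index, _STREAMS[stream]])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def default_amplicons() -> dict[str, AmpliconReference]:
    """Synthetic promoter amplicons (fixed, independent of the cohort seed).

    Synthetic stand-ins for the real promoter sequences: random inserts
    flanked by the printed assay primers, with >= 10 CpG sites each; two
    RAD51C CpG sites are marked excluded, mirroring the assay convention of
    dropping constitutively methylated sites."""
    rng = np.random.default_rng(20140331)
    amps = {}
    for name, primers, length in (
        ("BRCA1", BRCA1_PRIMERS, 140),
        ("RAD51C", RAD51C_PRIMERS, 130),
    ):
        while True:
            seq = _random_sequence(rng, length)
            n_cpg = seq.count("CG")
            if 10 <= n_cpg <= 20:
                break
        amp = AmpliconReference(name=name, sequence=seq, primers=primers)
        if name == "RAD51C":
            amp = AmpliconReference(
                name=name, sequence=seq, primers=primers,
                excluded_sites=amp.cpg_positions[:2],
            )
        amps[name] = amp
    return amps


def default_catalogs() -> tuple[SignatureCatalog, SignatureCatalog]:
    """Fixed synthetic signature catalogs (12 substitution signatures over
    96 trinucleotide channels, 6 rearrangement signatures over 32 channels),
    drawn once from Dirichlet distributions with a fixed internal seed."""
    rng = np.random.default_rng(560560)
    sub = rng.dirichlet(np.full(96, 0.3), size=12)
    rearr = rng.dirichlet(np.full(32, 0.4), size=6)
    sub_cat = SignatureCatalog(
        tuple(f"SBS{i + 1}" for i in range(12)),
        tuple(f"sub_{i + 1}" for i in range(96)),
        sub / sub.sum(axis=1, keepdims=True),
    )
    rearr_cat = SignatureCatalog(
        tuple(f"RS{i + 1}" for i in range(6)),
        tuple(f"rearr_{i + 1}" for i in range(32)),
        rearr / rearr.sum(axis=1, keepdims=True),
    )
    return sub_cat, rearr_cat


def simulate_ddpcr_wells(
    copies_per_ml: float,
    plasma_ml: float,
    n_wells: int,
    droplets_per_well: int,
    rng: np.random.Generator,
    droplet_volume_nl: float = 0.85,
) -> list[DropletWell]:
    """Simulate droplet partitioning for one assay at one timepoint.

    The reaction holds ``copies_per_ml * plasma_ml`` template copies split
    equally across wells; each droplet is positive with probability
    1 - exp(-lambda), lambda = copies per droplet."""
    if copies_per_ml < 0:
        raise ConfigError("copies_per_ml must be nonnegative")
    if n_wells <= 0 or droplets_per_well <= 0:
        raise ConfigError("n_wells and droplets_per_well must be positive")
    lam = copies_per_ml * plasma_ml / n_wells / droplets_per_well
    p_pos = 1.0 - np.exp(-lam)
    return [
        DropletWell(
            positive_droplets=int(rng.binomial(droplets_per_well, p_pos)),
            total_droplets=droplets_per_well,
            droplet_volume_nl=droplet_volume_nl,
        )
        for _ in range(n_wells)
    ]


def simulate_bisulfite_reads(
    amplicon: AmpliconReference,
    methyl_fraction: float,
    n_reads: int,
    conversion_error_rate: float,
    seq_error_rate: float,
    rng: np.random.Generator,
    read_prefix: str = "read",
) -> list[tuple[str, str]]:
    """Simulate merged, primer-trimmed bisulfite reads for one sample.

    A ``methyl_fraction`` share of reads derives from the fully methylated
    template (CpG cytosines retained, all other cytosines converted to T);
    the rest from the fully converted template (every C to T). Conversion
    errors leave a convertible C unconverted; sequencing errors substitute
    any base uniformly. No indels (short merged amplicon reads)."""
    if not 0 <= methyl_fraction <= 1:
        raise ConfigError("methyl_fraction must be a probability in [0, 1]")
    seq = np.frombuffer(amplicon.sequence.encode(), dtype=np.uint8).copy()
    length = len(seq)
    c_mask = seq == ord("C")
    cpg_mask = np.zeros(length, dtype=bool)
    cpg_mask[list(amplicon.cpg_positions)] = True
    tmpl_meth = seq.copy()
    tmpl_meth[c_mask & ~cpg_mask] = ord("T")
    tmpl_conv = seq.copy()
    tmpl_conv[c_mask] = ord("T")

    is_meth = rng.random(n_reads) < methyl_fraction
    reads = np.where(is_meth[:, None], tmpl_meth[None, :], tmpl_conv[None, :])
    # conversion errors: convertible C positions revert from T to C
    convertible = np.where(is_meth[:, None], (c_mask & ~cpg_mask)[None, :], c_mask[None, :])
    revert = convertible & (rng.random((n_reads, length)) < conversion_error_rate)
    reads[revert] = ord("C")
    # sequencing errors: uniform substitution to one of the other 3 bases
    err = rng.random((n_reads, length)) < seq_error_rate
    if err.any():
        idx = np.searchsorted(_BASES, reads[err])
        shift = rng.integers(1, 4, size=idx.size)
        reads[err] = _BASES[(idx + shift) % 4]
    return [
        (f"{read_prefix}_{i}", reads[i].tobytes().decode())
        for i in range(n_reads)
    ]


def _sample_mechanism(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    names = list(probs)
    p = np.array([probs[m] for m in names], dtype=float)
    residual = 1.0 - p.sum()
    if residual > 1e-12:
        names.append("none")
        p = np.append(p, residual)
    p = p / p.sum()
    return str(names[rng.choice(len(names), p=p)])


def _lognormal_feature(rng: np.random.Generator, median: float, log_sd: float) -> float:
    return float(np.exp(np.log(median) + rng.normal(0.0, log_sd)))


def _generate_segments(
    rng: np.random.Generator, target_loh: int
) -> tuple[list[CopyNumberSegment], int]:
    """Copy-number segments whose HRD-LOH index equals the realised count.

    Places up to two >15 Mb LOH segments on each autosome (target capped at
    34), plus a couple of sub-threshold LOH segments and, sometimes, one
    whole-chromosome LOH, neither of which counts toward the index."""
    autosomes = [str(c) for c in range(1, 23)]
    slots: list[tuple[str, float]] = [(c, 0.05) for c in autosomes]
    slots += [(c, 0.55) for c in autosomes if GRCH37_CHROMOSOME_LENGTHS[c] > 120_000_000]
    realised = min(target_loh, len(slots))
    chosen = [slots[i] for i in rng.choice(len(slots), size=realised, replace=False)]
    loh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, frac in chosen:
        clen = GRCH37_CHROMOSOME_LENGTHS[chrom]
        start = int(frac * clen)
        length = int(rng.uniform(16e6, min(40e6, clen * 0.4)))
        loh_by_chrom.setdefault(chrom, []).append((start, start + length))
    # non-counting decoys
    short_chroms = [autosomes[i] for i in rng.choice(22, size=2, replace=False)]
    whole_chrom = str(rng.choice(autosomes)) if rng.random() < 0.3 else None
    segments: list[CopyNumberSegment] = []
    for chrom in autosomes:
        clen = GRCH37_CHROMOSOME_LENGTHS[chrom]
        if chrom == whole_chrom and chrom not in loh_by_chrom:
            segments.append(CopyNumberSegment(chrom, 0, clen, 2, 0))
            continue
        intervals = sorted(loh_by_chrom.get(chrom, []))
        if chrom in short_chroms and not intervals and chrom != whole_chrom:
            mid = clen // 2
            intervals = [(mid, mid + int(rng.uniform(2e6, 12e6)))]
        pos = 0
        for s, e in intervals:
            if s > pos:
                segments.append(CopyNumberSegment(chrom, pos, s, 1, 1))
            segments.append(CopyNumberSegment(chrom, s, e, 1, 0))
            pos = e
        if pos < clen:
            segments.append(CopyNumberSegment(chrom, pos, clen, 1, 1))
    return segments, realised


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full raw-data bundle for a synthetic cohort.

    Deterministic for a fixed config and seed: all randomness flows through
    named substreams of the root seed."""
    config.validate()
    seed = config.seed
    amplicons = default_amplicons()
    sub_cat, rearr_cat = default_catalogs()
    design = SYNTHETIC_FEATURE_DESIGN

    truth_rows = []
    droplet_rows = []
    methyl_reads: dict[tuple[str, str], list[tuple[str, str]]] = {}
    ihc_rows = []
    ki67_rows = []
    cparp_rows = []
    sub_count_rows = {}
    rearr_count_rows = {}
    feature_rows = []
    segments: dict[str, list[CopyNumberSegment]] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        lat = _rng(seed, i, "latent")
        hr_deficient = bool(lat.random() < config.prevalence_hrd)
        mechanism = (
            _sample_mechanism(lat, config.prevalence_mechanisms) if hr_deficient else "none"
        )
        a, b = config.cdr_hrd_beta_params if hr_deficient else config.cdr_hrp_beta_params
        true_cdr = float(lat.beta(a, b))
        if mechanism in ("brca1_methylation", "rad51c_methylation"):
            lo, hi = config.methylated_fraction_range
            true_methyl_fraction = float(lat.uniform(lo, hi))
        else:
            true_methyl_fraction = config.background_methyl_fraction
        rad_mean = (
            config.rad51_score_hrd_mean if hr_deficient else config.rad51_score_hrp_mean
        )
        true_rad51 = float(np.clip(lat.normal(rad_mean, config.rad51_score_sd), 0.5, 95.0))
        truth_rows.append(
            PatientTruth(pid, hr_deficient, mechanism, true_cdr, true_methyl_fraction, true_rad51)
        )

        # --- ddPCR -------------------------------------------------------
        dd = _rng(seed, i, "ddpcr")
        n_mut = int(dd.integers(1, 4))
        for m in range(n_mut):
            base_conc = float(
                10 ** dd.normal(config.ctdna_baseline_log10_mean, config.ctdna_baseline_log10_sd)
            )
            eot_conc = base_conc * true_cdr
            for timepoint, conc in (("baseline", base_conc), ("EOT", eot_conc)):
                wells = simulate_ddpcr_wells(
                    conc, config.plasma_ml, config.n_wells,
                    config.droplets_per_well, dd, config.droplet_volume_nl,
                )
                for w_idx, w in enumerate(wells):
                    droplet_rows.append({
                        "patient": pid, "mutation": f"{pid}_mut{m + 1}",
                        "timepoint": timepoint, "well": w_idx + 1,
                        "positive": w.positive_droplets, "total": w.total_droplets,
                        "plasma_ml": config.plasma_ml,
                    })

        # --- bisulfite reads ---------------------------------------------
        me = _rng(seed, i, "methyl")
        for amp_name, amp in amplicons.items():
            if amp_name == "BRCA1" and mechanism == "brca1_methylation":
                frac = true_methyl_fraction
            elif amp_name == "RAD51C" and mechanism == "rad51c_methylation":
                frac = true_methyl_fraction
            else:
                frac = config.background_methyl_fraction
            methyl_reads[(pid, amp_name)] = simulate_bisulfite_reads(
                amp, frac, config.methyl_read_count,
                config.conversion_error_rate, config.seq_error_rate, me,
                read_prefix=f"{pid}_{amp_name}",
            )

        # --- IHC ---------------------------------------------------------
        ih = _rng(seed, i, "ihc")
        baseline_rad51 = float(
            np.clip(ih.normal(config.rad51_baseline_score_mean, 3.0), 0.2, 95.0)
        )
        for timepoint, score in (("baseline", baseline_rad51), ("EOT", true_rad51)):
            for scorer in ("scorer1", "scorer2"):
                for f_idx in range(5):
                    tumour = int(ih.poisson(config.ihc_field_cell_mean)) + 1
                    gmnn = int(ih.binomial(tumour, 0.25))
                    rad = int(ih.binomial(gmnn, score / 100.0)) if gmnn else 0
                    ihc_rows.append({
                        "sample": pid, "timepoint": timepoint, "scorer": scorer,
                        "field": f_idx + 1, "tumour_cells": tumour,
                        "gmnn_pos": gmnn, "rad51_pos": rad,
                    })
        ki67_baseline = float(ih.uniform(20, 60))
        responder = bool(ih.random() < config.ki67_response_rate)
        factor = ih.uniform(0.2, 0.45) if responder else ih.uniform(0.55, 1.15)
        ki67_eot = float(np.clip(ki67_baseline * factor, 0, 100))
        for timepoint, frac_pos in (("baseline", ki67_baseline), ("EOT", ki67_eot)):
            ki67_rows.append({
                "sample": pid, "timepoint": timepoint,
                "cells_counted": int(ih.integers(200, 401)),
                "positive_fraction": frac_pos,
            })
        for timepoint in ("baseline", "EOT"):
            cells = int(ih.integers(300, 1500))
            cparp_rows.append({
                "sample": pid, "timepoint": timepoint, "cells_counted": cells,
                "positive_count": int(ih.binomial(cells, ih.uniform(0.005, 0.04))),
            })

        # --- signatures & copy number ------------------------------------
        sg = _rng(seed, i, "signatures")
        exposures_sub = np.zeros(len(sub_cat.signature_names))
        exposures_rearr = np.zeros(len(rearr_cat.signature_names))
        log_sd = 0.5
        cls = 0 if hr_deficient else 1
        exposures_sub[0] = _lognormal_feature(sg, 1500.0, 0.4)  # clock-like background
        exposures_sub[1] = _lognormal_feature(sg, 400.0, 0.5)
        exposures_sub[2] = _lognormal_feature(sg, design["sub_sig3_exposure"][cls], log_sd)
        exposures_sub[7] = _lognormal_feature(sg, design["sub_sig8_exposure"][cls], log_sd)
        exposures_rearr[0] = _lognormal_feature(sg, 40.0, 0.5)
        exposures_rearr[2] = _lognormal_feature(sg, design["rearr_sig3_exposure"][cls], log_sd)
        exposures_rearr[4] = _lognormal_feature(sg, design["rearr_sig5_exposure"][cls], log_sd)
        sub_count_rows[pid] = sg.poisson(exposures_sub @ sub_cat.matrix)
        rearr_count_rows[pid] = sg.poisson(exposures_rearr @ rearr_cat.matrix)
        mh_med = design["del_microhomology_proportion"][cls]
        del_mh = float(np.clip(sg.normal(mh_med, 0.08), 0.0, 1.0))
        cn = _rng(seed, i, "segments")
        target_loh = int(cn.poisson(design["hrd_loh_index"][cls]))
        segs, realised_loh = _generate_segments(cn, target_loh)
        segments[pid] = segs
        feature_rows.append({
            "patient": pid,
            "true_sub_sig3": exposures_sub[2],
            "true_sub_sig8": exposures_sub[7],
            "true_rearr_sig3": exposures_rearr[2],
            "true_rearr_sig5": exposures_rearr[4],
            "del_microhomology_proportion": del_mh,
            "hrd_loh_index": realised_loh,
        })

    truth = pd.DataFrame([asdict(t) for t in truth_rows])
    if truth.empty:
        truth = pd.DataFrame(
            columns=["patient_id", "hr_deficient", "mechanism", "true_cdr",
                     "true_methyl_fraction", "true_rad51_score"]
        )
    return Cohort(
        config=config,
        truth=truth,
        droplets=pd.DataFrame(droplet_rows),
        amplicons=amplicons,
        methyl_reads=methyl_reads,
        ihc_fields=pd.DataFrame(ihc_rows),
        ki67=pd.DataFrame(ki67_rows),
        cparp=pd.DataFrame(cparp_rows),
        sub_catalog=sub_cat,
        rearr_catalog=rearr_cat,
        sub_counts=pd.DataFrame.from_dict(
            sub_count_rows, orient="index", columns=list(sub_cat.channels)
        ),
        rearr_counts=pd.DataFrame.from_dict(
            rearr_count_rows, orient="index", columns=list(rearr_cat.channels)
        ),
        features_truth=pd.DataFrame(feature_rows),
        segments=segments,
    )
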