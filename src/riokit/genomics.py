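"""Genomic features of homologous-recombination deficiency and the
HRDetect-style weighted logistic score.

Feature derivation covered here:

* signature exposures: nonnegative least-squares refit of a per-sample
  mutation-count vector against a fixed signature catalog (the catalog is an
  input, never re-derived);
* HRD-LOH index: number of loss-of-heterozygosity segments longer than
  15 Mb that do not span a whole chromosome, from allele-specific
  copy-number segments;
* HRDetect score: logistic regression over six features (substitution
  signatures 3 and 8, rearrangement signatures 3 and 5, the proportion of
  deletions at microhomology, and the HRD-LOH index), each log-transformed
  and standardised. Positive above 0.70 (strict).

The engine is weight-agnostic: coefficients, standardisation constants and
the log offset load from a JSON model config. The built-in default model is
calibrated analytically to this package's synthetic cohort generator (see
``synthetic_default_model``), not to any published coefficient set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SignatureCatalog",
    "HrFeatureVector",
    "HrdetectModel",
    "HrdetectResult",
    "CopyNumberSegment",
    "fit_exposures",
    "hrd_loh_index",
    "hrdetect_score",
    "classify_hrd_score",
    "synthetic_default_model",
    "GRCH37_CHROMOSOME_LENGTHS",
    "HRD_FEATURES",
]

HRDETECT_THRESHOLD = 0.70  # positive strictly above
HRD_SCORE_THRESHOLD = 42  # composite genomic-instability index, strict >
LOH_MIN_LENGTH_BP = 15_000_000

HRD_FEATURES = (
    "sub_sig3_exposure",
    "sub_sig8_exposure",
    "rearr_sig3_exposure",
    "rearr_sig5_exposure",
    "del_microhomology_proportion",
    "hrd_loh_index",
)

GRCH37_CHROMOSOME_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}


@dataclass(frozen=True)
class SignatureCatalog:
    """Fixed reference matrix of mutational signatures.

    ``matrix`` has one row per signature and one column per mutation
    channel; rows are probability distributions over channels."""

    signature_names: tuple[str, ...]
    channels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.signature_names), len(self.channels)):
            raise ValueError("matrix shape does not match signature/channel labels")
        if (m < 0).any():
            raise ValueError("signature weights must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each signature must sum to 1 over channels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.signature_names),
                            columns=list(self.channels))

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class HrFeatureVector:
    sub_sig3_exposure: float
    sub_sig8_exposure: float
    rearr_sig3_exposure: float
    rearr_sig5_exposure: float
    del_microhomology_proportion: float
    hrd_loh_index: float

    def __post_init__(self) -> None:
        for name in HRD_FEATURES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.del_microhomology_proportion > 1:
            raise ValueError("del_microhomology_proportion is a fraction in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in HRD_FEATURES}


@dataclass
class HrdetectModel:
    """Weighted logistic model over the six HR-deficiency features.

    Each raw feature x is transformed z = (log(x + log_offset) - mean) / sd
    and the score is logistic(intercept + sum(weight * z))."""

    intercept: float
    weights: Mapping[str, float]
    transform: Mapping[str, tuple[float, float]]  # feature -> (mean, sd)
    log_offset: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in HRD_FEATURES:
            if f not in self.weights:
                raise ValueError(f"model is missing a weight for feature {f!r}")
            if f not in self.transform:
                raise ValueError(f"model is missing transform constants for feature {f!r}")
            if self.transform[f][1] <= 0:
                raise ValueError(f"transform sd for {f!r} must be positive")

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "intercept": self.intercept,
            "log_offset": self.log_offset,
            "weights": dict(self.weights),
            "transform": {k: list(v) for k, v in self.transform.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HrdetectModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            weights=payload["weights"],
            transform={k: tuple(v) for k, v in payload["transform"].items()},
            log_offset=payload.get("log_offset", 1.0),
            name=payload.get("name", "custom"),
        )


@dataclass(frozen=True)
class HrdetectResult:
    score: float
    positive: bool  # score > 0.70
    hrd_score_positive: bool | None = None  # composite HRD score > 42, if supplied


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start ({self.chrom}:{self.start}-{self.end})")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start


def fit_exposures(
    catalog: SignatureCatalog, mutation_counts: Sequence[float] | Mapping[str, float]
) -> tuple[dict[str, float], float]:
    """Nonnegative least-squares signature exposure refit.

    Solves min ||counts - exposures @ matrix||^2 with exposures >= 0 and
    returns ({signature: exposure}, residual norm)."""
    if isinstance(mutation_counts, Mapping):
        missing = set(catalog.channels) - set(mutation_counts)
        if missing:
            raise ValueError(f"mutation counts missing channels: {sorted(missing)[:5]}")
        counts = np.array([mutation_counts[c] for c in catalog.channels], dtype=float)
    else:
        counts = np.asarray(mutation_counts, dtype=float)
        if counts.shape != (len(catalog.channels),):
            raise ValueError(
                f"expected {len(catalog.channels)} channel counts, got {counts.shape}"
            )
    if (counts < 0).any():
        raise ValueError("mutation counts must be nonnegative")
    exposures, residual = nnls(catalog.matrix.T, counts)
    return dict(zip(catalog.signature_names, exposures)), float(residual)


def _merge_adjacent(segments: list[CopyNumberSegment]) -> list[CopyNumberSegment]:
    merged: list[CopyNumberSegment] = []
    for seg in segments:
        if (
            merged
            and merged[-1].end == seg.start
            and (merged[-1].major_cn, merged[-1].minor_cn) == (seg.major_cn, seg.minor_cn)
        ):
            prev = merged.pop()
            seg = CopyNumberSegment(seg.chrom, prev.start, seg.end, seg.major_cn, seg.minor_cn)
        merged.append(seg)
    return merged


def hrd_loh_index(
    segments: Sequence[CopyNumberSegment],
    chromosome_lengths: Mapping[str, int] = GRCH37_CHROMOSOME_LENGTHS,
) -> int:
    """HRD-LOH index: LOH segments (minor CN 0, major CN >= 1) longer than
    15 Mb that do not span their whole chromosome.

    Adjacent segments with identical copy number are merged first, so the
    index is invariant to how a segmentation splits a constant-CN run.
    Overlapping segments on a chromosome are rejected."""
    count = 0
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(f"overlapping segments on chromosome {chrom}")
        chrom_len = chromosome_lengths.get(chrom.removeprefix("chr"))
        for seg in _merge_adjacent(segs):
            if seg.minor_cn == 0 and seg.major_cn >= 1 and seg.length > LOH_MIN_LENGTH_BP:
                whole = chrom_len is not None and seg.start == 0 and seg.end >= chrom_len
                if not whole:
                    count += 1
    return count


def hrdetect_score(
    features: HrFeatureVector,
    model: HrdetectModel,
    hrd_score_value: float | None = None,
    threshold: float = HRDETECT_THRESHOLD,
) -> HrdetectResult:
    """HRDetect-style probability of HR deficiency for one sample."""
    logit = model.intercept
    for name, x in features.as_dict().items():
        mean, sd = model.transform[name]
        z = (math.log(x + model.log_offset) - mean) / sd
        logit += model.weights[name] * z
    score = 1.0 / (1.0 + math.exp(-logit))
    return HrdetectResult(
        score=score,
        positive=score > threshold,
        hrd_score_positive=None if hrd_score_value is None else classify_hrd_score(hrd_score_value),
    )


def classify_hrd_score(hrd_score_value: float) -> bool:
    """Composite genomic-instability HRD score classification (> 42)."""
    if hrd_score_value < 0:
        raise ValueError("HRD score must be nonnegative")
    return hrd_score_value > HRD_SCORE_THRESHOLD


# Design medians of the six features in the synthetic cohort generator, for
# HR-deficient and HR-proficient tumours. Used both by the generator and to
# calibrate the synthetic default model below.
SYNTHETIC_FEATURE_DESIGN: dict[str, tuple[float, float]] = {
    # feature: (HR-deficient median, HR-proficient median)
    "sub_sig3_exposure": (2000.0, 100.0),
    "sub_sig8_exposure": (300.0, 80.0),
    "rearr_sig3_exposure": (120.0, 15.0),
    "rearr_sig5_exposure": (60.0, 20.0),
    "del_microhomology_proportion": (0.65, 0.12),
    "hrd_loh_index": (18.0, 3.0),
}

_SYNTHETIC_WEIGHTS = {
    "sub_sig3_exposure": 2.5,
    "sub_sig8_exposure": 0.8,
    "rearr_sig3_exposure": 1.5,
    "rearr_sig5_exposure": 1.0,
    "del_microhomology_proportion": 2.0,
    "hrd_loh_index": 1.2,
}


def synthetic_default_model() -> HrdetectModel:
    """Default model calibrated to the synthetic generator's feature design.

    Synthetic calibration only: each feature is standardised so the two
    latent classes sit near z = +/-1 (mean = midpoint of the class medians
    on the log scale, sd = half their log-scale separation), with positive
    weights and zero intercept. Published coefficient sets can be supplied
    via :meth:`HrdetectModel.from_json` instead."""
    transform = {}
    for name, (hrd_med, hrp_med) in SYNTHETIC_FEATURE_DESIGN.items():
        hi = math.log(hrd_med + 1.0)
        lo = math.log(hrp_med + 1.0)
        transform[name] = ((hi + lo) / 2.0, (hi - lo) / 2.0)
    return HrdetectModel(
        intercept=0.0,
        weights=dict(_SYNTHETIC_WEIGHTS),
        transform=transform,
        log_offset=1.0,
        name="synthetic-cohort-calibration-v1",
    )


def read_segments_tsv(path) -> list[CopyNumberSegment]:
    """BED-like TSV: chrom, start, end, major_cn, minor_cn (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CopyNumberSegment(str(r.chrom), int(r.start), int(r.end), int(r.major_cn), int(r.minor_cn))
        for r in df.itertuples()
    ]
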