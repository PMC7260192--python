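"""Immunohistochemistry scoring: Ki67 response, cleaved PARP, RAD51 foci.

Ki67 response is a relative fall of at least 50% in the Ki67-positive tumour
cell fraction between baseline and end-of-treatment biopsy. Cleaved-PARP
(apoptosis) percentages require at least 500 assessable invasive tumour
cells, otherwise the sample is "insufficient invasive tumour" (IIT).

The RAD51 assay counts, per 40x field, tumour cells, geminin-positive cells
(S/G2 phase, where homologous recombination is active) and geminin-positive
cells with >= 5 RAD51 nuclear foci. Counts are pooled across fields per
scorer before forming ratios (ratio of sums, not mean of ratios):

    proliferation fraction = 100 * GMNN+ / tumour cells
    RAD51 score            = 100 * RAD51+ / GMNN+

A sample is valid when a scorer counted >= 300 tumour cells and >= 30
GMNN-positive cells; a valid RAD51 score < 20% indicates functional HR
deficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Mapping, Sequence

__all__ = [
    "Ki67Measurement",
    "CparpResult",
    "FociFieldCounts",
    "Rad51Result",
    "ki67_response",
    "cparp_score",
    "rad51_score",
]

RAD51_DEFICIENCY_CUTOFF = 20.0  # percent, strict <
MIN_TUMOUR_CELLS = 300
MIN_GMNN_POSITIVE = 30
CPARP_MIN_CELLS = 500


@dataclass(frozen=True)
class Ki67Measurement:
    timepoint: str
    cells_counted: int
    positive_fraction: float  # percent

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 100:
            raise ValueError("positive_fraction is a percent in [0, 100]")
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be nonnegative")

    @property
    def per_protocol(self) -> bool:
        """Protocol asks for 200-400 invasive tumour cells."""
        return 200 <= self.cells_counted <= 400


@dataclass(frozen=True)
class CparpResult:
    cells_counted: int
    positive_percent: float | None  # None when insufficient invasive tumour

    @property
    def insufficient_invasive_tumour(self) -> bool:
        return self.positive_percent is None


@dataclass(frozen=True)
class FociFieldCounts:
    field_id: str
    tumour_cells: int
    gmnn_positive: int
    rad51_positive: int
    scorer_id: str = "scorer1"

    def __post_init__(self) -> None:
        if not 0 <= self.rad51_positive <= self.gmnn_positive <= self.tumour_cells:
            raise ValueError(
                f"need rad51_positive <= gmnn_positive <= tumour_cells, got "
                f"{self.rad51_positive}/{self.gmnn_positive}/{self.tumour_cells}"
            )


@dataclass
class Rad51Result:
    proliferation_fraction: float | None  # percent
    rad51_score: float | None  # percent, mean across scorers
    valid: bool
    hr_deficient: bool
    per_scorer_scores: Mapping[str, float]


def ki67_response(
    baseline: Ki67Measurement,
    eot: Ki67Measurement,
    threshold: float = 0.50,
    strict: bool = False,
) -> tuple[bool, float]:
    """Responder verdict and relative fall in Ki67.

    Relative change = (baseline - EOT) / baseline; responder when the fall
    reaches ``threshold`` (>= by default; ``strict`` switches to >)."""
    if baseline.positive_fraction <= 0:
        raise ValueError("baseline Ki67 fraction is zero; response undefined")
    change = (baseline.positive_fraction - eot.positive_fraction) / baseline.positive_fraction
    responder = change > threshold if strict else change >= threshold
    return responder, change


def cparp_score(cells_counted: int, positive_count: int) -> CparpResult:
    """Cleaved-PARP positive percentage, or IIT below 500 assessable cells."""
    if cells_counted < 0 or positive_count < 0:
        raise ValueError("counts must be nonnegative")
    if positive_count > cells_counted:
        raise ValueError("positive_count exceeds cells_counted")
    if cells_counted < CPARP_MIN_CELLS:
        return CparpResult(cells_counted, None)
    return CparpResult(cells_counted, 100.0 * positive_count / cells_counted)


def rad51_score(fields: Sequence[FociFieldCounts]) -> Rad51Result:
    """RAD51 score and proliferation fraction from per-field counts.

    Counts are pooled across fields within each scorer; the reported score
    is the mean of per-scorer scores. Validity (>= 300 tumour cells and
    >= 30 GMNN+ cells, per scorer) must hold for every scorer; an invalid
    sample is never called HR deficient."""
    if not fields:
        raise ValueError("at least one field required")
    by_scorer: dict[str, list[FociFieldCounts]] = {}
    for f in fields:
        by_scorer.setdefault(f.scorer_id, []).append(f)
    scores: dict[str, float] = {}
    prolifs: list[float] = []
    valid = True
    for scorer, flds in by_scorer.items():
        tumour = sum(f.tumour_cells for f in flds)
        gmnn = sum(f.gmnn_positive for f in flds)
        rad = sum(f.rad51_positive for f in flds)
        if tumour < MIN_TUMOUR_CELLS or gmnn < MIN_GMNN_POSITIVE:
            valid = False
            continue
        scores[scorer] = 100.0 * rad / gmnn
        prolifs.append(100.0 * gmnn / tumour)
    if not valid or not scores:
        return Rad51Result(None, None, False, False, scores)
    score = mean(scores.values())
    return Rad51Result(
        proliferation_fraction=mean(prolifs),
        rad51_score=score,
        valid=True,
        hr_deficient=score < RAD51_DEFICIENCY_CUTOFF,
        per_scorer_scores=scores,
    )
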