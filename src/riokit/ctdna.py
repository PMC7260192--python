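"""Droplet digital PCR quantification and ctDNA dynamics (CDR15).

A ddPCR well partitions the template into ~15,000 droplets; the template
concentration follows from the fraction of positive droplets by Poisson
inversion, copies = -ln(1 - k/N) * N. Plasma concentrations pool the wells
run for a sample and divide by the plasma volume they represent.

The circulating-DNA ratio at day 15 (CDR15) is the end-of-treatment ctDNA
concentration divided by the baseline concentration, per tracked mutation,
combined across mutations by a baseline-copies-weighted mean. Only mutations
with at least ``min_baseline_droplets`` positive droplets at baseline are
evaluable; CDR15 below the suppression cutoff (default 0.25, strict)
classifies the patient as having suppressed ctDNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "DropletWell",
    "TimepointQuant",
    "CdrResult",
    "SaturationError",
    "quantify_well",
    "copies_per_ml",
    "dna_mass_ng",
    "cdr15",
    "read_droplet_csv",
    "cdr_table",
]

HAPLOID_GENOME_PG = 3.3  # mass of one haploid human genome ("c value"), pg


class SaturationError(ValueError):
    """All droplets positive: concentration is unbounded."""


@dataclass(frozen=True)
class DropletWell:
    positive_droplets: int
    total_droplets: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError(
                f"positive_droplets must lie in [0, {self.total_droplets}], "
                f"got {self.positive_droplets}"
            )


@dataclass
class TimepointQuant:
    """Quantification of one mutation assay at one timepoint."""

    mutation_id: str
    timepoint: Literal["baseline", "EOT"]
    wells: Sequence[DropletWell]
    plasma_ml_equivalent: float = 2.0
    copies_per_ml: float = field(init=False)
    total_positive_droplets: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.wells) == 0:
            raise ValueError("at least one well required")
        if self.plasma_ml_equivalent <= 0:
            raise ValueError("plasma_ml_equivalent must be positive")
        self.total_positive_droplets = sum(w.positive_droplets for w in self.wells)
        self.copies_per_ml = copies_per_ml(self)


@dataclass
class CdrResult:
    per_mutation_ratios: Mapping[str, float]
    weights: Mapping[str, float]
    cdr15: float | None
    evaluable: bool
    suppressed: bool
    cutoff: float = 0.25


def quantify_well(well: DropletWell) -> float:
    """Copies of template in one well by Poisson partition inversion."""
    k, n = well.positive_droplets, well.total_droplets
    if k == n:
        raise SaturationError(f"all {n} droplets positive; concentration unbounded")
    if k == 0:
        return 0.0
    return -math.log(1.0 - k / n) * n


def copies_per_ml(quant: TimepointQuant) -> float:
    """Pooled concentration: summed well copies over plasma ml represented."""
    return sum(quantify_well(w) for w in quant.wells) / quant.plasma_ml_equivalent


def dna_mass_ng(rpph1_copies_per_well: float) -> float:
    """DNA mass from copies of the single-copy RPPH1 reference: 3.3 pg per
    haploid genome copy, reported in ng."""
    if rpph1_copies_per_well < 0:
        raise ValueError("copies must be nonnegative")
    return rpph1_copies_per_well * HAPLOID_GENOME_PG * 1e-3


def cdr15(
    baseline: Sequence[TimepointQuant],
    eot: Sequence[TimepointQuant],
    cutoff: float = 0.25,
    min_baseline_droplets: int = 4,
) -> CdrResult:
    """Circulating-DNA ratio at day 15 across the tracked mutations.

    Mutations whose baseline wells total fewer than ``min_baseline_droplets``
    positive droplets are excluded. Remaining per-mutation ratios
    (EOT / baseline copies per ml) are combined by a weighted mean with
    weights proportional to baseline copies/ml, which is algebraically the
    pooled ratio sum(EOT) / sum(baseline). A patient with no evaluable
    mutation yields evaluable=False (not an error). Suppression is strict:
    cdr15 < cutoff.
    """
    base = {q.mutation_id: q for q in baseline}
    end = {q.mutation_id: q for q in eot}
    shared = [m for m in base if m in end]
    if not shared:
        raise ValueError("no mutation identifiers shared between baseline and EOT")
    ratios: dict[str, float] = {}
    weights_raw: dict[str, float] = {}
    for m in shared:
        if base[m].total_positive_droplets < min_baseline_droplets:
            continue
        ratios[m] = end[m].copies_per_ml / base[m].copies_per_ml
        weights_raw[m] = base[m].copies_per_ml
    if not ratios:
        return CdrResult({}, {}, None, evaluable=False, suppressed=False, cutoff=cutoff)
    total_w = sum(weights_raw.values())
    weights = {m: w / total_w for m, w in weights_raw.items()}
    value = sum(weights[m] * ratios[m] for m in ratios)
    return CdrResult(
        per_mutation_ratios=ratios,
        weights=weights,
        cdr15=value,
        evaluable=True,
        suppressed=value < cutoff,
        cutoff=cutoff,
    )


def read_droplet_csv(path) -> pd.DataFrame:
    """Read a droplet-count table (patient, mutation, timepoint, well,
    positive, total, plasma_ml)."""
    df = pd.read_csv(path)
    required = {"patient", "mutation", "timepoint", "well", "positive", "total", "plasma_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    return df


def read_tracked_mutations_vcf(path) -> pd.DataFrame:
    """Tracked mutations from a minimal (uncompressed) VCF.

    Returns a frame with chrom, pos, ref, alt and the sample name carried in
    the ID column (or '.'), one row per ALT allele."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append({
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                    "alt": alt, "sample": rec.id or ".",
                })
    return pd.DataFrame(rows)


def cdr_table(
    droplets: pd.DataFrame,
    cutoff: float = 0.25,
    min_baseline_droplets: int = 4,
) -> pd.DataFrame:
    """Per-patient CDR15 summary from a long-format droplet-count table."""
    rows = []
    for patient, pdf in droplets.groupby("patient", sort=True):
        quants: dict[str, list[TimepointQuant]] = {"baseline": [], "EOT": []}
        for (mutation, timepoint), mdf in pdf.groupby(["mutation", "timepoint"], sort=True):
            wells = [
                DropletWell(int(r.positive), int(r.total)) for r in mdf.itertuples()
            ]
            quants[timepoint].append(
                TimepointQuant(
                    mutation_id=str(mutation),
                    timepoint=timepoint,
                    wells=wells,
                    plasma_ml_equivalent=float(mdf["plasma_ml"].iloc[0]),
                )
            )
        result = cdr15(
            quants["baseline"], quants["EOT"],
            cutoff=cutoff, min_baseline_droplets=min_baseline_droplets,
        )
        rows.append(
            {
                "patient": patient,
                "n_mutations_evaluable": len(result.per_mutation_ratios),
                "cdr15": result.cdr15,
                "evaluable": result.evaluable,
                "suppressed": result.suppressed,
            }
        )
    return pd.DataFrame(rows)
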