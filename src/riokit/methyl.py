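"""Promoter methylation calling from merged bisulfite amplicon reads.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine at CpG sites is protected and remains C. A merged
amplicon read is therefore compared to the unconverted genomic top strand
with conversion-aware scoring: a read T opposite a reference C is a
potential conversion, not a mismatch.

Per-read workflow: global pairwise alignment (affine gaps, asymmetric
substitution matrix), QC filtering (identity >= 90%, at most 1 non-bisulfite
mismatch, complete conversion at non-CpG cytosines, every CpG column C or
T), then the methylation verdict: a read is methylated when strictly more
than 90% of its non-excluded CpG sites retain C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AmpliconReference",
    "ReadMethylationCall",
    "SampleMethylationResult",
    "BisulfiteAlignment",
    "bisulfite_align",
    "qc_filter",
    "call_read",
    "process_read",
    "summarize_sample",
    "read_fastq",
    "BRCA1_PRIMERS",
    "RAD51C_PRIMERS",
]

# Amplification primers for the two promoter assays (forward, reverse).
BRCA1_PRIMERS = ("TATTTTGAGAGGTTGCTGTTTAG", "CTAAAAAACCCCACAACCTATCCC")
RAD51C_PRIMERS = ("TGGTAATTGGTTAGTGTGTGT", "TCCTCATCAAATATACACCCTAACT")

RejectReason = Literal[
    "low_identity", "excess_mismatch", "incomplete_conversion", "degenerate_cpg", "none"
]


@dataclass(frozen=True)
class AmpliconReference:
    """Unconverted genomic top strand between primers, with its CpG map.

    ``cpg_positions`` are 0-based offsets of CpG cytosines; derived from the
    sequence when not supplied. ``excluded_sites`` are CpG positions omitted
    from the methylation verdict (e.g. sites constitutively methylated in
    every sample)."""

    name: str
    sequence: str
    cpg_positions: tuple[int, ...] = ()
    excluded_sites: tuple[int, ...] = ()
    primers: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("amplicon sequence is empty")
        if not self.cpg_positions:
            found = tuple(
                i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
            )
            object.__setattr__(self, "cpg_positions", found)
        for p in self.cpg_positions:
            if seq[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not a CpG cytosine in {self.name}")
        if not set(self.excluded_sites) <= set(self.cpg_positions):
            raise ValueError("excluded_sites must be a subset of cpg_positions")
        if not self.cpg_positions:
            raise ValueError(f"amplicon {self.name} has no CpG site")

    @property
    def included_cpg_positions(self) -> tuple[int, ...]:
        excl = set(self.excluded_sites)
        return tuple(p for p in self.cpg_positions if p not in excl)

    def converted(self, methylated: bool) -> str:
        """Bisulfite-converted top strand: every C becomes T except, when
        ``methylated``, the CpG cytosines."""
        keep = set(self.cpg_positions) if methylated else set()
        return "".join(
            "T" if b == "C" and i not in keep else b
            for i, b in enumerate(self.sequence)
        )


@dataclass
class BisulfiteAlignment:
    read_id: str
    aligned: bool
    identity: float
    non_bisulfite_mismatches: int
    unconverted_noncpg_c: int
    # read base (or '-' ) at each reference position, reference-indexed
    ref_to_read_base: dict[int, str] = field(default_factory=dict)


@dataclass
class ReadMethylationCall:
    read_id: str
    aligned: bool
    identity: float
    non_bisulfite_mismatches: int
    unconverted_noncpg_c: int
    cpg_total: int
    cpg_methylated: int
    passed_qc: bool
    methylated: bool
    reject_reason: RejectReason


@dataclass
class SampleMethylationResult:
    sample_id: str
    amplicon: str
    reads_total: int
    reads_passed: int
    methylated_reads: int
    methylated_fraction: float | None
    sample_positive: bool | None
    positivity_threshold: float


def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 1.0 if a == b else -1.0
    matrix["C", "T"] = 1.0  # reference C read as T: bisulfite conversion
    for x in "ACGTN":
        matrix["N", x] = 0.0
        matrix[x, "N"] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def bisulfite_align(
    read: str,
    amplicon: AmpliconReference,
    read_id: str = "read",
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    min_length_fraction: float = 0.30,
) -> BisulfiteAlignment:
    """Global conversion-aware alignment of a merged read to the amplicon.

    Identity counts a read T opposite a reference C as matching (potential
    conversion); all other substitutions are non-bisulfite mismatches.
    Identity is matching columns over the reference length. Reads shorter
    than ``min_length_fraction`` of the amplicon are rejected outright.
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    ref = amplicon.sequence
    if len(read) < min_length_fraction * len(ref):
        return BisulfiteAlignment(read_id, False, 0.0, 0, 0)
    if len(read) == len(ref):
        # Gapless comparison is the optimal global alignment whenever the
        # equal-length identity is high: under the default scoring a
        # mismatch (-1 vs +1) is always cheaper than the two gap opens
        # needed to avoid it. Skip the DP for these reads.
        shortcut = _gapless(read, ref, amplicon, read_id)
        if shortcut.identity >= 0.95:
            return shortcut
    alignment = _aligner(gap_open, gap_extend).align(ref, read)[0]
    ref_gapped, read_gapped = str(alignment[0]), str(alignment[1])
    cpg = set(amplicon.cpg_positions)
    matches = 0
    mismatches = 0
    unconverted = 0
    ref_to_read: dict[int, str] = {}
    ref_pos = 0
    for rb, qb in zip(ref_gapped, read_gapped):
        if rb != "-":
            ref_to_read[ref_pos] = qb
            if qb == "-":
                pass
            elif qb == rb or (rb == "C" and qb == "T"):
                matches += 1
                if rb == "C" and qb == "C" and ref_pos not in cpg:
                    unconverted += 1
            else:
                mismatches += 1
            ref_pos += 1
    identity = matches / len(ref)
    return BisulfiteAlignment(
        read_id, True, identity, mismatches, unconverted, ref_to_read
    )


def _gapless(
    read: str, ref: str, amplicon: AmpliconReference, read_id: str
) -> BisulfiteAlignment:
    cpg = set(amplicon.cpg_positions)
    matches = mismatches = unconverted = 0
    ref_to_read: dict[int, str] = {}
    for i, (rb, qb) in enumerate(zip(ref, read)):
        ref_to_read[i] = qb
        if qb == rb or (rb == "C" and qb == "T"):
            matches += 1
            if rb == "C" and qb == "C" and i not in cpg:
                unconverted += 1
        else:
            mismatches += 1
    return BisulfiteAlignment(
        read_id, True, matches / len(ref), mismatches, unconverted, ref_to_read
    )


def qc_filter(
    alignment: BisulfiteAlignment,
    amplicon: AmpliconReference,
    min_identity: float = 0.90,
    max_non_bisulfite_mismatches: int = 1,
    max_unconverted_noncpg_c: int = 0,
) -> RejectReason:
    """Apply the read QC cascade; returns the first failing reason or "none".

    Order: low_identity, excess_mismatch, incomplete_conversion,
    degenerate_cpg (any non-excluded CpG column that is neither C nor T).
    """
    if not alignment.aligned or alignment.identity < min_identity:
        return "low_identity"
    if alignment.non_bisulfite_mismatches > max_non_bisulfite_mismatches:
        return "excess_mismatch"
    if alignment.unconverted_noncpg_c > max_unconverted_noncpg_c:
        return "incomplete_conversion"
    included = amplicon.included_cpg_positions
    if not included:
        return "degenerate_cpg"
    for p in included:
        if alignment.ref_to_read_base.get(p, "-") not in ("C", "T"):
            return "degenerate_cpg"
    return "none"


def call_read(
    alignment: BisulfiteAlignment,
    amplicon: AmpliconReference,
    methylated_read_threshold: float = 0.90,
) -> tuple[int, int, bool]:
    """Count methylated CpG sites on a QC-passed read.

    A site is methylated iff the read retains C at the reference CpG
    cytosine; excluded sites are omitted from numerator and denominator.
    The read is methylated when the methylated fraction strictly exceeds
    ``methylated_read_threshold``. Returns (cpg_total, cpg_methylated,
    methylated)."""
    included = amplicon.included_cpg_positions
    total = len(included)
    if total == 0:
        raise ValueError("no CpG sites remain after exclusions")
    methylated_sites = sum(
        1 for p in included if alignment.ref_to_read_base.get(p) == "C"
    )
    verdict = methylated_sites / total > methylated_read_threshold
    return total, methylated_sites, verdict


def process_read(
    read: str,
    amplicon: AmpliconReference,
    read_id: str = "read",
    min_identity: float = 0.90,
    max_non_bisulfite_mismatches: int = 1,
    max_unconverted_noncpg_c: int = 0,
    methylated_read_threshold: float = 0.90,
) -> ReadMethylationCall:
    """Align, QC and call one merged read."""
    aln = bisulfite_align(read, amplicon, read_id=read_id)
    reason = qc_filter(
        aln, amplicon,
        min_identity=min_identity,
        max_non_bisulfite_mismatches=max_non_bisulfite_mismatches,
        max_unconverted_noncpg_c=max_unconverted_noncpg_c,
    )
    if reason != "none":
        return ReadMethylationCall(
            read_id, aln.aligned, aln.identity, aln.non_bisulfite_mismatches,
            aln.unconverted_noncpg_c, 0, 0, False, False, reason,
        )
    total, meth, verdict = call_read(aln, amplicon, methylated_read_threshold)
    return ReadMethylationCall(
        read_id, True, aln.identity, aln.non_bisulfite_mismatches,
        aln.unconverted_noncpg_c, total, meth, True, verdict, "none",
    )


def summarize_sample(
    calls: Iterable[ReadMethylationCall],
    sample_id: str = "sample",
    amplicon_name: str = "",
    positivity_threshold: float = 0.10,
    min_passed_reads: int = 100,
) -> SampleMethylationResult:
    """Sample-level methylation summary over per-read calls.

    The sample is positive when the methylated-read fraction reaches
    ``positivity_threshold`` and at least ``min_passed_reads`` reads passed
    QC; with zero passed reads the verdict is undefined (None)."""
    calls = list(calls)
    if not calls:
        raise ValueError("no reads supplied")
    passed = [c for c in calls if c.passed_qc]
    meth = sum(1 for c in passed if c.methylated)
    if passed:
        fraction = meth / len(passed)
        positive = fraction >= positivity_threshold and len(passed) >= min_passed_reads
    else:
        fraction = None
        positive = None
    return SampleMethylationResult(
        sample_id=sample_id,
        amplicon=amplicon_name,
        reads_total=len(calls),
        reads_passed=len(passed),
        methylated_reads=meth,
        methylated_fraction=fraction,
        sample_positive=positive,
        positivity_threshold=positivity_threshold,
    )


def read_fastq(path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def calls_to_frame(calls: Iterable[ReadMethylationCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
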