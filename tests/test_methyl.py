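"""Bisulfite amplicon alignment, QC and methylation-calling tests."""

import numpy as np
import pytest

from riokit.methyl import (
    AmpliconReference,
    bisulfite_align,
    call_read,
    process_read,
    qc_filter,
    summarize_sample,
)
from riokit.synth import simulate_bisulfite_reads

TOY = AmpliconReference(name="toy", sequence="ACGTACGTCCGATCGATTCGAA")
# CpG cytosines in TOY: positions of C followed by G


def gotoh_oracle(ref, read, gap_open=-2.0, gap_extend=-0.5):
    """Affine-gap global alignment score by explicit dynamic programming,
    with the bisulfite-aware substitution scores (ref C vs read T = match)."""
    def score(rb, qb):
        if qb == rb or (rb == "C" and qb == "T"):
            return 1.0
        return -1.0

    n, m = len(ref), len(read)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in read (ref consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in ref (read consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(ref[i - 1], read[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# -------------------------------------------------------------- alignment
def test_fully_converted_read_has_full_identity():
    aln = bisulfite_align(TOY.converted(False), TOY)
    assert aln.identity == pytest.approx(1.0)
    assert aln.non_bisulfite_mismatches == 0
    assert aln.unconverted_noncpg_c == 0


def test_non_bisulfite_substitutions_counted():
    seq = list(TOY.sequence)
    # two A->G substitutions at non-C positions
    positions = [i for i, b in enumerate(seq) if b == "A"][:2]
    for p in positions:
        seq[p] = "G"
    aln = bisulfite_align("".join(seq), TOY)
    assert aln.non_bisulfite_mismatches == 2


def test_unconverted_noncpg_cytosines_counted():
    # fully methylated template retains CpG C only; non-CpG C are errors here
    read = list(TOY.converted(True))
    noncpg_c = [i for i, b in enumerate(TOY.sequence)
                if b == "C" and i not in TOY.cpg_positions]
    read[noncpg_c[0]] = "C"
    aln = bisulfite_align("".join(read), TOY)
    assert aln.unconverted_noncpg_c == 1
    assert aln.non_bisulfite_mismatches == 0  # C matches reference C


def test_short_read_rejected():
    aln = bisulfite_align("ACG", TOY)
    assert not aln.aligned
    assert qc_filter(aln, TOY) == "low_identity"


def test_alignment_matches_affine_dp_oracle(rng):
    from riokit.methyl import _aligner

    aligner = _aligner(-2.0, -0.5)
    bases = "ACGT"
    for _ in range(60):
        n = int(rng.integers(6, 21))
        ref = "".join(bases[i] for i in rng.integers(0, 4, size=n))
        if "CG" not in ref:
            ref = ref[:2] + "CG" + ref[4:]
        read = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(0, len(read)))
            read[p] = bases[int(rng.integers(0, 4))]
        if rng.random() < 0.5 and len(read) > 8:
            p = int(rng.integers(0, len(read) - 2))
            del read[p : p + int(rng.integers(1, 3))]
        read = "".join(read)
        assert aligner.score(ref, read) == pytest.approx(
            gotoh_oracle(ref, read), abs=1e-9
        )


# --------------------------------------------------------------------- qc
def test_qc_reject_order_and_reasons():
    good = bisulfite_align(TOY.converted(False), TOY)
    assert qc_filter(good, TOY) == "none"

    # low identity dominates
    bad = bisulfite_align("T" * len(TOY.sequence), TOY)
    if bad.identity < 0.90:
        assert qc_filter(bad, TOY) == "low_identity"

    # two non-bisulfite mismatches with high identity
    seq = list(TOY.converted(False))
    a_positions = [i for i, b in enumerate(TOY.sequence) if b == "A"][:2]
    for p in a_positions:
        seq[p] = "G"
    two_mm = bisulfite_align("".join(seq), TOY)
    assert two_mm.identity >= 0.90
    assert qc_filter(two_mm, TOY) == "excess_mismatch"

    # one unconverted non-CpG cytosine, default tolerance 0
    seq = list(TOY.converted(False))
    noncpg_c = [i for i, b in enumerate(TOY.sequence)
                if b == "C" and i not in TOY.cpg_positions][0]
    seq[noncpg_c] = "C"
    unconv = bisulfite_align("".join(seq), TOY)
    assert qc_filter(unconv, TOY) == "incomplete_conversion"
    assert qc_filter(unconv, TOY, max_unconverted_noncpg_c=1) == "none"

    # a CpG site read as neither C nor T
    seq = list(TOY.converted(False))
    seq[TOY.cpg_positions[0]] = "A"
    degen = bisulfite_align("".join(seq), TOY)
    assert qc_filter(degen, TOY) == "degenerate_cpg"


def test_qc_identity_threshold_is_090():
    aln = bisulfite_align(TOY.converted(False), TOY)
    aln.identity = 0.89
    assert qc_filter(aln, TOY) == "low_identity"


# ------------------------------------------------------------------ calls
def ten_cpg_amplicon():
    seq = "AT" + "CGTA" * 10 + "TT"  # exactly 10 CpG sites
    return AmpliconReference(name="ten", sequence=seq)


def test_read_methylated_only_above_90pct_of_sites():
    amp = ten_cpg_amplicon()
    fully = process_read(amp.converted(True), amp)
    assert fully.cpg_total == 10 and fully.cpg_methylated == 10
    assert fully.methylated

    # convert exactly one CpG site: 9/10 = 0.90 is NOT > 0.90
    read = list(amp.converted(True))
    read[amp.cpg_positions[0]] = "T"
    nine = process_read("".join(read), amp)
    assert nine.cpg_methylated == 9
    assert not nine.methylated


def test_excluded_sites_dropped_from_both_sides():
    amp = ten_cpg_amplicon()
    excl = AmpliconReference(
        name="excl", sequence=amp.sequence, excluded_sites=amp.cpg_positions[:2]
    )
    # both excluded sites methylated, 9 of remaining 10... construct 12-site case
    seq = "AT" + "CGTA" * 12 + "TT"
    amp12 = AmpliconReference(name="t12", sequence=seq)
    excl12 = AmpliconReference(
        name="t12e", sequence=seq, excluded_sites=amp12.cpg_positions[:2]
    )
    read = list(excl12.converted(True))  # all 12 sites C
    read[excl12.cpg_positions[2]] = "T"  # 9/10 included sites methylated
    aln = bisulfite_align("".join(read), excl12)
    total, meth, verdict = call_read(aln, excl12)
    assert (total, meth) == (10, 9)
    assert not verdict


def test_all_sites_excluded_is_degenerate():
    amp = ten_cpg_amplicon()
    full_excl = AmpliconReference(
        name="all", sequence=amp.sequence, excluded_sites=amp.cpg_positions
    )
    aln = bisulfite_align(full_excl.converted(True), full_excl)
    with pytest.raises(ValueError):
        call_read(aln, full_excl)
    assert qc_filter(aln, full_excl) == "degenerate_cpg"


def test_amplicon_validation():
    with pytest.raises(ValueError):
        AmpliconReference(name="bad", sequence="ATATAT")  # no CpG
    with pytest.raises(ValueError):
        AmpliconReference(name="bad", sequence="ACGT", cpg_positions=(3,))


# --------------------------------------------------------- sample summary
def test_summary_fraction_and_positivity():
    amp = ten_cpg_amplicon()
    meth_calls = [process_read(amp.converted(True), amp, read_id=f"m{i}") for i in range(120)]
    conv_calls = [process_read(amp.converted(False), amp, read_id=f"u{i}") for i in range(120)]
    all_meth = summarize_sample(meth_calls)
    assert all_meth.methylated_fraction == 1.0 and all_meth.sample_positive
    none_meth = summarize_sample(conv_calls)
    assert none_meth.methylated_fraction == 0.0 and not none_meth.sample_positive
    # below the minimum read depth the verdict cannot be positive
    shallow = summarize_sample(meth_calls[:50])
    assert shallow.sample_positive is False or shallow.sample_positive is None


def test_summary_invariant_to_read_order(rng):
    amp = ten_cpg_amplicon()
    calls = [process_read(amp.converted(i % 3 == 0), amp, read_id=f"r{i}") for i in range(30)]
    shuffled = list(calls)
    rng.shuffle(shuffled)
    a = summarize_sample(calls, min_passed_reads=10)
    b = summarize_sample(shuffled, min_passed_reads=10)
    assert (a.methylated_reads, a.reads_passed, a.sample_positive) == (
        b.methylated_reads, b.reads_passed, b.sample_positive
    )


# --------------------------------------------- simulation round trips
def test_errorfree_fully_methylated_reads_all_called(brca1, rng):
    reads = simulate_bisulfite_reads(brca1, 1.0, 100, 0.0, 0.0, rng)
    calls = [process_read(seq, brca1, read_id=rid) for rid, seq in reads]
    assert all(c.passed_qc and c.methylated for c in calls)


def test_errorfree_converted_reads_never_called(brca1, rng):
    reads = simulate_bisulfite_reads(brca1, 0.0, 100, 0.0, 0.0, rng)
    calls = [process_read(seq, brca1, read_id=rid) for rid, seq in reads]
    assert all(c.passed_qc for c in calls)
    assert not any(c.methylated for c in calls)


def test_called_fraction_tracks_simulated_fraction(brca1, rng):
    frac, n = 0.3, 2000
    reads = simulate_bisulfite_reads(brca1, frac, n, 0.001, 0.001, rng)
    calls = [process_read(seq, brca1, read_id=rid) for rid, seq in reads]
    res = summarize_sample(calls, sample_id="s", amplicon_name="BRCA1")
    se = np.sqrt(frac * (1 - frac) / res.reads_passed)
    assert abs(res.methylated_fraction - frac) < 3 * se


def test_conversion_errors_never_increase_pass_rate(brca1, rng):
    n = 2000
    passed = []
    for rate in (0.0, 0.05):
        reads = simulate_bisulfite_reads(brca1, 0.5, n, rate, 0.0, rng)
        calls = [process_read(seq, brca1, read_id=rid) for rid, seq in reads]
        passed.append(sum(c.passed_qc for c in calls))
    assert passed[1] <= passed[0]
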