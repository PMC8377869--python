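import random

import pytest

from ampdel.align import (
    Alignment,
    Read,
    Scoring,
    affine_align,
    align_read,
    merge_deletions,
    normalize_ops,
    read_alignments,
    validate_alignment,
    write_alignments,
)
from ampdel.dna import revcomp

SC = Scoring()


def brute_force_overlap_score(read, ref, sc=SC):
    """Plain three-matrix affine DP, unbanded, free end gaps both sides.

    Independent oracle for the production aligner: no banding, no
    traceback, direct recurrences.
    """
    m, n = len(read), len(ref)
    NEG = -1e9
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming ref
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming read
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(m + 1):
        H[i][0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1], H[i][j - 1] + sc.gap_open) + sc.gap_extend
            F[i][j] = max(F[i - 1][j], H[i - 1][j] + sc.gap_open) + sc.gap_extend
            s = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(
        max(H[m][j] for j in range(n + 1)), max(H[i][n] for i in range(m + 1))
    )


def mutate(ref, rng, n_events):
    read = list(ref)
    for _ in range(n_events):
        if not read:
            break
        k = rng.randrange(len(read))
        op = rng.choice(["sub", "ins", "del"])
        if op == "sub":
            read[k] = rng.choice("ACGT")
        elif op == "ins":
            read.insert(k, rng.choice("ACGT"))
        elif len(read) > 5:
            del read[k : k + rng.randint(1, 5)]
    return "".join(read)


def test_identity_alignment():
    seq = "ACGTTGCAACGTTGCAACGT"
    score, rs, ops = affine_align(seq, seq)
    assert (score, rs, ops) == (2 * len(seq), 0, [("=", len(seq))])


def test_substring_alignment():
    rng = random.Random(1)
    ref = "".join(rng.choice("ACGT") for _ in range(400))
    score, rs, ops = affine_align(ref[100:300], ref)
    assert rs == 100 and ops == [("=", 200)] and score == 400


def test_central_excision_is_single_deletion():
    rng = random.Random(2)
    ref = "".join(rng.choice("ACGT") for _ in range(60))
    read = ref[:20] + ref[40:]
    score, rs, ops = affine_align(read, ref)
    assert ops == [("=", 20), ("D", 20), ("=", 20)]
    assert score == 80 + SC.gap_cost(20)


def test_score_matches_bruteforce_oracle_on_random_indel_pairs():
    rng = random.Random(42)
    for _ in range(200):
        n = rng.randint(10, 60)
        ref = "".join(rng.choice("ACGT") for _ in range(n))
        read = mutate(ref, rng, rng.randint(0, 4))
        if not read:
            continue
        score, _, _ = affine_align(read, ref)
        assert score == pytest.approx(brute_force_overlap_score(read, ref))


def test_banded_equals_unbanded_when_band_covers_matrix():
    rng = random.Random(3)
    ref = "".join(rng.choice("ACGT") for _ in range(80))
    read = ref[:30] + ref[50:]
    s1, r1, o1 = affine_align(read, ref)
    s2, r2, o2 = affine_align(read, ref, band_width=3000)
    assert (s1, r1, o1) == (s2, r2, o2)


def test_strand_symmetry(small_amplicon):
    ref = small_amplicon
    read_seq = ref.sequence[:500] + ref.sequence[800:]
    fwd = align_read(Read("f", read_seq), ref, strand="both")
    rev = align_read(Read("r", revcomp(read_seq)), ref, strand="both")
    assert fwd.strand == "+" and rev.strand == "-"
    assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)
    assert merge_deletions(fwd) == merge_deletions(rev)


def test_engines_agree_on_large_deletion(small_amplicon):
    ref = small_amplicon
    read_seq = ref.sequence[:500] + ref.sequence[700:]
    a_fast = align_read(Read("x", read_seq), ref, strand="+")
    a_dp = align_read(Read("x", read_seq), ref, strand="+", engine="affine")
    ev_fast, ev_dp = merge_deletions(a_fast), merge_deletions(a_dp)
    # co-optimal paths may shift a deletion within a repeat by a few bases
    assert [e.deleted_bp for e in ev_fast] == [e.deleted_bp for e in ev_dp]
    assert abs(ev_fast[0].ref_start - ev_dp[0].ref_start) <= 5
    assert a_fast.score == a_dp.score


def test_empty_read_unaligned(small_amplicon):
    assert align_read(Read("e", ""), small_amplicon) is None


def test_garbage_read_unaligned(small_amplicon):
    rng = random.Random(9)
    junk = "".join(rng.choice("ACGT") for _ in range(300))
    # unrelated sequence scores below the acceptance threshold
    assert align_read(Read("junk", junk), small_amplicon, strand="+") is None


def test_alignment_bookkeeping_on_noisy_reads(small_amplicon, error_model, rng):
    from ampdel import dna
    from ampdel.errors import apply_errors

    codes = dna.encode(small_amplicon.sequence)
    for i in range(20):
        noisy = dna.decode(apply_errors(codes, error_model, rng))
        aln = align_read(Read(f"n{i}", noisy), small_amplicon, strand="+")
        validate_alignment(aln, len(noisy), small_amplicon.length)


# ---------------------------------------------------------------------------
# merge_deletions
# ---------------------------------------------------------------------------


def make_aln(ops, ref_start=0):
    return Alignment("r", "ref", ref_start, "+", normalize_ops(ops))


def test_merge_nearby_deletions_sums_deleted_bases():
    aln = make_aln([("=", 100), ("D", 60), ("=", 5), ("D", 50), ("=", 100)])
    events = merge_deletions(aln, merge_gap=10)
    assert len(events) == 1
    assert events[0].deleted_bp == 110
    assert (events[0].ref_start, events[0].ref_end) == (100, 215)


def test_distant_deletions_stay_separate():
    aln = make_aln([("=", 100), ("D", 60), ("=", 50), ("D", 50), ("=", 100)])
    events = merge_deletions(aln, merge_gap=10)
    assert [e.deleted_bp for e in events] == [60, 50]


def test_no_deletions_no_events():
    assert merge_deletions(make_aln([("=", 500)])) == []


def test_insertions_do_not_break_merging():
    aln = make_aln([("=", 10), ("D", 30), ("I", 40), ("D", 30), ("=", 10)])
    events = merge_deletions(aln, merge_gap=10)
    assert len(events) == 1 and events[0].deleted_bp == 60


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------


def test_sam_round_trip(tmp_path, small_amplicon):
    ref = small_amplicon
    read_seq = ref.sequence[100:500] + ref.sequence[700:1100]
    aln = align_read(Read("rt", read_seq), ref, strand="+")
    path = str(tmp_path / "out.sam")
    write_alignments([aln], path, {ref.name: ref.length}, sequences={"rt": read_seq})
    back, summary = read_alignments(path, references={ref.name: ref.sequence})
    assert summary["primary"] == 1
    b = back[0]
    assert (b.ref_start, b.strand, b.ops) == (aln.ref_start, aln.strand, aln.ops)


def test_sam_hard_clip_read_as_softclip_accounting(tmp_path):
    sam = tmp_path / "h.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n"
        "r1\t0\tref\t11\t60\t5H20M\t*\t0\t0\t*\t*\n"
    )
    alns, _ = read_alignments(str(sam))
    assert alns[0].ops == [("S", 5), ("=", 20)]
    assert alns[0].ref_start == 10  # SAM POS is 1-based


def test_sam_unmapped_and_secondary_counted_not_returned(tmp_path):
    sam = tmp_path / "u.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n"
        "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        "r2\t256\tref\t1\t0\t4M\t*\t0\t0\tACGT\t*\n"
        "r3\t0\tref\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
    )
    alns, summary = read_alignments(str(sam))
    assert [a.read_id for a in alns] == ["r3"]  # secondary/unmapped excluded
    assert summary["unmapped"] == 1 and summary["secondary"] == 1
    assert summary["primary"] == 1
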