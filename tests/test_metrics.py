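import numpy as np
import pytest

from ampdel.align import Alignment, DeletionEvent, normalize_ops
from ampdel.metrics import (
    compute_metrics,
    coverage_profile,
    deletion_index,
    deplete_hdr,
    dx_fractions,
    loh_check,
    raw_deletion,
    read_base_at,
    subtract_background,
)
from ampdel.references import Snp, build_reference


def full_read(rid, length, ref_name="locusA"):
    return Alignment(rid, ref_name, 0, "+", [("=", length)])


def del_read(rid, length, del_start, del_len, ref_name="locusA"):
    ops = normalize_ops(
        [("=", del_start), ("D", del_len), ("=", length - del_start - del_len)]
    )
    return Alignment(rid, ref_name, 0, "+", ops)


@pytest.fixture(scope="module")
def ref5k():
    return build_reference(5000, seed=1, cut_site=2500, name="locusA")


def test_uniform_full_coverage(ref5k):
    alns = [full_read(f"r{i}", 5000) for i in range(100)]
    prof = coverage_profile(alns, ref5k, total_reads=100)
    assert (prof.depth == 100).all()
    assert prof.mean_depth == 100
    assert raw_deletion(prof) == 0.0


def test_half_coverage_read(ref5k):
    aln = Alignment("r", "locusA", 0, "+", [("=", 2500), ("S", 10)])
    prof = coverage_profile([aln], ref5k, total_reads=1)
    assert prof.mean_depth == pytest.approx(0.5)


def test_deletion_reads_reduce_mean_depth(ref5k):
    # 10,000 reads, 20% with a 1000 bp deletion on a 5000 bp amplicon:
    # covered bases = 8000*5000 + 2000*4000 -> mean depth 9600
    alns = [full_read(f"f{i}", 5000) for i in range(8000)]
    alns += [del_read(f"d{i}", 5000, 2000, 1000) for i in range(2000)]
    prof = coverage_profile(alns, ref5k, total_reads=10000)
    assert prof.mean_depth == pytest.approx(9600)
    assert raw_deletion(prof) == pytest.approx(4.0)


def test_raw_deletion_formula(ref5k):
    alns = [full_read(f"f{i}", 5000) for i in range(900)]
    prof = coverage_profile(alns, ref5k, total_reads=1000)
    assert raw_deletion(prof) == pytest.approx(10.0)
    assert raw_deletion(prof, aligned_only=True) == pytest.approx(0.0)


def test_raw_deletion_undefined_for_zero_reads(ref5k):
    prof = coverage_profile([], ref5k, total_reads=0)
    with pytest.raises(ValueError):
        raw_deletion(prof)


def test_alignment_beyond_reference_is_hard_error(ref5k):
    bad = Alignment("r", "locusA", 4500, "+", [("=", 1000)])
    with pytest.raises(ValueError):
        coverage_profile([bad], ref5k, total_reads=1)


def test_deletion_index_preserves_negative_values():
    assert deletion_index(10.0, 3.3) == pytest.approx(6.7)
    assert deletion_index(5.0, 5.0) == 0.0
    assert deletion_index(4.0, 4.3) == pytest.approx(-0.3)


def test_dx_strict_threshold_rule():
    events = {f"d{i}": [DeletionEvent(2000, 3000, 1000)] for i in range(200)}
    events.update({f"f{i}": [] for i in range(800)})
    dx = dx_fractions(events, total_reads=1000)
    assert dx[100] == pytest.approx(0.20)
    assert dx[500] == pytest.approx(0.20)
    assert dx[1000] == 0.0  # strictly greater than the threshold
    assert dx[2000] == 0.0


def test_dx_monotone_nonincreasing(rng):
    events = {}
    for i in range(500):
        k = int(rng.integers(0, 3))
        events[f"r{i}"] = [
            DeletionEvent(0, d, d) for d in rng.integers(10, 2500, size=k)
        ]
    dx = dx_fractions(events, total_reads=600)
    vals = [dx[t] for t in sorted(dx)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_unaligned_reads_stay_in_denominator(ref5k):
    alns = [del_read(f"d{i}", 5000, 2000, 1000) for i in range(10)]
    m = compute_metrics(alns, ref5k, total_reads=20)
    assert m.dx_raw[100] == pytest.approx(0.5)
    assert m.aligned_reads == 10 and m.total_reads == 20


def test_hdr_depletion_worked_example(ref5k):
    """1000 reads: 400 HDR full-length, 60 with a 1 kb deletion, 540
    unmodified -> full raw deletion 1.2%, HDR-depleted 2.0%."""
    alns = [full_read(f"h{i}", 5000) for i in range(400)]
    alns += [del_read(f"d{i}", 5000, 2000, 1000) for i in range(60)]
    alns += [full_read(f"u{i}", 5000) for i in range(540)]
    calls = {a.read_id: ("hdr" if a.read_id.startswith("h") else "unmodified") for a in alns}
    full = compute_metrics(alns, ref5k, total_reads=1000)
    assert full.raw_deletion_pct == pytest.approx(1.2)
    depleted = deplete_hdr(alns, calls, ref5k, total_reads=1000)
    assert depleted.raw_deletion_pct == pytest.approx(2.0)
    assert depleted.total_reads == 600


def test_hdr_depletion_noop_without_hdr(ref5k):
    alns = [full_read(f"u{i}", 5000) for i in range(50)]
    calls = {a.read_id: "unmodified" for a in alns}
    depleted = deplete_hdr(alns, calls, ref5k, total_reads=50)
    assert depleted.raw_deletion_pct == compute_metrics(alns, ref5k, 50).raw_deletion_pct


def test_hdr_depletion_all_hdr_is_error(ref5k):
    alns = [full_read("h0", 5000)]
    with pytest.raises(ValueError):
        deplete_hdr(alns, {"h0": "hdr"}, ref5k, total_reads=1)


def test_subtract_background_fills_index_fields(ref5k):
    ed = compute_metrics(
        [del_read(f"d{i}", 5000, 2000, 1000) for i in range(20)]
        + [full_read(f"f{i}", 5000) for i in range(80)],
        ref5k,
        100,
    )
    wt = compute_metrics([full_read(f"w{i}", 5000) for i in range(100)], ref5k, 100)
    subtract_background(ed, wt)
    assert ed.deletion_index_pct == pytest.approx(ed.raw_deletion_pct)
    assert ed.dx_index[100] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# LOH
# ---------------------------------------------------------------------------


def loh_input(ref, n_ref, n_alt, snp_pos):
    pairs = []
    alt_seq = ref.sequence[:snp_pos] + "T" + ref.sequence[snp_pos + 1 :]
    for i in range(n_ref):
        pairs.append((full_read(f"a{i}", ref.length, ref.name), ref.sequence))
    for i in range(n_alt):
        pairs.append((full_read(f"b{i}", ref.length, ref.name), alt_seq))
    return pairs


@pytest.fixture(scope="module")
def snp_ref():
    ref = build_reference(2000, seed=5, cut_site=1000, name="snp_amp")
    pos = 1200
    base = ref.sequence[pos]
    assert base != "T"
    return ref, Snp(pos, base, "T", "rs_test")


def test_loh_balanced_counts_heterozygous(snp_ref):
    ref, snp = snp_ref
    rep = loh_check(loh_input(ref, 50, 50, snp.position), (snp,))
    assert rep.verdict == "heterozygous_retained"
    assert rep.snps[0].ref_count == 50 and rep.snps[0].alt_count == 50


def test_loh_monoallelic_suspected(snp_ref):
    ref, snp = snp_ref
    rep = loh_check(loh_input(ref, 100, 0, snp.position), (snp,))
    assert rep.verdict == "loh_suspected"


def test_loh_boundary_inclusive(snp_ref):
    ref, snp = snp_ref
    rep = loh_check(loh_input(ref, 80, 20, snp.position), (snp,), het_threshold=0.2)
    assert rep.verdict == "heterozygous_retained"


def test_loh_uninformative_below_min_reads(snp_ref):
    ref, snp = snp_ref
    rep = loh_check(loh_input(ref, 5, 5, snp.position), (snp,), min_reads=20)
    assert rep.verdict == "uninformative"


def test_loh_no_snps_uninformative(snp_ref):
    ref, _ = snp_ref
    assert loh_check([], ()).verdict == "uninformative"


def test_read_base_skips_deletion_spanned_positions(snp_ref):
    ref, snp = snp_ref
    aln = del_read("d", ref.length, snp.position - 50, 100, ref.name)
    assert read_base_at(aln, ref.sequence[:-100], snp.position) is None
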