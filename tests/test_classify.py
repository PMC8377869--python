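import pytest

from ampdel.align import Read, align_read
from ampdel.alleles import DSODN_34, HDR_INSERT_18
from ampdel.classify import EditTemplates, classify_read, tabulate_edits
from ampdel.dna import revcomp


def call_for(ref, read_seq, templates=EditTemplates()):
    aln = align_read(Read("r", read_seq), ref, strand="+")
    assert aln is not None
    return classify_read(aln, read_seq, ref, templates)


@pytest.fixture(scope="module")
def ref(amplicon):
    return amplicon[0]


@pytest.fixture(scope="module")
def mmej_start(amplicon):
    return amplicon[1]


def test_reference_read_is_unmodified(ref):
    assert call_for(ref, ref.sequence).category == "unmodified"


def test_substitution_only_read_is_unmodified(ref):
    cut = ref.cut_site
    base = "A" if ref.sequence[cut] != "A" else "G"
    seq = ref.sequence[:cut] + base + ref.sequence[cut + 1 :]
    assert call_for(ref, seq).category == "unmodified"


def test_plus_a_insertion_signature(ref):
    cut = ref.cut_site
    seq = ref.sequence[:cut] + "A" + ref.sequence[cut:]
    call = call_for(ref, seq)
    assert call.category == "nhej_small_indel"
    assert call.signature == "+A"
    assert call.net_indel_bp == 1


def test_mmej_deletion_signature(ref, mmej_start):
    seq = ref.sequence[:mmej_start] + ref.sequence[mmej_start + 25 :]
    call = call_for(ref, seq)
    assert call.category == "nhej_small_indel"
    assert call.signature == "-25"


def test_small_deletion_without_signature(ref):
    cut = ref.cut_site
    seq = ref.sequence[: cut - 3] + ref.sequence[cut + 4 :]
    call = call_for(ref, seq)
    assert call.category == "nhej_small_indel"
    assert call.signature == ""
    assert call.net_indel_bp == -7


def test_hdr_insert_detected(ref):
    cut = ref.cut_site
    seq = ref.sequence[:cut] + HDR_INSERT_18 + ref.sequence[cut:]
    call = call_for(ref, seq)
    assert call.category == "hdr"
    assert call.insert_identity == pytest.approx(1.0)


def test_dsodn_orientations_distinguished(ref):
    cut = ref.cut_site
    fwd = ref.sequence[:cut] + DSODN_34 + ref.sequence[cut:]
    rev = ref.sequence[:cut] + revcomp(DSODN_34) + ref.sequence[cut:]
    assert call_for(ref, fwd).category == "dsodn_forward"
    assert call_for(ref, rev).category == "dsodn_reverse"


def test_large_deletion_dominates(ref):
    cut = ref.cut_site
    seq = ref.sequence[: cut - 400] + ref.sequence[cut + 400 :]
    call = call_for(ref, seq)
    assert call.category == "large_deletion"
    assert call.net_indel_bp == -800


def test_hdr_takes_precedence_over_large_deletion(ref):
    # HDR insert at the cut plus an unrelated distal kilobase deletion:
    # template match (rule 1) wins by precedence
    cut = ref.cut_site
    seq = ref.sequence[:cut] + HDR_INSERT_18 + ref.sequence[cut:3500] + ref.sequence[4500:]
    assert call_for(ref, seq).category == "hdr"


def test_indel_far_from_cut_is_ignored(ref):
    cut = ref.cut_site
    seq = ref.sequence[: cut - 300] + ref.sequence[cut - 298 :]  # -2 bp, 300 bp away
    assert call_for(ref, seq).category == "unmodified"


def test_window_outside_reference_rejected(small_amplicon):
    from ampdel.align import Alignment

    aln = Alignment("r", small_amplicon.name, 0, "+", [("=", small_amplicon.length)])
    bad = EditTemplates(window_halfwidth=700)
    with pytest.raises(ValueError):
        classify_read(aln, small_amplicon.sequence, small_amplicon, bad)


# ---------------------------------------------------------------------------
# tabulate_edits
# ---------------------------------------------------------------------------


def test_tabulate_partitions_and_totals(ref):
    cut = ref.cut_site
    seqs = (
        [ref.sequence] * 5
        + [ref.sequence[:cut] + HDR_INSERT_18 + ref.sequence[cut:]] * 3
        + [ref.sequence[:cut] + "A" + ref.sequence[cut:]] * 2
    )
    calls = [call_for(ref, s) for s in seqs]
    summary = tabulate_edits(calls)
    assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert summary.hdr_pct == pytest.approx(30.0)
    assert summary.nhej_pct == pytest.approx(20.0)
    assert summary.total_editing_pct == pytest.approx(50.0)
    assert summary.plusA_pct == pytest.approx(20.0)


def test_tabulate_all_unmodified(ref):
    calls = [call_for(ref, ref.sequence) for _ in range(3)]
    s = tabulate_edits(calls)
    assert s.total_editing_pct == 0.0


def test_tabulate_empty_rejected():
    with pytest.raises(ValueError):
        tabulate_edits([])
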