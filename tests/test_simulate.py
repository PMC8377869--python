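import collections

import numpy as np
import pytest

from ampdel.alleles import build_allele_table, preset_weights
from ampdel.dna import revcomp
from ampdel.errors import ZERO_ERROR, ErrorModel
from ampdel.simulate import (
    EditScenario,
    simulate_qpcr_plate,
    simulate_reads,
    write_fastq,
    write_truth,
)
from ampdel.alleles import allele_sequence


def scenario(ref, weights, n, seed, mmej_start=None, **kw):
    table = build_allele_table(weights, ref, seed=1, mmej_deletion_start=mmej_start)
    return EditScenario(reference=ref, alleles=table, n_reads=n, seed=seed, **kw)


def test_zero_reads(small_amplicon):
    reads, truth = simulate_reads(scenario(small_amplicon, {"unmodified": 1}, 0, 5), ZERO_ERROR)
    assert reads == [] and truth == []


def test_empty_allele_table_rejected(small_amplicon):
    sc = EditScenario(reference=small_amplicon, alleles=[], n_reads=5, seed=1)
    with pytest.raises(ValueError):
        simulate_reads(sc, ZERO_ERROR)


def test_zero_error_reads_reconstruct_alleles_exactly(amplicon):
    ref, mmej_start = amplicon
    sc = scenario(ref, preset_weights("RNP"), 60, 9, mmej_start=mmej_start)
    reads, truth = simulate_reads(sc, ZERO_ERROR, barcode="ACGTACGTAC")
    by_class = {}
    for a in sc.alleles:
        by_class.setdefault(a.allele_class, []).append(
            "ACGTACGTAC" + allele_sequence(ref, a)
        )
    assert len(reads) == 60
    for read, t in zip(reads, truth):
        expected = by_class[t.allele_class]
        assert read.sequence in expected or revcomp(read.sequence) in expected


def test_byte_determinism(tmp_path, amplicon, error_model):
    ref, _ = amplicon
    paths = []
    for run in ("a", "b"):
        sc = scenario(ref, preset_weights("RNP"), 50, 33, label="det")
        reads, truth = simulate_reads(sc, error_model, barcode="ACGTACGTAC")
        fq = tmp_path / f"{run}.fastq"
        tv = tmp_path / f"{run}.tsv"
        write_fastq(reads, fq)
        write_truth(truth, tv)
        paths.append((fq.read_bytes(), tv.read_bytes()))
    assert paths[0] == paths[1]


def test_truth_fractions_converge_to_configured(amplicon, error_model):
    ref, mmej_start = amplicon
    weights = preset_weights("RNP")
    sc = scenario(ref, weights, 8000, 17, mmej_start=mmej_start)
    _, truth = simulate_reads(sc, error_model)
    counts = collections.Counter(t.allele_class for t in truth)
    n = len(truth)
    total_w = sum(weights.values())
    for cls, w in weights.items():
        f = w / total_w
        ci = 1.96 * np.sqrt(f * (1 - f) / n)
        assert abs(counts[cls] / n - f) < max(ci, 0.01) * 1.6, cls


def test_strand_flip_rate(amplicon):
    ref, _ = amplicon
    sc = scenario(ref, {"unmodified": 1}, 1000, 3)
    reads, _ = simulate_reads(sc, ZERO_ERROR)
    fwd = sum(1 for r in reads if r.sequence == ref.sequence)
    rev = sum(1 for r in reads if r.sequence == revcomp(ref.sequence))
    assert fwd + rev == 1000
    assert 420 < fwd < 580  # binomial(1000, 0.5) within ~5 SD


def test_truncated_fraction_knob(amplicon):
    ref, _ = amplicon
    sc = scenario(ref, {"unmodified": 1}, 400, 3, truncated_fraction=0.5)
    reads, _ = simulate_reads(sc, ZERO_ERROR)
    short = sum(1 for r in reads if len(r.sequence) < ref.length)
    assert 120 < short < 280


# ---------------------------------------------------------------------------
# qPCR plate
# ---------------------------------------------------------------------------


def test_qpcr_plate_noise_free_ct_shift():
    plate = simulate_qpcr_plate(
        {"WT": {"40kb": 2}, "clone": {"40kb": 1}}, base_ct=25.0, noise_sd=0.0
    )
    wt = plate[(plate.sample_id == "WT")].target_ct.unique()
    cl = plate[(plate.sample_id == "clone")].target_ct.unique()
    assert wt == pytest.approx([25.0])
    assert cl == pytest.approx([26.0])  # one copy lost -> one cycle later


def test_qpcr_plate_zero_copy_flag():
    plate = simulate_qpcr_plate({"clone": {"40kb": 0}}, noise_sd=0.0)
    assert plate.at_detection_limit.all()
    assert (plate.target_ct == 40.0).all()


def test_qpcr_plate_seeded_determinism():
    kw = dict(base_ct=25.0, noise_sd=0.3, seed=12)
    a = simulate_qpcr_plate({"WT": {"40kb": 2, "80kb": 2}}, **kw)
    b = simulate_qpcr_plate({"WT": {"40kb": 2, "80kb": 2}}, **kw)
    assert a.equals(b)


def test_qpcr_plate_rejects_bad_copies():
    with pytest.raises(ValueError):
        simulate_qpcr_plate({"c": {"40kb": 3}})
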