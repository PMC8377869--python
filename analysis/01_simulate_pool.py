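#!/usr/bin/env python
"""Simulate a pooled long-amplicon nanopore run.

One 5 kb amplicon (heterozygous SNPs annotated, MMEJ microhomology at
the cut), seven barcoded samples: unedited WT, RNP alone, the three
deletion-sparing interventions (ssODN, dsODN, AAV donors) and NHEJ
inhibition (M3814).  Writes the pooled FASTQ, per-read ground truth,
reference FASTA + annotation sidecar, barcode table and a run config
under results/sim/.
"""

import argparse
import json
from pathlib import Path

from ampdel.alleles import build_allele_table, preset_weights
from ampdel.demux import make_barcodes
from ampdel.errors import ErrorModel
from ampdel.references import Snp, build_reference, plant_microhomology, write_references
from ampdel.simulate import EditScenario, simulate_reads, write_fastq, write_truth

LABELS = ["WT", "RNP", "RNP+ssODN", "RNP+dsODN", "RNP+AAV", "RNP+M3814"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-reads", type=int, default=3000, help="reads per sample")
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ref = build_reference(
        5000,
        seed=args.seed,
        cut_site=2500,
        name="locusA",
        snps=(Snp(1700, "", "", "rs_sim_1"), Snp(3300, "", "", "rs_sim_2")),
    )
    # annotate the SNP alleles from the generated sequence (alt = transversion)
    snps = tuple(
        Snp(s.position, ref.sequence[s.position],
            {"A": "T", "T": "A", "C": "G", "G": "C"}[ref.sequence[s.position]], s.rsid)
        for s in ref.snps
    )
    ref = build_reference(sequence=ref.sequence, cut_site=2500, name="locusA", snps=snps)
    ref, mmej_start = plant_microhomology(ref)

    barcodes = make_barcodes(
        [f"s_{l}" for l in LABELS], ref.name, seed=args.seed + 1, exclude_from=[ref.sequence]
    )
    em = ErrorModel()
    pool, truth_all = [], []
    for i, (label, bc) in enumerate(zip(LABELS, barcodes)):
        table = build_allele_table(
            preset_weights(label), ref, seed=args.seed + 2, mmej_deletion_start=mmej_start
        )
        sc = EditScenario(
            reference=ref, alleles=table, n_reads=args.n_reads,
            seed=args.seed * 100 + i, label=label,
        )
        reads, truth = simulate_reads(sc, em, barcode=bc.barcode)
        pool.extend(reads)
        truth_all.extend(truth)
        print(f"  {label:10s} {len(reads)} reads (barcode {bc.barcode})")

    write_fastq(pool, args.out / "pool.fastq")
    write_truth(truth_all, args.out / "truth.tsv")
    write_references([ref], args.out / "references.fasta", args.out / "references.json")
    with open(args.out / "barcodes.tsv", "w") as fh:
        fh.write("sample_id\tbarcode\tamplicon_name\n")
        for bc in barcodes:
            fh.write(f"{bc.sample_id}\t{bc.barcode}\t{bc.amplicon_name}\n")
    config = {
        "seed": args.seed,
        "n_reads": args.n_reads,
        "labels": LABELS,
        "mmej_start": mmej_start,
        "wt_sample": "s_WT",
    }
    (args.out / "config.json").write_text(json.dumps(config, indent=2) + "\n")
    print(f"pooled {len(pool)} reads -> {args.out}/pool.fastq")


if __name__ == "__main__":
    main()
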