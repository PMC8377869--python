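#!/usr/bin/env python
"""Demultiplex the pooled run, align each bin and compute deletion metrics.

Reads results/sim/ from 01_simulate_pool.py.  Writes per-sample SAM
alignments, a demux summary, the per-sample deletion-metrics table
(raw deletion %, deletion index vs the WT bin, D100-D2000 raw and
index) and a coverage plot for the RNP bin showing the deletion dip
around the cut site.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ampdel.demux import demultiplex, demux_summary
from ampdel.pipeline import attach_background, quantify_reads
from ampdel.references import read_references
from ampdel.report import plot_coverage
from ampdel.simulate import read_fastq
from ampdel.align import write_alignments
from ampdel.demux import BarcodeSpec
from ampdel.metrics import coverage_profile


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = json.loads((args.sim / "config.json").read_text())
    ref = read_references(args.sim / "references.fasta", args.sim / "references.json")[0]
    bc_df = pd.read_csv(args.sim / "barcodes.tsv", sep="\t")
    barcodes = [BarcodeSpec(r.sample_id, r.barcode, r.amplicon_name) for r in bc_df.itertuples()]
    pool = read_fastq(args.sim / "pool.fastq")

    results, bins = demultiplex(pool, barcodes)
    summary = demux_summary(results)
    summary.to_csv(args.out / "demux_summary.tsv", sep="\t", index=False)
    print("demux summary:")
    print(summary.to_string(index=False))

    samples = {}
    for label in config["labels"]:
        sid = f"s_{label}"
        res = quantify_reads(bins[sid], ref, label=label, classify=False)
        samples[label] = res
        write_alignments(
            res.alignments,
            str(args.out / f"aln_{label.replace('+', '_')}.sam"),
            {ref.name: ref.length},
            sequences={r.read_id: r.sequence for r in res.reads},
        )
    wt = samples["WT"]
    rows = []
    for label, res in samples.items():
        if label != "WT":
            attach_background(res, wt)
        rows.append(res.row())
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "deletion_metrics.tsv", sep="\t", index=False, float_format="%.5g")
    cols = ["label", "total_reads", "raw_deletion_pct", "deletion_index_pct", "D100_raw", "D100_index"]
    print("\ndeletion metrics:")
    print(table.reindex(columns=[c for c in cols if c in table]).to_string(index=False))

    prof = coverage_profile(samples["RNP"].alignments, ref, samples["RNP"].total_reads)
    plot_coverage(prof, cut_site=ref.cut_site, path=args.out / "coverage_RNP.png")
    print(f"\nwrote {args.out}/deletion_metrics.tsv and coverage_RNP.png")


if __name__ == "__main__":
    main()
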