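#!/usr/bin/env python
"""Intervention effect sizes and DI / D100 concordance.

Joins the deletion-metrics and edit-summary tables, computes the
percent reduction of the deletion index and of D100 for each donor
intervention relative to RNP alone, and the correlation between the
deletion index and D100 across samples.
"""

import argparse
from pathlib import Path

import pandas as pd

from ampdel.report import percent_reduction, r_squared, summarize_run


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.out / "deletion_metrics.tsv", sep="\t")
    edits = pd.read_csv(args.out / "edit_summary.tsv", sep="\t")
    joined = metrics.merge(edits.drop(columns=["n_reads"]), on="label", how="left")
    summarize_run(
        joined.to_dict("records"),
        out_tsv=args.out / "run_report.tsv",
        out_json=args.out / "run_report.json",
    )

    m = metrics.set_index("label")
    control_di = m.loc["RNP", "deletion_index_pct"]
    control_d100 = m.loc["RNP", "D100_index"]
    print("percent reductions vs RNP alone:")
    rows = []
    for label in ("RNP+ssODN", "RNP+dsODN", "RNP+AAV"):
        di_red = percent_reduction(control_di, m.loc[label, "deletion_index_pct"])
        d100_red = percent_reduction(control_d100, m.loc[label, "D100_index"])
        rows.append({"label": label,
                     "di_reduction_pct": di_red.percent_reduction,
                     "d100_reduction_pct": d100_red.percent_reduction})
        print(f"  {label:10s} DI -{di_red.percent_reduction:5.1f}%   D100 -{d100_red.percent_reduction:5.1f}%")
    pd.DataFrame(rows).to_csv(args.out / "reductions.tsv", sep="\t", index=False, float_format="%.4g")

    edited = metrics[metrics.label != "WT"]
    corr = r_squared(100 * edited["D100_index"], edited["deletion_index_pct"])
    print(f"\nDI vs D100 across edited samples: R^2 = {corr.r_squared:.3f} (n={corr.n})")
    print(f"wrote {args.out}/run_report.tsv")


if __name__ == "__main__":
    main()
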