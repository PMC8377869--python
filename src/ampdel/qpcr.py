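"""Relative copy number from qPCR Ct values (comparative Ct method).

Mega-deletions extending tens of kilobases beyond the amplicon are
invisible to amplicon sequencing; they are detected as copy loss at
probe sites 40-160 kb from the cut.  Per replicate,
``dCt = target_ct − reference_ct`` (internal reference gene); per
(sample, site), ``ddCt = mean dCt(sample) − mean dCt(WT)``; relative
copy ratio = ``efficiency^(−ddCt)`` with efficiency 2.0 (100%
amplification, no standard-curve correction).  A diploid intact site
has ratio 1, a mono-allelic deletion 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "site_label", "target_ct", "reference_ct")


def delta_delta_ct(
    records: pd.DataFrame,
    wt_sample_id: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Copy-number report per (sample, site) relative to the WT sample.

    ``records`` needs columns sample_id, site_label, target_ct,
    reference_ct (and optionally replicate).  Rows with a missing
    reference Ct are dropped with a warning; a WT sample missing any
    site present in the data is an error.  Replicate SD is propagated in
    Ct space and exponentiated into an asymmetric ratio band.
    """
    df = records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    n_dropped = int(df["reference_ct"].isna().sum())
    if n_dropped:
        logger.warning("dropping %d records without reference Ct", n_dropped)
        df = df.dropna(subset=["reference_ct"])
    bad_ct = ~df["target_ct"].between(0, 45) | ~df["reference_ct"].between(0, 45)
    if bad_ct.any():
        raise ValueError("Ct values must lie in (0, 45]")
    if wt_sample_id not in set(df["sample_id"]):
        raise ValueError(f"WT sample {wt_sample_id!r} absent from records")

    df["d_ct"] = df["target_ct"] - df["reference_ct"]
    grouped = (
        df.groupby(["sample_id", "site_label"])["d_ct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    wt = grouped[grouped["sample_id"] == wt_sample_id].set_index("site_label")["mean"]
    sites_missing = set(grouped["site_label"]) - set(wt.index)
    if sites_missing:
        raise ValueError(f"WT sample lacks sites: {sorted(sites_missing)}")

    rows = []
    log_eff = np.log(efficiency)
    for _, r in grouped.iterrows():
        dd_ct = r["mean"] - wt[r["site_label"]]
        ratio = float(np.exp(-dd_ct * log_eff))
        sd_ct = 0.0 if np.isnan(r["std"]) else float(r["std"])
        rows.append(
            {
                "sample_id": r["sample_id"],
                "site_label": r["site_label"],
                "dd_ct": float(dd_ct),
                "copy_ratio": ratio,
                "ratio_low": float(np.exp(-(dd_ct + sd_ct) * log_eff)),
                "ratio_high": float(np.exp(-(dd_ct - sd_ct) * log_eff)),
                "sd_ct": sd_ct,
                "n": int(r["count"]),
            }
        )
    return pd.DataFrame(rows)
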