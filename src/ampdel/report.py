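"""Cross-sample summaries: correlations, percent reductions, run reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ReductionResult:
    control_di: float
    treated_di: float
    percent_reduction: float
    clamped_percent_reduction: float
    control_was_zero: bool = False


def r_squared(x, y) -> CorrelationResult:
    """Ordinary least squares of y on x with R^2 = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        logger.warning("zero variance in y; r_squared defined as 0")
        return CorrelationResult(0.0, float(y[0]), 0.0, len(x))
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=len(x),
    )


def percent_reduction(control_di: float, treated_di: float) -> ReductionResult:
    """(control − treated)/control × 100; the clamped variant floors both
    deletion indexes at zero first (a DI below background is no deletion)."""
    c0 = max(control_di, 0.0)
    t0 = max(treated_di, 0.0)
    clamped = 100.0 * (c0 - t0) / c0 if c0 > 0 else 0.0
    if control_di == 0:
        return ReductionResult(control_di, treated_di, float("nan"), clamped, True)
    return ReductionResult(
        control_di,
        treated_di,
        100.0 * (control_di - treated_di) / control_di,
        min(clamped, 100.0),
    )


def summarize_run(
    sample_rows: list[dict],
    out_tsv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> pd.DataFrame:
    """Join per-sample result dicts into one report table (one row each)."""
    if not sample_rows:
        raise ValueError("no samples to summarize")
    df = pd.DataFrame(sample_rows)
    if df["label"].duplicated().any() if "label" in df else False:
        raise ValueError("duplicate sample labels in report")
    if out_tsv:
        df.to_csv(out_tsv, sep="\t", index=False, float_format="%.6g")
    if out_json:
        Path(out_json).write_text(df.to_json(orient="records", indent=2) + "\n")
    return df


def plot_coverage(profile, cut_site: int | None = None, path: str | Path | None = None):
    """Coverage track; the dip around the cut site is the deletion signal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.fill_between(np.arange(len(profile.depth)), profile.depth, color="#4878a8", lw=0)
    if cut_site is not None:
        ax.axvline(cut_site, color="crimson", ls="--", lw=1, label="cut site")
        ax.legend(frameon=False)
    ax.set_xlabel("amplicon position (bp)")
    ax.set_ylabel("depth")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
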