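"""Nanopore-like sequencing error model.

Errors are applied per base: substitutions with probability ``p_sub``,
insertion opens with ``p_ins`` and deletion opens with ``p_del``; indel
lengths are geometric.  The deletion process is a renewal (skip-ahead)
process — a deletion open consumes a geometric number of template bases
and no new open occurs inside a deletion — so the expected deleted-base
fraction has the closed form

    p_del * E[len] / (1 - p_del + p_del * E[len]),   E[len] = 1 / del_len_geom_p.

Defaults are calibrated so that an unedited (wildtype) run shows ~3.3%
raw deletion, the background level attributable to sequencing error on
this platform.  Quality scores are constant: the downstream analysis
never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ErrorModel:
    p_sub: float = 0.020
    p_ins: float = 0.015
    p_del: float = 0.02225
    del_len_geom_p: float = 2.0 / 3.0
    ins_len_geom_p: float = 2.0 / 3.0
    q_const: int = 12

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("del_len_geom_p", "ins_len_geom_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def expected_deleted_fraction(self) -> float:
        """Closed-form expected fraction of template bases deleted."""
        mean_len = 1.0 / self.del_len_geom_p
        return self.p_del * mean_len / (1.0 - self.p_del + self.p_del * mean_len)

    def mc_deleted_fraction(self, n_bases: int = 1_000_000, seed: int = 0) -> float:
        """Monte-Carlo estimate of the deleted-base fraction (calibration aid)."""
        rng = np.random.default_rng(seed)
        template = np.zeros(n_bases, dtype=np.uint8)
        kept = _apply_deletions(template, self, rng)
        return 1.0 - len(kept) / n_bases


ZERO_ERROR = ErrorModel(p_sub=0.0, p_ins=0.0, p_del=0.0)


def _apply_deletions(
    codes: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Delete geometric runs opened at renewal points; returns kept bases."""
    n = len(codes)
    if model.p_del <= 0 or n == 0:
        return codes
    opens = np.flatnonzero(rng.random(n) < model.p_del)
    if len(opens) == 0:
        return codes
    lengths = rng.geometric(model.del_len_geom_p, size=len(opens))
    keep = np.ones(n, dtype=bool)
    cursor = -1
    for pos, ln in zip(opens, lengths):
        if pos < cursor:  # inside a previous deletion: not a real open
            continue
        keep[pos : pos + ln] = False
        cursor = pos + ln
    return codes[keep]


def apply_errors(
    codes: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply the error model to a 2-bit-coded sequence; returns a new array."""
    kept = _apply_deletions(codes, model, rng)
    m = len(kept)
    if m == 0:
        return kept.copy()
    out_codes = kept.copy()
    if model.p_sub > 0:
        sub_mask = rng.random(m) < model.p_sub
        k = int(sub_mask.sum())
        if k:
            out_codes[sub_mask] = (out_codes[sub_mask] + rng.integers(1, 4, k)) % 4
    if model.p_ins > 0:
        ins_open = rng.random(m) < model.p_ins
        counts = np.zeros(m, dtype=np.int64)
        k = int(ins_open.sum())
        if k:
            counts[ins_open] = rng.geometric(model.ins_len_geom_p, size=k)
        total_ins = int(counts.sum())
        if total_ins:
            # inserted bases land before the base that opened them
            final_pos = np.arange(m) + np.cumsum(counts)
            out = rng.integers(0, 4, m + total_ins).astype(np.uint8)
            out[final_pos] = out_codes
            return out
    return out_codes
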