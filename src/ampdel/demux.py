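"""Barcode demultiplexing of pooled amplicon reads.

Reads carry an 8-12 nt sample barcode at the 5' end of the forward
primer.  Assignment is by exact barcode occurrence (grep semantics)
within the first ``search_window`` bases of the read or of its reverse
complement; a read matching zero or more than one barcode is UNASSIGNED
— there is no score to break ties with.  An optional ``max_mismatch``
relaxes the match for real long-read data.  Assigned reads are returned
barcode-trimmed and re-oriented to the forward strand of the amplicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from .dna import hamming, random_dna, revcomp
from .simulate import SimRead

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class BarcodeSpec:
    sample_id: str
    barcode: str
    amplicon_name: str

    def __post_init__(self) -> None:
        if not (8 <= len(self.barcode) <= 12):
            raise ValueError(
                f"barcode {self.sample_id}: length must be 8-12 nt, got {len(self.barcode)}"
            )


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    assignment: str  # sample_id or UNASSIGNED
    orientation: str | None  # "forward" / "reverse" when assigned
    trimmed_sequence: str
    trimmed_quality: str | None


def _find_barcode(seq: str, barcode: str, window: int, max_mismatch: int) -> int:
    """Return the index just past the barcode match, or -1."""
    if max_mismatch == 0:
        idx = seq.find(barcode, 0, window + len(barcode) - 1)
        return -1 if idx < 0 else idx + len(barcode)
    res = edlib.align(
        barcode, seq[: window + len(barcode) - 1], task="locations", mode="HW", k=max_mismatch
    )
    if res["editDistance"] < 0:
        return -1
    return res["locations"][0][1] + 1


def demultiplex(
    reads: list[SimRead],
    barcodes: list[BarcodeSpec],
    search_window: int = 100,
    max_mismatch: int = 0,
) -> tuple[list[DemuxResult], dict[str, list[SimRead]]]:
    """Assign pooled reads to samples by 5' barcode.

    Returns per-read results (one per input read) and per-sample bins of
    trimmed, forward-oriented reads.
    """
    seqs = [b.barcode for b in barcodes]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate barcode sequences in pool")
    if search_window < max(len(s) for s in seqs):
        raise ValueError("search_window must be >= the longest barcode")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a.barcode, b.barcode) < 2:
                logger.warning(
                    "barcodes %s and %s have Hamming distance < 2; "
                    "cross-assignment is likely on noisy data",
                    a.sample_id,
                    b.sample_id,
                )

    results: list[DemuxResult] = []
    bins: dict[str, list[SimRead]] = {b.sample_id: [] for b in barcodes}
    for read in reads:
        rc_seq = revcomp(read.sequence)
        hits: list[tuple[str, str, int]] = []  # (sample_id, orientation, end)
        for bc in barcodes:
            end = _find_barcode(read.sequence, bc.barcode, search_window, max_mismatch)
            if end >= 0:
                hits.append((bc.sample_id, "forward", end))
                continue  # a barcode matching both strands still counts once
            end = _find_barcode(rc_seq, bc.barcode, search_window, max_mismatch)
            if end >= 0:
                hits.append((bc.sample_id, "reverse", end))
        if len(hits) != 1:
            results.append(DemuxResult(read.read_id, UNASSIGNED, None, read.sequence, read.quality))
            continue
        sample_id, orientation, end = hits[0]
        if orientation == "forward":
            trimmed_seq = read.sequence[end:]
            trimmed_qual = read.quality[end:] if read.quality else None
        else:
            trimmed_seq = rc_seq[end:]
            trimmed_qual = read.quality[::-1][end:] if read.quality else None
        results.append(
            DemuxResult(read.read_id, sample_id, orientation, trimmed_seq, trimmed_qual)
        )
        bins[sample_id].append(SimRead(read.read_id, trimmed_seq, trimmed_qual or ""))
    return results, bins


def demux_summary(results: list[DemuxResult]) -> "pd.DataFrame":
    import pandas as pd

    total = len(results)
    counts: dict[str, int] = {}
    for r in results:
        counts[r.assignment] = counts.get(r.assignment, 0) + 1
    rows = [
        {"bin": k, "reads": v, "fraction": v / total if total else 0.0}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def make_barcodes(
    sample_ids: list[str],
    amplicon_names: list[str] | str,
    length: int = 10,
    seed: int = 0,
    min_distance: int = 3,
    exclude_from: list[str] | None = None,
    search_window: int = 100,
) -> list[BarcodeSpec]:
    """Generate Hamming-separated barcodes for a pool.

    ``exclude_from`` sequences (typically the reference amplicons) are
    checked so that no barcode occurs by chance within the demultiplexing
    search window at either end of any amplicon — this makes error-free
    assignment unambiguous by construction.
    """
    rng = np.random.default_rng(seed)
    if isinstance(amplicon_names, str):
        amplicon_names = [amplicon_names] * len(sample_ids)
    forbidden: list[str] = []
    for seq in exclude_from or []:
        span = search_window + length
        forbidden.append(seq[:span])
        forbidden.append(revcomp(seq[-span:]))
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < len(sample_ids):
        cand = random_dna(length, rng)
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not find enough separated barcodes")
        if any(hamming(cand, c) < min_distance for c in chosen):
            continue
        if any(cand in f for f in forbidden):
            continue
        chosen.append(cand)
    return [
        BarcodeSpec(sid, bc, amp)
        for sid, bc, amp in zip(sample_ids, chosen, amplicon_names)
    ]
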