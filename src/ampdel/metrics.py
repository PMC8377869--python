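"""Coverage-based deletion statistics.

Core quantities:

* raw deletion % = 100 − (mean depth × 100) / total reads, where mean
  depth averages per-position coverage over the FULL amplicon length and
  total reads is the demultiplexed read count for the bin ("read
  depth").  Equivalently (read depth − mean depth) / read depth.
* deletion index (DI) = raw deletion % of the edited sample minus raw
  deletion % of the matched unedited wildtype sample (sequencing-error
  background); negative values are preserved.
* Dx = fraction of reads carrying at least one merged deletion event
  strictly longer than x bp, x in {100, 500, 1000, 1500, 2000}; D100 is
  the conventional large-deletion fraction.

Unaligned reads stay in the denominator by default (they contribute no
coverage, exactly as in a samtools-coverage workflow over the demuxed
read set); ``aligned_only=True`` switches the denominator to aligned
reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, DeletionEvent, merge_deletions
from .references import AmpliconReference, Snp

logger = logging.getLogger(__name__)

DX_THRESHOLDS = (100, 500, 1000, 1500, 2000)


@dataclass
class CoverageProfile:
    ref_name: str
    depth: np.ndarray
    total_reads: int
    aligned_reads: int

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def __post_init__(self) -> None:
        if self.aligned_reads > self.total_reads:
            raise ValueError(
                f"aligned reads ({self.aligned_reads}) exceed total reads "
                f"({self.total_reads})"
            )


@dataclass
class DeletionMetrics:
    raw_deletion_pct: float
    dx_raw: dict[int, float]
    total_reads: int
    aligned_reads: int
    mean_depth: float
    deletion_index_pct: float | None = None
    dx_index: dict[int, float] | None = None
    hdr_depleted: "DeletionMetrics | None" = None


def coverage_profile(
    alignments: list[Alignment],
    reference: AmpliconReference,
    total_reads: int,
) -> CoverageProfile:
    """Per-position depth from primary alignments.

    Depth counts match/mismatch ops only: deletion ops leave the "white
    area" dip in the coverage track that the raw-deletion formula
    measures.
    """
    if total_reads < len(alignments):
        raise ValueError("total_reads must be >= number of alignments")
    diff = np.zeros(reference.length + 1, dtype=np.int64)
    for aln in alignments:
        pos = aln.ref_start
        if pos < 0 or aln.ref_end > reference.length:
            raise ValueError(f"alignment {aln.read_id} outside reference bounds")
        for op, n in aln.ops:
            if op in ("=", "X"):
                diff[pos] += 1
                diff[pos + n] -= 1
                pos += n
            elif op == "D":
                pos += n
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(
        ref_name=reference.name,
        depth=depth,
        total_reads=total_reads,
        aligned_reads=len(alignments),
    )


def raw_deletion(profile: CoverageProfile, aligned_only: bool = False) -> float:
    """Raw deletion percentage (background included)."""
    denom = profile.aligned_reads if aligned_only else profile.total_reads
    if denom <= 0:
        raise ValueError("deletion percentage undefined for zero reads")
    return 100.0 - (profile.mean_depth * 100.0) / denom


def deletion_index(raw_edited_pct: float, raw_wt_pct: float) -> float:
    """Edited-minus-wildtype deletion percentage; NOT clamped at zero."""
    return raw_edited_pct - raw_wt_pct


def dx_fractions(
    events_by_read: dict[str, list[DeletionEvent]],
    total_reads: int,
    thresholds: tuple[int, ...] = DX_THRESHOLDS,
) -> dict[int, float]:
    """Fraction of reads with >= 1 merged deletion strictly > t bp.

    ``events_by_read`` holds merged deletion events per aligned read;
    unaligned reads (absent keys) never count in the numerator but stay
    in the ``total_reads`` denominator.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    out = {}
    maxima = [max((e.deleted_bp for e in evs), default=0) for evs in events_by_read.values()]
    for t in thresholds:
        out[t] = sum(1 for m in maxima if m > t) / total_reads
    return out


def compute_metrics(
    alignments: list[Alignment],
    reference: AmpliconReference,
    total_reads: int,
    merge_gap: int = 10,
    thresholds: tuple[int, ...] = DX_THRESHOLDS,
    aligned_only: bool = False,
) -> DeletionMetrics:
    """Coverage, raw deletion and Dx for one sample bin."""
    profile = coverage_profile(alignments, reference, total_reads)
    events = {a.read_id: merge_deletions(a, merge_gap) for a in alignments}
    denom = profile.aligned_reads if aligned_only else total_reads
    return DeletionMetrics(
        raw_deletion_pct=raw_deletion(profile, aligned_only),
        dx_raw=dx_fractions(events, denom, thresholds),
        total_reads=total_reads,
        aligned_reads=profile.aligned_reads,
        mean_depth=profile.mean_depth,
    )


def subtract_background(
    edited: DeletionMetrics, wildtype: DeletionMetrics
) -> DeletionMetrics:
    """Fill deletion-index fields of ``edited`` from a matched WT sample."""
    edited.deletion_index_pct = deletion_index(
        edited.raw_deletion_pct, wildtype.raw_deletion_pct
    )
    edited.dx_index = {
        t: edited.dx_raw[t] - wildtype.dx_raw.get(t, 0.0) for t in edited.dx_raw
    }
    return edited


def deplete_hdr(
    alignments: list[Alignment],
    edit_calls: dict[str, str],
    reference: AmpliconReference,
    total_reads: int,
    merge_gap: int = 10,
    aligned_only: bool = False,
) -> DeletionMetrics:
    """Re-compute metrics after removing HDR-classified reads.

    HDR reads leave both the numerator (coverage) and the denominator.
    Used to check that HDR alleles in the pool do not artificially dilute
    the deletion signal.
    """
    hdr_ids = {rid for rid, cat in edit_calls.items() if cat == "hdr"}
    kept = [a for a in alignments if a.read_id not in hdr_ids]
    n_hdr = sum(1 for a in alignments if a.read_id in hdr_ids)
    new_total = total_reads - n_hdr
    if new_total <= 0 or not kept:
        raise ValueError("all reads classified HDR; empty denominator")
    return compute_metrics(
        kept, reference, new_total, merge_gap=merge_gap, aligned_only=aligned_only
    )


# ---------------------------------------------------------------------------
# SNP loss-of-heterozygosity check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpCounts:
    rsid: str
    position: int
    ref_count: int
    alt_count: int

    @property
    def minor_allele_fraction(self) -> float:
        total = self.ref_count + self.alt_count
        return min(self.ref_count, self.alt_count) / total if total else 0.0


@dataclass
class LohReport:
    snps: list[SnpCounts]
    verdict: str  # heterozygous_retained / loh_suspected / uninformative
    min_reads: int
    het_threshold: float


def read_base_at(alignment: Alignment, read_seq: str, ref_pos: int) -> str | None:
    """Base of the (forward-oriented) read aligned at a reference position.

    Returns ``None`` when the position is deletion-spanned or outside the
    aligned interval.
    """
    rpos = alignment.ref_start
    qpos = 0
    for op, n in alignment.ops:
        if op in ("=", "X"):
            if rpos <= ref_pos < rpos + n:
                return read_seq[qpos + (ref_pos - rpos)]
            rpos += n
            qpos += n
        elif op == "D":
            if rpos <= ref_pos < rpos + n:
                return None
            rpos += n
        elif op in ("I", "S"):
            qpos += n
    return None


def loh_check(
    aligned_reads: list[tuple[Alignment, str]],
    snps: tuple[Snp, ...],
    min_reads: int = 20,
    het_threshold: float = 0.2,
) -> LohReport:
    """Allele counting at annotated SNPs.

    A clone retains heterozygosity when the minor-allele fraction is at
    least ``het_threshold`` at every informative SNP (boundary
    inclusive).  Bases other than the annotated ref/alt alleles and
    deletion-spanned positions are ignored.
    """
    counts: list[SnpCounts] = []
    for snp in snps:
        ref_n = alt_n = 0
        for aln, seq in aligned_reads:
            base = read_base_at(aln, seq, snp.position)
            if base == snp.ref_allele:
                ref_n += 1
            elif base == snp.alt_allele:
                alt_n += 1
        counts.append(SnpCounts(snp.rsid, snp.position, ref_n, alt_n))
    informative = [c for c in counts if c.ref_count + c.alt_count >= min_reads]
    if not informative:
        verdict = "uninformative"
    elif all(c.minor_allele_fraction >= het_threshold for c in informative):
        verdict = "heterozygous_retained"
    else:
        verdict = "loh_suspected"
    return LohReport(counts, verdict, min_reads, het_threshold)
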