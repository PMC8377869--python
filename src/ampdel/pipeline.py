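"""End-to-end sample processing: simulate -> demux -> align -> quantify.

These helpers chain the library modules the way the analysis scripts
and the acceptance checks use them; each step remains available on its
own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import Alignment, Read, Scoring, align_read, merge_deletions
from .classify import EditCall, EditSummary, EditTemplates, classify_read, tabulate_edits
from .demux import BarcodeSpec, demultiplex
from .errors import ErrorModel
from .metrics import DeletionMetrics, compute_metrics, deplete_hdr, subtract_background
from .references import AmpliconReference
from .simulate import EditScenario, SimRead, TruthRecord, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    label: str
    total_reads: int
    aligned_reads: int
    metrics: DeletionMetrics
    alignments: list[Alignment]
    reads: list[SimRead]
    calls: list[EditCall] | None = None
    edit_summary: EditSummary | None = None

    def row(self) -> dict:
        """Flat report row for summarize_run."""
        m = self.metrics
        out = {
            "label": self.label,
            "total_reads": self.total_reads,
            "aligned_reads": self.aligned_reads,
            "mean_depth": m.mean_depth,
            "raw_deletion_pct": m.raw_deletion_pct,
            "deletion_index_pct": m.deletion_index_pct,
        }
        for t, f in m.dx_raw.items():
            out[f"D{t}_raw"] = f
        if m.dx_index:
            for t, f in m.dx_index.items():
                out[f"D{t}_index"] = f
        if self.edit_summary:
            s = self.edit_summary
            out.update(
                nhej_pct=s.nhej_pct,
                hdr_pct=s.hdr_pct,
                dsodn_pct=s.dsodn_pct,
                total_editing_pct=s.total_editing_pct,
                plusA_pct=s.plusA_pct,
                mmej25_pct=s.mmej25_pct,
            )
        return out


def quantify_reads(
    reads: list[SimRead],
    reference: AmpliconReference,
    label: str = "sample",
    total_reads: int | None = None,
    templates: EditTemplates | None = None,
    classify: bool = True,
    strand: str = "+",
    scoring: Scoring = Scoring(),
    merge_gap: int = 10,
) -> SampleResult:
    """Align a bin of (demultiplexed, forward-oriented) reads and compute
    deletion metrics and, optionally, per-read edit calls."""
    total = total_reads if total_reads is not None else len(reads)
    alignments = []
    aligned_reads: list[tuple[Alignment, str]] = []
    for r in reads:
        aln = align_read(Read(r.read_id, r.sequence), reference, scoring=scoring, strand=strand)
        if aln is not None:
            alignments.append(aln)
            aligned_reads.append((aln, r.sequence))
    metrics = compute_metrics(alignments, reference, total, merge_gap=merge_gap)
    result = SampleResult(
        label=label,
        total_reads=total,
        aligned_reads=len(alignments),
        metrics=metrics,
        alignments=alignments,
        reads=reads,
    )
    if classify:
        tmpl = templates or EditTemplates()
        result.calls = [classify_read(a, s, reference, tmpl) for a, s in aligned_reads]
        if result.calls:
            result.edit_summary = tabulate_edits(result.calls)
    return result


def run_scenario(
    scenario: EditScenario,
    error_model: ErrorModel,
    barcode: BarcodeSpec | None = None,
    templates: EditTemplates | None = None,
    classify: bool = True,
    search_window: int = 100,
) -> tuple[SampleResult, list[TruthRecord]]:
    """Simulate one scenario and push it through demux + quantification.

    When a barcode is given, reads are emitted barcoded and demultiplexed
    exactly as a pooled run would be; reads failing barcode match drop
    out of the bin (and its denominator), as in the real workflow.
    """
    reads, truth = simulate_reads(
        scenario, error_model, barcode=barcode.barcode if barcode else ""
    )
    if barcode is not None:
        _, bins = demultiplex(reads, [barcode], search_window=search_window)
        bin_reads = bins[barcode.sample_id]
    else:
        bin_reads = reads
    result = quantify_reads(
        bin_reads,
        scenario.reference,
        label=scenario.label,
        templates=templates,
        classify=classify,
        # demultiplexed bins are re-oriented to the forward strand; an
        # un-demuxed simulation still holds both orientations
        strand="+" if barcode is not None else "both",
    )
    return result, truth


def attach_background(edited: SampleResult, wildtype: SampleResult) -> SampleResult:
    """Fill deletion-index fields of an edited sample from its WT pair."""
    subtract_background(edited.metrics, wildtype.metrics)
    return edited


def hdr_depleted_metrics(result: SampleResult, reference: AmpliconReference) -> DeletionMetrics:
    """Re-run deletion metrics with HDR reads removed (sanity re-analysis)."""
    if result.calls is None:
        raise ValueError("sample was quantified without classification")
    call_map = {c.read_id: c.category for c in result.calls}
    depleted = deplete_hdr(
        result.alignments, call_map, reference, result.total_reads
    )
    result.metrics.hdr_depleted = depleted
    return depleted
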