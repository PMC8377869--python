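"""Read-to-amplicon alignment.

Two routes produce the same ``Alignment`` objects:

* the package's own semi-global affine-gap dynamic-programming aligner
  (``engine="affine"``): free end gaps on the reference (overhangs are
  unpenalised) and on the read (overhangs become soft clips), optional
  band around the scaled diagonal.  Affine gap costs make a single
  contiguous gap strictly cheaper than the same gap interrupted by
  isolated 1-2 bp matches, which is essential for representing large
  deletions faithfully;

* a fast engine (``engine="edlib"``, default) that computes a global
  unit-cost alignment with edlib and then re-polishes every large-gap
  region with the affine DP on a local window.  Unit-cost co-optimal
  paths tend to shred a kilobase-scale deletion into fragments separated
  by spurious chance matches; the affine polish restores the contiguous
  event, so coverage and deletion-length bookkeeping match the affine
  aligner's output at a fraction of the cost.

External aligner output (SAM/BAM with CIGAR) can be ingested instead via
:func:`read_alignments`.

Coordinates are 0-based half-open throughout; SAM's 1-based POS is
converted at the I/O boundary.  Alignment ops use SAM-style codes:
``=`` match, ``X`` mismatch, ``I`` insertion, ``D`` deletion, ``S`` soft
clip.  Minus-strand alignments store ops along the forward reference
with the read reverse-complemented (SAM convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .dna import revcomp
from .references import AmpliconReference

logger = logging.getLogger(__name__)

READ_CONSUMING = {"=", "X", "I", "S"}
REF_CONSUMING = {"=", "X", "D"}

_CIGAR_RE = re.compile(r"(\d+)([=XIDSHM])")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass
class Alignment:
    read_id: str
    ref_name: str
    ref_start: int
    strand: str  # "+" or "-"
    ops: list[tuple[str, int]]
    score: float = 0.0

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in REF_CONSUMING)

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.ops if op in READ_CONSUMING)

    def aligned_read_fraction(self) -> float:
        aligned = sum(n for op, n in self.ops if op in ("=", "X", "I"))
        return aligned / max(1, self.read_length)


@dataclass(frozen=True)
class DeletionEvent:
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    deleted_bp: int  # sum of constituent deletion-op lengths


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4  # charged once per gap, on top of per-base extension
    gap_extend: int = -2

    def gap_cost(self, length: int) -> int:
        return self.gap_open + self.gap_extend * length


def normalize_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Drop zero-length ops and coalesce adjacent ops of the same kind."""
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def validate_alignment(aln: Alignment, read_length: int, ref_length: int) -> None:
    """Raise if op-length bookkeeping is inconsistent."""
    if aln.read_length != read_length:
        raise ValueError(
            f"{aln.read_id}: read-consuming ops sum to {aln.read_length}, "
            f"read length is {read_length}"
        )
    if aln.ref_end > ref_length or aln.ref_start < 0:
        raise ValueError(f"{aln.read_id}: alignment [{aln.ref_start},{aln.ref_end}) "
                         f"outside reference of length {ref_length}")
    for i in range(1, len(aln.ops)):
        if aln.ops[i][0] == aln.ops[i - 1][0]:
            raise ValueError(f"{aln.read_id}: adjacent ops of the same kind")


# ---------------------------------------------------------------------------
# Affine-gap semi-global DP
# ---------------------------------------------------------------------------

NEG_INF = np.float32(-1e30)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    raise

@njit(cache=True)
def _affine_kernel(q, t, match, mismatch, gap_open, gap_ext, lo_arr, hi_arr,
                   free_ref_ends, free_read_ends):
    m = len(q)
    n = len(t)
    NEG = np.float32(-1e30)
    H = np.full((m + 1, n + 1), NEG, np.float32)
    V = np.full((m + 1, n + 1), NEG, np.float32)
    D = np.full((m + 1, n + 1), NEG, np.float32)
    ptr = np.zeros((m + 1, n + 1), np.uint8)  # H source: 0 diag, 1 V, 2 D
    pV = np.zeros((m + 1, n + 1), np.uint8)  # 1: V extends V
    pD = np.zeros((m + 1, n + 1), np.uint8)  # 1: D extends D
    for j in range(n + 1):
        if free_ref_ends or j == 0:
            H[0, j] = 0.0
        else:
            H[0, j] = gap_open + gap_ext * j
    for i in range(m + 1):
        if free_read_ends or i == 0:
            H[i, 0] = 0.0
        else:
            H[i, 0] = gap_open + gap_ext * i
    oe = np.float32(gap_open + gap_ext)
    ge = np.float32(gap_ext)
    for i in range(1, m + 1):
        lo = lo_arr[i]
        hi = hi_arr[i]
        qi = q[i - 1]
        for j in range(lo, hi + 1):
            v_ext = V[i - 1, j] + ge
            v_open = H[i - 1, j] + oe
            if v_ext >= v_open:
                V[i, j] = v_ext
                pV[i, j] = 1
            else:
                V[i, j] = v_open
            d_ext = D[i, j - 1] + ge
            d_open = H[i, j - 1] + oe
            if d_ext >= d_open:
                D[i, j] = d_ext
                pD[i, j] = 1
            else:
                D[i, j] = d_open
            s = match if qi == t[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            p = 0
            if V[i, j] > h:
                h = V[i, j]
                p = 1
            if D[i, j] > h:
                h = D[i, j]
                p = 2
            H[i, j] = h
            ptr[i, j] = p
    return H, ptr, pV, pD


def affine_align(
    read: str,
    ref: str,
    scoring: Scoring = Scoring(),
    band_width: int | None = None,
    free_read_ends: bool = True,
    free_ref_ends: bool = True,
) -> tuple[float, int, list[tuple[str, int]]]:
    """Affine-gap DP alignment of ``read`` against ``ref``.

    With both free-end flags set (the default) this is an overlap
    alignment: unaligned reference overhangs are unpenalised and read
    overhangs come back as soft clips.  With both flags false it is a
    global (Needleman-Wunsch) alignment, used internally to re-polish
    anchored segments.  ``band_width`` restricts the DP to cells within
    that distance of the scaled diagonal; ``None`` means unbanded.
    A gap of length L costs ``gap_open + L * gap_extend``.

    Returns ``(score, ref_start, ops)``.
    """
    m, n = len(read), len(ref)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(ref.encode(), dtype=np.uint8)
    if band_width is None:
        lo_arr = np.ones(m + 1, dtype=np.int64)
        hi_arr = np.full(m + 1, n, dtype=np.int64)
    else:
        centers = np.arange(m + 1) * (n / m)
        lo_arr = np.maximum(1, (centers - band_width).astype(np.int64))
        hi_arr = np.minimum(n, (centers + band_width).astype(np.int64))
    H, ptr, pV, pD = _affine_kernel(
        q,
        t,
        np.float32(scoring.match),
        np.float32(scoring.mismatch),
        np.float32(scoring.gap_open),
        np.float32(scoring.gap_extend),
        lo_arr,
        hi_arr,
        free_ref_ends,
        free_read_ends,
    )

    if free_ref_ends and free_read_ends:
        jbest = int(np.argmax(H[m, :]))
        ibest = int(np.argmax(H[:, n]))
        ei, ej = (m, jbest) if H[m, jbest] >= H[ibest, n] else (ibest, n)
    elif free_ref_ends:
        ei, ej = m, int(np.argmax(H[m, :]))
    elif free_read_ends:
        ei, ej = int(np.argmax(H[:, n])), n
    else:
        ei, ej = m, n
    score = float(H[ei, ej])

    ops: list[tuple[str, int]] = []
    if ei < m:
        ops.append(("S", m - ei))
    i, j = ei, ej
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i, j]
            if p == 0:
                ops.append(("=" if read[i - 1] == ref[j - 1] else "X", 1))
                i -= 1
                j -= 1
            elif p == 1:
                state = "V"
            else:
                state = "D"
        elif state == "V":
            ops.append(("I", 1))
            if pV[i, j] == 0:
                state = "H"
            i -= 1
        else:  # "D"
            ops.append(("D", 1))
            if pD[i, j] == 0:
                state = "H"
            j -= 1
    if i > 0:
        # unaligned read prefix: soft clip under free read ends, else a
        # leading insertion (global mode)
        ops.append(("S", i) if free_read_ends else ("I", i))
    ref_start = j
    if not free_ref_ends and j > 0:
        ops.append(("D", j))
        ref_start = 0
    ops.reverse()
    return score, ref_start, normalize_ops(ops)


# ---------------------------------------------------------------------------
# edlib engine + affine polish
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _edlib_ops(read: str, ref: str) -> tuple[int, list[tuple[str, int]]]:
    """Global unit-cost alignment; terminal ref gaps become overhangs."""
    res = edlib.align(read, ref, task="path", mode="NW")
    ops = _parse_cigar(res["cigar"])
    ref_start = 0
    if ops and ops[0][0] == "D":  # unaligned reference prefix
        ref_start = ops[0][1]
        ops = ops[1:]
    if ops and ops[-1][0] == "D":  # unaligned reference suffix
        ops = ops[:-1]
    # read overhangs (terminal insertions) become soft clips
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    return ref_start, ops


def _polish_large_gaps(
    read: str,
    ref: str,
    ref_start: int,
    ops: list[tuple[str, int]],
    scoring: Scoring,
    min_gap: int = 30,
    min_ins: int = 5,
    min_mixed: int = 3,
    min_frag_total: int = 10,
    merge_gap: int = 10,
    max_cells: int = 20_000_000,
) -> tuple[int, list[tuple[str, int]]]:
    """Re-align indel clusters with the affine DP.

    Unit-cost co-optimal paths misrepresent structured indels: a big
    deletion comes back as D runs interleaved with spurious chance
    matches, and a template insertion can come back split into an I run
    plus a compensating D downstream.  Gap ops chained with <=
    ``merge_gap`` intervening reference bases form a cluster; a cluster
    is re-aligned globally under affine scoring when its deletion mass
    reaches ``min_gap`` bp, its insertion mass reaches ``min_ins`` bp,
    it mixes insertions and deletions of >= ``min_mixed`` bp each, or it
    is fragmented (>= 2 gap runs) with >= ``min_frag_total`` gapped bases
    — co-optimal shredding also affects 20-30 bp deletions in repeats.  Cluster boundaries sit on gap ops, so the
    flanking alignment pins the segment and the splice is plain op-list
    surgery.
    """
    nops = len(ops)
    refoff = [0]
    readoff = [0]
    for op, n in ops:
        refoff.append(refoff[-1] + (n if op in REF_CONSUMING else 0))
        readoff.append(readoff[-1] + (n if op in READ_CONSUMING else 0))

    clusters: list[tuple[int, int]] = []
    k = 0
    while k < nops:
        if ops[k][0] not in ("D", "I"):
            k += 1
            continue
        k0 = k1 = k
        tot = {"D": 0, "I": 0}
        tot[ops[k][0]] += ops[k][1]
        gap = 0
        j = k + 1
        while j < nops:
            op, n = ops[j]
            if op in ("D", "I"):
                tot[op] += n
                k1 = j
                gap = 0
            elif op == "S":
                break
            else:
                gap += n
                if gap > merge_gap:
                    break
            j += 1
        n_gap_runs = sum(1 for kk in range(k0, k1 + 1) if ops[kk][0] in ("D", "I"))
        if (
            tot["D"] >= min_gap
            or tot["I"] >= min_ins
            or min(tot["D"], tot["I"]) >= min_mixed
            or (n_gap_runs >= 2 and tot["D"] + tot["I"] >= min_frag_total)
        ):
            clusters.append((k0, k1))
        k = max(j, k1 + 1)
    if not clusters:
        return ref_start, ops

    new_ops: list[tuple[str, int]] = []
    cur = 0
    for k0, k1 in clusters:
        new_ops.extend(ops[cur:k0])
        q0, q1 = readoff[k0], readoff[k1 + 1]
        r0, r1 = refoff[k0], refoff[k1 + 1]
        seg_read = read[q0:q1]
        seg_ref = ref[ref_start + r0 : ref_start + r1]
        if not seg_read and seg_ref:
            new_ops.append(("D", r1 - r0))
        elif not seg_ref and seg_read:
            new_ops.append(("I", q1 - q0))
        elif len(seg_read) * len(seg_ref) > max_cells:
            new_ops.extend(ops[k0 : k1 + 1])  # too large to polish; keep as-is
        else:
            _, _, seg_ops = affine_align(
                seg_read, seg_ref, scoring, free_read_ends=False, free_ref_ends=False
            )
            new_ops.extend(seg_ops)
        cur = k1 + 1
    new_ops.extend(ops[cur:])
    return ref_start, normalize_ops(new_ops)


def score_ops(ops: list[tuple[str, int]], scoring: Scoring) -> float:
    s = 0.0
    for op, n in ops:
        if op == "=":
            s += scoring.match * n
        elif op == "X":
            s += scoring.mismatch * n
        elif op in ("I", "D"):
            s += scoring.gap_cost(n)
    return s


def align_read(
    read: Read,
    reference: AmpliconReference,
    scoring: Scoring = Scoring(),
    band_width: int = 3000,
    engine: str = "edlib",
    strand: str = "both",
    min_score_frac: float = 0.3,
) -> Alignment | None:
    """Align one read to the reference; returns ``None`` when unalignable.

    ``strand`` may be ``"+"``, ``"-"`` or ``"both"`` (try both, keep the
    better score — demultiplexing usually fixes the orientation already).
    Reads scoring below ``min_score_frac * match * read_length`` are
    reported unaligned.
    """
    if not read.sequence:
        logger.warning("read %s: empty sequence, unaligned", read.read_id)
        return None
    candidates = []
    strands = ["+", "-"] if strand == "both" else [strand]
    for st in strands:
        seq = read.sequence if st == "+" else revcomp(read.sequence)
        if engine == "edlib":
            if strand == "both":
                d = edlib.align(seq, reference.sequence, task="distance", mode="NW")
                candidates.append((st, seq, d["editDistance"]))
            else:
                candidates.append((st, seq, 0))
        elif engine == "affine":
            sc, ref_start, ops = affine_align(
                seq, reference.sequence, scoring, band_width=band_width
            )
            candidates.append((st, seq, sc, ref_start, ops))
        else:
            raise ValueError(f"unknown engine {engine!r}")

    if engine == "edlib":
        st, seq, _ = min(candidates, key=lambda c: c[2])
        ref_start, ops = _edlib_ops(seq, reference.sequence)
        ref_start, ops = _polish_large_gaps(
            seq, reference.sequence, ref_start, ops, scoring
        )
        score = score_ops(ops, scoring)
    else:
        st, seq, score, ref_start, ops = max(candidates, key=lambda c: c[2])

    if score < min_score_frac * scoring.match * len(read.sequence):
        return None
    aln = Alignment(
        read_id=read.read_id,
        ref_name=reference.name,
        ref_start=ref_start,
        strand=st,
        ops=normalize_ops(ops),
        score=score,
    )
    validate_alignment(aln, len(read.sequence), reference.length)
    return aln


# ---------------------------------------------------------------------------
# Deletion-event merging
# ---------------------------------------------------------------------------


def merge_deletions(aln: Alignment, merge_gap: int = 10) -> list[DeletionEvent]:
    """Merge deletion ops separated by <= ``merge_gap`` reference bases.

    ``deleted_bp`` sums only deleted bases, so an event interrupted by a
    few aligned bases reports the true removed mass, not the span.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    events: list[DeletionEvent] = []
    ref_pos = aln.ref_start
    cur_start = cur_end = None
    cur_bp = 0
    gap = 0
    for op, n in aln.ops:
        if op == "D":
            if cur_start is None:
                cur_start, cur_end, cur_bp = ref_pos, ref_pos + n, n
            elif gap <= merge_gap:
                cur_end = ref_pos + n
                cur_bp += n
            else:
                events.append(DeletionEvent(cur_start, cur_end, cur_bp))
                cur_start, cur_end, cur_bp = ref_pos, ref_pos + n, n
            gap = 0
            ref_pos += n
        else:
            if op in REF_CONSUMING:
                ref_pos += n
                if cur_start is not None:
                    gap += n
    if cur_start is not None:
        events.append(DeletionEvent(cur_start, cur_end, cur_bp))
    return sorted(events, key=lambda e: e.ref_start)


# ---------------------------------------------------------------------------
# SAM I/O (pysam)
# ---------------------------------------------------------------------------

_OP2CODE = {"M": 0, "I": 1, "D": 2, "S": 4, "H": 5, "=": 7, "X": 8}
_CODE2OP = {v: k for k, v in _OP2CODE.items()}


def write_alignments(
    alignments: list[Alignment],
    path: str,
    references: dict[str, int],
    sequences: dict[str, str] | None = None,
) -> None:
    """Write alignments as SAM (``=``/``X`` CIGAR ops)."""
    import pysam

    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": references[n]} for n in names],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for a in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = a.read_id
            rec.reference_id = names.index(a.ref_name)
            rec.reference_start = a.ref_start
            rec.flag = 16 if a.strand == "-" else 0
            rec.mapping_quality = 60
            rec.cigartuples = [(_OP2CODE[op], n) for op, n in a.ops]
            if sequences and a.read_id in sequences:
                seq = sequences[a.read_id]
                rec.query_sequence = seq if a.strand == "+" else revcomp(seq)
            fh.write(rec)


def read_alignments(
    path: str, references: dict[str, str] | None = None
) -> tuple[list[Alignment], dict[str, int]]:
    """Read primary alignments from SAM/BAM.

    ``M`` ops are split into ``=``/``X`` when the reference sequence is
    supplied (otherwise kept as matches); hard clips are converted to the
    soft-clip-equivalent read-space accounting.  Secondary/supplementary
    and unmapped records are counted in the returned summary, not merged.
    """
    import pysam

    out: list[Alignment] = []
    summary = {"primary": 0, "secondary": 0, "supplementary": 0, "unmapped": 0, "skipped": 0}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                summary["unmapped"] += 1
                continue
            if rec.is_secondary:
                summary["secondary"] += 1
                continue
            if rec.is_supplementary:
                summary["supplementary"] += 1
                continue
            if rec.cigartuples is None:
                summary["skipped"] += 1
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            ops: list[tuple[str, int]] = []
            ref_pos = rec.reference_start
            seq = rec.query_sequence
            read_pos = 0
            refseq = references.get(rec.reference_name) if references else None
            for code, n in rec.cigartuples:
                op = _CODE2OP.get(code)
                if op is None:
                    raise ValueError(f"unsupported CIGAR op code {code}")
                if op == "H":
                    op = "S"  # hard clip: same read-space accounting, bases absent
                if op == "M":
                    if refseq is not None and seq is not None:
                        for k in range(n):
                            same = seq[read_pos + k] == refseq[ref_pos + k]
                            ops.append(("=" if same else "X", 1))
                    else:
                        ops.append(("=", n))
                else:
                    ops.append((op, n))
                if op in REF_CONSUMING:
                    ref_pos += n
                if op in READ_CONSUMING and code != 5:
                    read_pos += n
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    ref_name=rec.reference_name,
                    ref_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    ops=normalize_ops(ops),
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                )
            )
            summary["primary"] += 1
    return out, summary
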