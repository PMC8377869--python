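"""Per-read editing-outcome classification.

A window classifier in the spirit of amplicon-editing quantifiers: for
each aligned read, variant ops overlapping a window around the cut site
decide the outcome.  Precedence:

1. insertion matching the HDR donor insert (edit distance <= a fraction
   of the insert length) -> ``hdr``;
2. insertion matching the dsODN or its reverse complement ->
   ``dsodn_forward`` / ``dsodn_reverse``;
3. any merged deletion > 100 bp anywhere on the read ->
   ``large_deletion`` (kilobase-scale events dominate the phenotype
   regardless of where the aligner placed them);
4. any other indel at the cut -> ``nhej_small_indel``, with the
   signatures "+A" (single inserted A at the cut) and "-25" (25 bp
   deletion flanked by the configured microhomology);
5. otherwise ``unmodified`` — substitution-only reads are treated as
   sequencing error.

Long-read error rates put roughly one spurious indel in any +/-20 bp
window, so rule 4 does not accept every window indel: an indel counts
as a real edit only when some equivalent placement of it (indels in
repeats are normalised to their full left/right shift range, as in VCF
normalisation) intersects the ``signal_halfwidth`` zone around the cut
where genuine repair outcomes sit.  The wider window is still used for
collecting template-insert bases and net-indel bookkeeping.

Before rule 4 the window is locally re-aligned with an indel-preferring
affine scoring (a 1 bp insertion plus a 1 bp deletion outscore two
mismatches, unlike under edit distance or standard affine scoring).
Whole-read alignment otherwise absorbs a genuine 1 bp edit adjacent to
a sequencing-error indel into a pair of substitutions, silently erasing
the edit; isolated substitutions still stay substitutions, so
unmodified windows gain no spurious indels.

Note dsODN captures are reported as their own category here, distinct
from HDR, even though NGS quantifiers that are given the dsODN as an
"expected allele" fold them into their HDR tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import Alignment, Scoring, affine_align, merge_deletions
from .alleles import DSODN_34, HDR_INSERT_18, MMEJ_DELETION_LENGTH, MMEJ_MICROHOMOLOGY
from .dna import revcomp
from .references import AmpliconReference

# window re-alignment scoring: I1+D1 (-8) beats 2X (-10); contiguous
# gaps still beat split ones
CLASSIFY_SCORING = Scoring(match=2, mismatch=-5, gap_open=-2, gap_extend=-2)

CATEGORIES = (
    "unmodified",
    "nhej_small_indel",
    "hdr",
    "dsodn_forward",
    "dsodn_reverse",
    "large_deletion",
    "ambiguous",
)


@dataclass(frozen=True)
class EditTemplates:
    hdr_insert: str = HDR_INSERT_18
    dsodn: str = DSODN_34
    mmej_deletion_length: int = MMEJ_DELETION_LENGTH
    mmej_microhomology: str = MMEJ_MICROHOMOLOGY
    window_halfwidth: int = 20
    signal_halfwidth: int = 1
    identity_tolerance: float = 0.25
    large_deletion_threshold: int = 100
    merge_gap: int = 10

    def __post_init__(self) -> None:
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")


@dataclass(frozen=True)
class EditCall:
    read_id: str
    category: str
    net_indel_bp: int = 0
    signature: str = ""
    insert_identity: float = 0.0


@dataclass
class EditSummary:
    fractions: dict[str, float]
    n_reads: int
    nhej_pct: float
    hdr_pct: float
    dsodn_pct: float
    total_editing_pct: float
    plusA_pct: float
    mmej25_pct: float


def _identity_fraction(insert: str, template: str) -> float:
    """Edit distance between insert and template over the template length."""
    if not insert or not template:
        return 1.0
    d = edlib.align(insert, template, task="distance", mode="NW")["editDistance"]
    return d / len(template)


def _template_hit_fraction(window_seq: str, template: str) -> float:
    """Best infix match of the template inside the read window.

    Alignment placement of an insertion is ambiguous when its edges
    chance-match the reference, so the template is searched directly in
    the read bases spanning the window (insertions included) rather than
    compared against the collected insertion ops.
    """
    if not window_seq or not template:
        return 1.0
    d = edlib.align(template, window_seq, task="distance", mode="HW")["editDistance"]
    return d / len(template)


def _read_window_sequence(aln, read_seq: str, lo: int, hi: int) -> str:
    """Read bases (insertions included) aligned within reference [lo, hi)."""
    rpos = aln.ref_start
    qpos = 0
    q0 = q1 = None
    for op, n in aln.ops:
        if op in ("=", "X"):
            if rpos < hi and rpos + n > lo:
                s = qpos + max(0, lo - rpos)
                e = qpos + min(n, hi - rpos)
                q0 = s if q0 is None else q0
                q1 = e
            rpos += n
            qpos += n
        elif op == "I":
            if lo <= rpos < hi:
                q0 = qpos if q0 is None else q0
                q1 = qpos + n
            qpos += n
        elif op == "D":
            rpos += n
        elif op == "S":
            qpos += n
    if q0 is None:
        return ""
    return read_seq[q0:q1]


def _collect_window_variants(
    aln: Alignment, read_seq: str, lo: int, hi: int
) -> tuple[list[tuple[int, str]], list[tuple[int, int]]]:
    """Insertions (ref_pos, bases) and deletions (ref_start, len) in [lo, hi)."""
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    rpos = aln.ref_start
    qpos = 0
    for op, n in aln.ops:
        if op in ("=", "X"):
            rpos += n
            qpos += n
        elif op == "I":
            if lo <= rpos < hi:
                insertions.append((rpos, read_seq[qpos : qpos + n]))
            qpos += n
        elif op == "D":
            if rpos < hi and rpos + n > lo:
                deletions.append((rpos, n))
            rpos += n
        elif op == "S":
            qpos += n
    return insertions, deletions


def _insertion_placement_range(ref: str, pos: int, bases: str) -> tuple[int, int]:
    """Leftmost..rightmost equivalent placements of an insertion (inclusive)."""
    pl, sl = pos, bases
    while pl > 0 and ref[pl - 1] == sl[-1]:
        sl = sl[-1] + sl[:-1]
        pl -= 1
    pr, sr = pos, bases
    while pr < len(ref) and ref[pr] == sr[0]:
        sr = sr[1:] + sr[0]
        pr += 1
    return pl, pr


def _deletion_placement_range(ref: str, start: int, length: int) -> tuple[int, int]:
    """Leftmost..rightmost equivalent start positions of a deletion."""
    sl = start
    while sl > 0 and ref[sl - 1] == ref[sl + length - 1]:
        sl -= 1
    sr = start
    while sr + length < len(ref) and ref[sr + length] == ref[sr]:
        sr += 1
    return sl, sr


def _indel_hits_zone(
    ref: str, cut: int, halfwidth: int, insertions, deletions
) -> bool:
    """True when any indel, under some equivalent placement, intersects
    the ``[cut - halfwidth, cut + halfwidth)`` zone."""
    lo, hi = cut - halfwidth, cut + halfwidth
    for pos, bases in insertions:
        pl, pr = _insertion_placement_range(ref, pos, bases)
        # an insertion must be placeable exactly at the cut
        if pl <= cut <= pr:
            return True
    for start, length in deletions:
        sl, sr = _deletion_placement_range(ref, start, length)
        # interval [s, s+length) for s in [sl, sr]
        if sl < hi and sr + length > lo:
            return True
    return False


def _find_mmej_site(
    reference: AmpliconReference, templates: EditTemplates, lo: int, hi: int
) -> int | None:
    """Start of a microhomology-pair deletion interval inside [lo, hi)."""
    mh = templates.mmej_microhomology
    L = templates.mmej_deletion_length
    seq = reference.sequence
    for d in range(max(0, lo), min(hi - L - len(mh), len(seq) - L - len(mh))):
        if seq[d : d + len(mh)] == mh and seq[d + L : d + L + len(mh)] == mh:
            return d
    return None


def _is_mmej_deletion(
    reference: AmpliconReference, del_start: int, del_len: int, templates: EditTemplates
) -> bool:
    """25 bp deletion whose interval is flanked by the microhomology.

    The aligner may place a deletion anywhere within the microhomology
    repeat, so nearby shifts of the interval are accepted.
    """
    if del_len != templates.mmej_deletion_length:
        return False
    mh = templates.mmej_microhomology
    seq = reference.sequence
    for d in range(del_start - len(mh), del_start + len(mh) + 1):
        if d < 0 or d + del_len + len(mh) > len(seq):
            continue
        if seq[d : d + len(mh)] == mh and seq[d + del_len : d + del_len + len(mh)] == mh:
            return True
    return False


def classify_read(
    aln: Alignment,
    read_seq: str,
    reference: AmpliconReference,
    templates: EditTemplates = EditTemplates(),
) -> EditCall:
    """Classify one aligned read's editing outcome."""
    cut = reference.cut_site
    w = templates.window_halfwidth
    lo, hi = cut - w, cut + w
    if lo < 0 or hi > reference.length:
        raise ValueError("classification window outside reference")

    # local re-alignment of the window under indel-preferring scoring
    pad = 5
    wlo = max(0, lo - pad)
    whi = min(reference.length, hi + pad)
    window_seq = _read_window_sequence(aln, read_seq, wlo, whi)
    if window_seq:
        _, _, wops = affine_align(
            window_seq,
            reference.sequence[wlo:whi],
            CLASSIFY_SCORING,
            free_read_ends=False,
            free_ref_ends=False,
        )
        local = Alignment(aln.read_id, aln.ref_name, wlo, aln.strand, wops)
        insertions, deletions = _collect_window_variants(local, window_seq, lo, hi)
    else:
        insertions, deletions = [], []
    net = sum(len(s) for _, s in insertions) - sum(
        min(d + n, hi) - max(d, lo) for d, n in deletions
    )
    inserted = "".join(s for _, s in insertions)

    # 1-2: template-matched insertions (HDR donor or dsODN capture).
    # Require enough inserted mass in the window, then locate the
    # template as an infix of the window read sequence (robust to the
    # aligner scattering or shifting the insertion).
    if inserted:
        candidates = []
        for cat, template in (
            ("hdr", templates.hdr_insert),
            ("dsodn_forward", templates.dsodn),
            ("dsodn_reverse", revcomp(templates.dsodn)),
        ):
            if len(inserted) >= 0.5 * len(template):
                candidates.append((cat, _template_hit_fraction(window_seq, template)))
        candidates = [c for c in candidates if c[1] <= templates.identity_tolerance]
        if candidates:
            cat, ident = min(candidates, key=lambda c: c[1])
            return EditCall(aln.read_id, cat, net, insert_identity=1.0 - ident)

    # 3: large deletion anywhere on the read
    events = merge_deletions(aln, templates.merge_gap)
    big = [e for e in events if e.deleted_bp > templates.large_deletion_threshold]
    if big:
        worst = max(e.deleted_bp for e in big)
        return EditCall(aln.read_id, "large_deletion", -worst, signature=f"-{worst}")

    # 4: small indel at the cut
    if (insertions or deletions) and _indel_hits_zone(
        reference.sequence, cut, templates.signal_halfwidth, insertions, deletions
    ):
        signature = ""
        cut_a_insert = any(
            s == "A" and _insertion_placement_range(reference.sequence, p, s)[0] <= cut
            and _insertion_placement_range(reference.sequence, p, s)[1] >= cut
            for p, s in insertions
        )
        mmej_del = any(
            _is_mmej_deletion(reference, d, n, templates) for d, n in deletions
        )
        if mmej_del:
            signature = f"-{templates.mmej_deletion_length}"
        elif cut_a_insert:
            signature = "+A"
        return EditCall(aln.read_id, "nhej_small_indel", net, signature=signature)

    # 5: hypothesis recovery before calling unmodified.  A 1 bp edit next
    # to a sequencing-error indel is co-optimally absorbed into
    # substitutions and leaves no indel op to find; comparing the window
    # read sequence against explicit templates of the known predominant
    # outcomes (+A insertion; the microhomology deletion) recovers these:
    # the read is strictly closer to the edited template than to the
    # reference exactly when the edit is real.
    if window_seq:
        t0 = reference.sequence[wlo:whi]
        d0 = edlib.align(window_seq, t0, task="distance", mode="NW")["editDistance"]
        t_plus_a = t0[: cut - wlo] + "A" + t0[cut - wlo :]
        d_a = edlib.align(window_seq, t_plus_a, task="distance", mode="NW")["editDistance"]
        mm_start = _find_mmej_site(reference, templates, wlo, whi)
        d_m = None
        if mm_start is not None:
            s = mm_start - wlo
            t_mmej = t0[:s] + t0[s + templates.mmej_deletion_length :]
            d_m = edlib.align(window_seq, t_mmej, task="distance", mode="NW")["editDistance"]
        if d_m is not None and d_m < d0 and d_m <= d_a:
            return EditCall(
                aln.read_id,
                "nhej_small_indel",
                -templates.mmej_deletion_length,
                signature=f"-{templates.mmej_deletion_length}",
            )
        if d_a < d0:
            return EditCall(aln.read_id, "nhej_small_indel", 1, signature="+A")

    return EditCall(aln.read_id, "unmodified", 0)


def tabulate_edits(calls: list[EditCall]) -> EditSummary:
    """Per-sample outcome fractions.

    ``total_editing_pct`` excludes both unmodified and ambiguous reads
    from the numerator; the denominator is all classified reads.
    """
    if not calls:
        raise ValueError("no edit calls to tabulate")
    n = len(calls)
    fractions = {c: 0.0 for c in CATEGORIES}
    plus_a = mmej = 0
    for call in calls:
        fractions[call.category] += 1
        if call.signature == "+A":
            plus_a += 1
        elif call.category == "nhej_small_indel" and call.signature == "-25":
            mmej += 1
    fractions = {k: v / n for k, v in fractions.items()}
    return EditSummary(
        fractions=fractions,
        n_reads=n,
        nhej_pct=100 * fractions["nhej_small_indel"],
        hdr_pct=100 * fractions["hdr"],
        dsodn_pct=100 * (fractions["dsodn_forward"] + fractions["dsodn_reverse"]),
        total_editing_pct=100 * (1 - fractions["unmodified"] - fractions["ambiguous"]),
        plusA_pct=100 * plus_a / n,
        mmej25_pct=100 * mmej / n,
    )
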