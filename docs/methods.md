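# Methods

## Problem and model

A Cas9–gRNA ribonucleoprotein cut is repaired by NHEJ (small indels,
predominantly a +1 A insertion at the blunt cut), MMEJ (deletions between
short microhomologies, e.g. a 25 bp deletion flanked by `CAGGAAG`), HDR
(when a donor template is supplied), blunt dsODN capture, or — in a
substantial minority of alleles — resection producing deletions of
100–2000+ bp. The analysis quantifies that last class from long-PCR
amplicons (4–6 kb around the cut) sequenced as single full-length
nanopore reads.

The measurement model: every sequenced read is one amplicon molecule;
deleted bases produce a coverage deficit against the reference. With
mean per-position depth `d̄` over the full amplicon and `N` demultiplexed
reads, `raw deletion % = 100·(N − d̄)/N` equals the average fraction of
the amplicon missing per read. Sequencing-error deletions contribute a
locus-independent background; subtracting a matched unedited sample's raw
deletion (the **deletion index**, DI) isolates editing-induced loss. DI is
deliberately not clamped at zero — sampling noise makes true-zero samples
fall on both sides. The complementary per-read statistic **Dx** counts
reads with at least one merged deletion event strictly longer than x bp
(x = 100…2000); D100 is more sensitive than DI for rare long deletions
because a read counts equally regardless of deletion length.

## Synthetic data generator

The generator emulates the sequencing inputs the analysis expects, not a
particular instrument in detail:

- **Reference amplicons**: random uniform-composition DNA (configurable GC),
  4–6 kb, with an annotated blunt cut site (3 bp 5′ of the PAM on the
  protospacer strand), optional heterozygous SNPs, and an optional planted
  microhomology pair so the −25 MMEJ allele exists on the locus.
- **Allele mixtures**: weighted classes (unmodified, +A NHEJ, −25 MMEJ,
  other small indels, HDR insert, dsODN forward/reverse, large deletions).
  Large-deletion lengths are drawn once per table from a mixture placing
  ~82 % of mass in 100–1000 bp and <1 % beyond 2 kb, with the interval
  placed uniformly subject to containing the cut. Intervention presets
  scale the large-deletion weight (ssODN ×0.55, dsODN ×0.40, AAV ×0.20
  relative to RNP alone) and add the corresponding donor classes; they are
  generator dials, not measurements.
- **PCR length bias**: sampling weight `w ∝ f·exp(β·(L_ref − L_allele))`
  with per-bp exponent β ≥ 0. β = ln(62/38)/482 reproduces the observation
  that a 482 bp-shorter allele can reach a 62 % read share from an
  expected 50 %.
- **Error model**: per-base substitution (2.0 %), insertion-open (1.5 %)
  and deletion-open (2.225 %) probabilities with geometric indel lengths
  (mean 1.5 bp). The deletion process is a renewal process (no nested
  opens), giving the closed-form deleted-base fraction
  `p_del·E[len]/(1 − p_del + p_del·E[len]) = 3.30 %` — calibrated to the
  ~3.3 % wildtype raw-deletion background this platform shows. Quality
  strings are constant (Q12): the analysis never uses them. Reads are
  emitted on either strand with probability ½; a truncated/chimeric-read
  fraction exists as a knob and defaults to 0.
- **Ground truth**: one record per read (allele class, net indel, largest
  true deletion), used by every recovery test.

What the generator does **not** model: homopolymer-conditioned error
rates, realistic quality strings, PCR chimera structure, signal-level
artefacts, coverage bias along the amplicon. Passing tests therefore
demonstrate estimator correctness under the stated statistical structure,
not robustness to every artefact of real nanopore runs.

## Demultiplexing

Exact (grep-style) barcode matching within the first 100 bases of the
read or of its reverse complement; matching zero or ≥2 barcodes leaves a
read unassigned (there is no score to break ties). Assigned reads are
re-oriented and barcode-trimmed. An optional mismatch tolerance
(infix edit-distance search) exists for real data but defaults to 0.
The barcode generator enforces pairwise Hamming distance ≥3 and excludes
sequences occurring near any amplicon end, so error-free pools demux
perfectly by construction. Reads that fail demultiplexing drop out of the
bin *and its denominator*, mirroring the real workflow where "read depth"
is counted on the demultiplexed file.

## Alignment

Internal aligner: semi-global affine-gap DP (match +2, mismatch −4, gap
open −4, gap extend −2; a gap of length L costs `open + L·extend`), free
end gaps on the reference, soft-clipped read overhangs, optional band
around the scaled diagonal. Correctness is defined by an unbanded
brute-force DP oracle on small instances (property-tested). Affine costs
matter: under unit-cost (Levenshtein) alignment a kilobase deletion has
co-optimal paths shredded into fragments separated by spurious 1–2 bp
chance matches, which corrupts coverage; under affine costs interrupting
a gap never pays.

Production engine: edlib computes the global unit-cost path (terminal
reference gaps become unpenalised overhangs, terminal insertions become
soft clips), then every indel cluster — deletion mass ≥30 bp, insertion
mass ≥5 bp, mixed insertion+deletion ≥3 bp each, or ≥2 gap runs totalling
≥10 bp within a 10 bp chain — is re-aligned globally with the affine DP
over the read/reference interval it spans and spliced back. This
reproduces the affine aligner's deletion structure at ~2–10 ms per 5 kb
read. Reads scoring below `0.3 × match × read length` are reported
unaligned but stay in the metrics denominator (a flag switches to
aligned-only denominators). Primary-only SAM/BAM ingest (CIGAR `M` split
into `=`/`X` against the reference; hard clips treated as soft clips in
read-space accounting) supports external aligners.

Deletion events: consecutive deletion ops separated by ≤10 reference
bases merge into one event whose `deleted_bp` sums only deleted bases.
The merge gap absorbs both error interruptions and co-optimal
fragmentation remnants; background error deletions essentially never
reach 100 bp after merging (WT D100 ≈ 0).

## Edit classification

A window classifier around the cut (±20 bp window). Precedence: HDR
insert match → dsODN match (either orientation) → large deletion
(>100 bp anywhere on the read) → small indel at the cut → unmodified;
substitution-only reads are unmodified. Four refinements make this
robust at nanopore error rates (~1.5 spurious error indels per ±20 bp
window), where the naive "any indel in window" rule would misclassify
most unmodified reads:

1. **Template matching by infix search.** Collected insertion bases gate
   the check (≥half the template length inserted in the window), but the
   template is located by edit-distance infix search in the read's window
   sequence, because alignment placement of an insertion whose edges
   chance-match the reference is ambiguous (the insert comes back
   "rotated"). Identity tolerance 0.25 of template length: at these error
   rates an 18 bp insert carries Poisson(≈1.35) errors and a 0.20 cutoff
   rejects its upper tail.
2. **Local re-alignment under indel-preferring scoring** (match +2,
   mismatch −5, gap open −2, extend −2), so a genuine 1 bp edit adjacent
   to an error indel — which whole-read alignment co-optimally absorbs
   into two substitutions — resurfaces as indel ops, while isolated
   substitutions stay substitutions.
3. **Cut-site qualification zone with indel normalisation.** An indel
   counts as an edit only if some equivalent placement (left/right
   shifted through repeats, as in VCF normalisation) puts an insertion at
   the cut or a deletion interval across it (±1 bp zone).
4. **Hypothesis recovery.** Before calling a read unmodified, its window
   is compared against explicit templates of the known predominant
   outcomes (+A insertion; the −25 microhomology deletion); strictly
   better fit than the reference recovers edits that alignment erased.

Zero-error classification is exact (categories, dsODN orientation, +A/−25
signatures). At default error rates, accuracy on a balanced 8-class
mixture is ≈96 %; the residual is information-theoretic, not
implementation slack — a 1 bp insertion annihilated against a nearby 1 bp
error deletion is genuinely better explained as a substitution, and an
error deletion at the cut is indistinguishable from a true −1 allele.
Class mixtures dominated by 1 bp edits therefore sit lower (~94 %).
dsODN captures are reported as their own category, not folded into HDR
as short-read quantifiers do when given the dsODN as an expected allele;
users comparing to such output should add `dsodn_pct` to `hdr_pct`.

## HDR depletion and LOH

`deplete_hdr` removes HDR-classified reads from numerator and
denominator and recomputes all deletion metrics — the control for the
concern that full-length HDR alleles dilute the deletion signal. When
HDR and non-HDR alleles carry equal deletion rates the depleted metrics
equal the full-set metrics; when HDR alleles are deletion-free, depletion
concentrates the signal (the 1.2 % → 2.0 % covered-base example in the
test suite).

LOH screening counts, per annotated SNP, reads whose aligned base equals
the ref or alt allele (other bases and deletion-spanned positions are
ignored); a clone retains heterozygosity when the minor-allele fraction
is ≥0.2 at every SNP with ≥20 informative reads (boundary inclusive).

## qPCR copy number

Mega-deletions extending beyond the amplicon are detected as copy loss at
probe sites 40–160 kb from the cut: per replicate ΔCt against an internal
reference gene, ΔΔCt against the unedited WT sample, ratio =
`2^−ΔΔCt` (efficiency fixed at 2.0, configurable; no standard-curve
correction). Replicate SD is propagated in Ct space and exponentiated.
The plate simulator inverts the same model (Ct = base − log₂(copies/2) +
noise; zero copies report the 40-cycle detection limit, flagged), so
round-trip recovery is exact at zero noise. A control locus on another
chromosome is handled as just another site label.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; SAM's 1-based POS is
  converted at the I/O boundary.
- Dx thresholds are strict (`>` 100 bp, per "over 100 bp"); events
  anywhere on the amplicon count (no cut-overlap requirement) since
  merged background deletions stay far below 100 bp.
- Mean depth averages over the full reference length including uncovered
  ends.
- DP ties prefer diagonal moves; co-optimal placements of gaps inside
  repeats may shift an event by a few bases between engines — tests
  compare deletion mass and scores, not exact placements.
- The affine DP stores full score/pointer matrices (float32/uint8); the
  polish restricts it to cluster-local segments, capped at 2×10⁷ cells.
- Percent reductions are reported unclamped and with both deletion
  indexes floored at zero (`clamped`), since a below-background DI means
  "no detectable deletions", not negative deletions.
- Descriptive statistics only: group-comparison hypothesis testing is out
  of scope by design.

## Problem sizes

Simulated studies use 5 kb amplicons. Recovery and calibration analyses
run at 10,000 reads per sample, where binomial confidence intervals on
D100 are ±0.6–0.8 pp and deletion-index standard errors are below
0.1 pp; the narrative drivers under `analysis/` default to 1500–3000
reads per sample, which reproduces every qualitative result. With exact
barcode matching, roughly 42 % of error-carrying reads fail demultiplexing
(any error in a 10 nt barcode), so demultiplexed denominators are
correspondingly smaller; this loss is allele-independent and unbiased.

## Known limitations

- The simulator's error process is i.i.d. per base; real nanopore error
  is homopolymer- and context-dependent, and real WT backgrounds vary by
  locus (only the cross-locus mean is calibrated here).
- The fast engine's polish is local: a deletion fragmented across more
  than one cluster window could, in principle, merge differently than
  under the full affine DP (not observed in testing; `engine="affine"`
  is the reference behaviour).
- Chimeric/truncated reads are generated only as full-prefix truncations;
  split-read stitching is out of scope.
- Classification near the Bayes limit (see above) means per-read calls
  should be aggregated, not trusted individually, for 1 bp outcomes.
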