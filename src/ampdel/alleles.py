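"""Editing-outcome allele mixtures.

An edited cell population is modelled as a mixture of allele classes:

* ``unmodified`` — intact amplicon (includes perfectly re-ligated DSBs).
* ``nhej_plusA`` — the predominant +1 insertion (a single A at the cut).
* ``mmej_minus25`` — a 25 bp microhomology-mediated deletion (one copy of
  the flanking microhomology, e.g. CAGGAAG, is retained).
* ``small_indel`` — other small NHEJ indels (|net| <= ~10 bp) at the cut.
* ``large_deletion`` — deletions of 100 bp to >2 kb spanning the cut site.
* ``hdr`` — homology-directed repair installing a defined insert.
* ``dsodn_forward`` / ``dsodn_reverse`` — blunt dsODN captured at the DSB
  by NHEJ in either orientation.

Weights are user-set; named presets encode the study conditions
(RNP alone, RNP+ssODN, RNP+AAV, RNP+dsODN, NHEJ inhibition) as generator
dials for the synthetic scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import revcomp
from .references import AmpliconReference

ALLELE_CLASSES = (
    "unmodified",
    "nhej_plusA",
    "mmej_minus25",
    "small_indel",
    "large_deletion",
    "hdr",
    "dsodn_forward",
    "dsodn_reverse",
)

# Default insert templates.  The dsODN is the 34-nt blunt double-stranded
# tag widely used for DSB capture; 28/29-mers are truncations of it.
DSODN_34 = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"
DSODN_29 = DSODN_34[:29]
DSODN_28 = DSODN_34[:28]
HDR_INSERT_6 = "GAATTC"
HDR_INSERT_8 = "GGATCCAT"
HDR_INSERT_15 = "GCTAGCGAATTCACT"
HDR_INSERT_18 = "ATCGATAAGCTTGAATTC"

MMEJ_MICROHOMOLOGY = "CAGGAAG"
MMEJ_DELETION_LENGTH = 25


@dataclass
class AlleleSpec:
    """One concrete allele in a scenario mixture."""

    allele_class: str
    frequency: float
    indel_length: int = 0  # net signed bp for indel classes; 0 otherwise
    deletion_start: int | None = None  # large_deletion / mmej only
    insert_sequence: str = ""
    allele_length: int = 0  # derived: reference length + net indel

    def __post_init__(self) -> None:
        if self.allele_class not in ALLELE_CLASSES:
            raise ValueError(f"unknown allele class {self.allele_class!r}")
        if self.frequency < 0:
            raise ValueError("allele frequency must be >= 0")

    @property
    def net_indel(self) -> int:
        if self.insert_sequence:
            return len(self.insert_sequence) + self.indel_length
        return self.indel_length

    @property
    def largest_deletion(self) -> int:
        return max(0, -self.indel_length)


def default_deletion_length_sampler(rng: np.random.Generator) -> int:
    """Large-deletion length distribution.

    Roughly 80% of the mass in 100-1000 bp with a thin tail beyond 2 kb,
    matching the observed length spectrum of Cas9-induced large deletions.
    """
    u = rng.random()
    if u < 0.82:
        lo, hi = 101, 1000
    elif u < 0.965:
        lo, hi = 1000, 1500
    elif u < 0.995:
        lo, hi = 1500, 2000
    else:
        lo, hi = 2000, 2500
    return int(rng.integers(lo, hi + 1))


def allele_sequence(reference: AmpliconReference, spec: AlleleSpec) -> str:
    """Materialise the full allele sequence for one AlleleSpec."""
    ref = reference.sequence
    cut = reference.cut_site
    cls = spec.allele_class
    if cls == "unmodified":
        return ref
    if cls in ("nhej_plusA", "hdr", "dsodn_forward", "dsodn_reverse"):
        return ref[:cut] + spec.insert_sequence + ref[cut:]
    if cls in ("mmej_minus25", "large_deletion"):
        start = spec.deletion_start
        length = -spec.indel_length
        if start is None or length <= 0:
            raise ValueError(f"{cls} allele needs deletion_start and negative indel_length")
        return ref[:start] + ref[start + length :]
    if cls == "small_indel":
        if spec.insert_sequence:
            return ref[:cut] + spec.insert_sequence + ref[cut:]
        length = -spec.indel_length
        start = cut - length // 2
        return ref[:start] + ref[start + length :]
    raise ValueError(cls)


def build_allele_table(
    weights: dict[str, float],
    reference: AmpliconReference,
    seed: int = 0,
    *,
    hdr_insert: str = HDR_INSERT_18,
    dsodn: str = DSODN_34,
    mmej_deletion_start: int | None = None,
    mmej_deletion_length: int = MMEJ_DELETION_LENGTH,
    n_large_deletion_alleles: int = 50,
    deletion_length_sampler=default_deletion_length_sampler,
    small_indel_lengths: tuple[int, ...] = (-7, -4, -2, -1, 2, 3),
) -> list[AlleleSpec]:
    """Expand class weights into concrete, normalised AlleleSpecs.

    The ``large_deletion`` weight is split over
    ``n_large_deletion_alleles`` distinct alleles whose lengths are drawn
    from ``deletion_length_sampler`` and whose intervals are placed
    uniformly subject to containing the cut site.  The ``small_indel``
    weight is split uniformly over ``small_indel_lengths``.
    """
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all-zero allele weights")
    for cls in weights:
        if cls not in ALLELE_CLASSES:
            raise ValueError(f"unknown allele class {cls!r}")
        if weights[cls] < 0:
            raise ValueError("allele weights must be >= 0")

    rng = np.random.default_rng(seed)
    ref_len = reference.length
    cut = reference.cut_site
    out: list[AlleleSpec] = []

    def add(spec: AlleleSpec) -> None:
        spec.allele_length = ref_len + spec.net_indel
        out.append(spec)

    for cls, w in weights.items():
        f = w / total
        if f == 0:
            continue
        if cls == "unmodified":
            add(AlleleSpec(cls, f))
        elif cls == "nhej_plusA":
            add(AlleleSpec(cls, f, insert_sequence="A"))
        elif cls == "hdr":
            add(AlleleSpec(cls, f, insert_sequence=hdr_insert))
        elif cls == "dsodn_forward":
            add(AlleleSpec(cls, f, insert_sequence=dsodn))
        elif cls == "dsodn_reverse":
            add(AlleleSpec(cls, f, insert_sequence=revcomp(dsodn)))
        elif cls == "mmej_minus25":
            start = mmej_deletion_start if mmej_deletion_start is not None else cut - 12
            add(
                AlleleSpec(
                    cls, f, indel_length=-mmej_deletion_length, deletion_start=start
                )
            )
        elif cls == "small_indel":
            sub = f / len(small_indel_lengths)
            for ln in small_indel_lengths:
                if ln > 0:
                    codes = rng.integers(0, 4, ln)
                    ins = "".join("ACGT"[c] for c in codes)
                    add(AlleleSpec(cls, sub, insert_sequence=ins))
                else:
                    add(AlleleSpec(cls, sub, indel_length=ln))
        elif cls == "large_deletion":
            sub = f / n_large_deletion_alleles
            for _ in range(n_large_deletion_alleles):
                length = deletion_length_sampler(rng)
                # interval must contain the cut site: start in [cut-length+1, cut]
                lo = max(0, cut - length + 1)
                hi = min(cut, ref_len - length)
                start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, cut - length // 2)
                add(AlleleSpec(cls, sub, indel_length=-length, deletion_start=start))
    s = sum(a.frequency for a in out)
    for a in out:
        a.frequency /= s
    return out


# ---------------------------------------------------------------------------
# Scenario presets (generator dials for the study conditions)
# ---------------------------------------------------------------------------

# Large-deletion allele fraction in the RNP-only control, and the factor by
# which each intervention scales it (ssODN ~45% fewer, dsODN ~60% fewer,
# AAV ~80% fewer large-deletion alleles than RNP alone).
RNP_LARGE_DELETION_FRACTION = 0.10
INTERVENTION_SCALING = {"ssODN": 0.55, "dsODN": 0.40, "AAV": 0.20}


def preset_weights(label: str) -> dict[str, float]:
    """Class-weight presets for the simulated study conditions."""
    ld = RNP_LARGE_DELETION_FRACTION
    if label == "WT":
        return {"unmodified": 1.0}
    if label == "RNP":
        return {
            "unmodified": 0.25,
            "nhej_plusA": 0.30,
            "mmej_minus25": 0.05,
            "small_indel": 0.30,
            "large_deletion": ld,
        }
    if label == "RNP+ssODN":
        return {
            "unmodified": 0.17,
            "nhej_plusA": 0.18,
            "mmej_minus25": 0.03,
            "small_indel": 0.15,
            "hdr": 0.415,
            "large_deletion": ld * INTERVENTION_SCALING["ssODN"],
        }
    if label == "RNP+AAV":
        return {
            "unmodified": 0.21,
            "nhej_plusA": 0.15,
            "mmej_minus25": 0.02,
            "small_indel": 0.10,
            "hdr": 0.50,
            "large_deletion": ld * INTERVENTION_SCALING["AAV"],
        }
    if label == "RNP+dsODN":
        return {
            "unmodified": 0.30,
            "nhej_plusA": 0.22,
            "mmej_minus25": 0.04,
            "small_indel": 0.26,
            "dsodn_forward": 0.08,
            "dsodn_reverse": 0.06,
            "large_deletion": ld * INTERVENTION_SCALING["dsODN"],
        }
    if label == "RNP+M3814":
        # NHEJ inhibition: +A down, MMEJ and large deletions up.
        return {
            "unmodified": 0.28,
            "nhej_plusA": 0.07,
            "mmej_minus25": 0.20,
            "small_indel": 0.28,
            "large_deletion": 0.17,
        }
    raise ValueError(f"unknown preset {label!r}")


def apply_length_bias(
    alleles: list[AlleleSpec], beta: float, reference_length: int
) -> list[AlleleSpec]:
    """Re-weight allele frequencies for PCR length bias.

    Long-range PCR preferentially amplifies shorter templates.  Sampling
    weight ``w_i = f_i * exp(beta * (L_ref - L_i))`` with per-bp exponent
    ``beta >= 0``; ``beta = 0`` is unbiased.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return [replace(a) for a in alleles]
    logw = [
        math.log(a.frequency) + beta * (reference_length - a.allele_length)
        if a.frequency > 0
        else -math.inf
        for a in alleles
    ]
    m = max(logw)
    w = [math.exp(x - m) for x in logw]
    s = sum(w)
    return [replace(a, frequency=wi / s) for a, wi in zip(alleles, w)]
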