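"""Reference amplicons with cut-site and SNP annotation.

An amplicon is the 4-6 kb long-PCR product spanning a Cas9 target site.
The double-strand break (DSB) position follows the SpCas9 blunt-cut
convention: the cut falls 3 bp 5' of the PAM on the protospacer strand,
i.e. between ``cut_site - 1`` and ``cut_site`` in 0-based reference
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import random_dna


@dataclass(frozen=True)
class Snp:
    """A known heterozygous SNP on the amplicon (for LOH checks)."""

    position: int  # 0-based reference index
    ref_allele: str
    alt_allele: str
    rsid: str = ""


@dataclass
class AmpliconReference:
    name: str
    sequence: str
    cut_site: int
    pam_strand: str = "plus"
    snps: tuple[Snp, ...] = ()
    barcode_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"reference {self.name}: sequence contains non-ACGT characters")
        if not (0 < self.cut_site < len(self.sequence)):
            raise ValueError(
                f"reference {self.name}: cut_site {self.cut_site} outside sequence "
                f"of length {len(self.sequence)}"
            )
        if self.pam_strand not in ("plus", "minus"):
            raise ValueError("pam_strand must be 'plus' or 'minus'")
        self.snps = tuple(
            s if isinstance(s, Snp) else Snp(*s) for s in self.snps
        )
        for s in self.snps:
            if not (0 <= s.position < len(self.sequence)):
                raise ValueError(f"SNP {s.rsid or s.position} outside reference {self.name}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def cut_site_from_pam(pam_start: int, pam_strand: str = "plus") -> int:
    """Blunt SpCas9 cut position derived from the PAM location.

    ``pam_start`` is the 0-based reference index of the first PAM base.  On
    the plus strand the protospacer lies 5' of the PAM and the DSB is 3 bp
    upstream of the PAM, so the cut index is ``pam_start - 3``.  On the
    minus strand the protospacer extends to the right of the PAM in
    reference coordinates and the cut index is ``pam_start + 6``.
    """
    if pam_strand == "plus":
        return pam_start - 3
    if pam_strand == "minus":
        return pam_start + 6
    raise ValueError("pam_strand must be 'plus' or 'minus'")


def build_reference(
    length: int = 5000,
    gc_fraction: float = 0.5,
    seed: int = 0,
    *,
    name: str = "amplicon",
    sequence: str | None = None,
    cut_site: int | None = None,
    pam_start: int | None = None,
    pam_strand: str = "plus",
    snps: Sequence[Snp | tuple] = (),
    barcode_id: str | None = None,
) -> AmpliconReference:
    """Build (or annotate) a reference amplicon.

    Either pass a ``sequence`` (user-supplied amplicon, annotated as-is) or
    let a random sequence of the requested length/GC be generated
    deterministically from ``seed``.  The cut site is given explicitly or
    derived from a PAM location via the blunt-cut convention.
    """
    if sequence is None:
        if length < 500:
            raise ValueError("amplicon length must be >= 500")
        rng = np.random.default_rng(seed)
        sequence = random_dna(length, rng, gc_fraction)
    if cut_site is None:
        if pam_start is None:
            raise ValueError("provide either cut_site or pam_start")
        cut_site = cut_site_from_pam(pam_start, pam_strand)
    if not (0 < cut_site < len(sequence)):
        raise ValueError(f"cut site {cut_site} outside sequence of length {len(sequence)}")
    return AmpliconReference(
        name=name,
        sequence=sequence,
        cut_site=cut_site,
        pam_strand=pam_strand,
        snps=tuple(snps),
        barcode_id=barcode_id,
    )


def plant_microhomology(
    reference: AmpliconReference,
    microhomology: str = "CAGGAAG",
    deletion_length: int = 25,
    offset_5p: int = 12,
) -> tuple[AmpliconReference, int]:
    """Embed an MMEJ-competent microhomology pair around the cut site.

    Writes two copies of ``microhomology`` separated by ``deletion_length``
    bp so that deleting ``[start, start + deletion_length)`` removes one
    copy plus the spacer and leaves a single copy — the canonical
    microhomology-mediated end-joining (MMEJ) outcome.  The deletion
    interval contains the cut site (``offset_5p`` bases lie 5' of the cut).

    Returns the modified reference and the deletion start index.
    """
    mh = microhomology.upper()
    start = reference.cut_site - offset_5p
    if start < 0 or start + deletion_length + len(mh) > reference.length:
        raise ValueError("microhomology site does not fit around the cut site")
    seq = list(reference.sequence)
    seq[start : start + len(mh)] = mh
    seq[start + deletion_length : start + deletion_length + len(mh)] = mh
    modified = AmpliconReference(
        name=reference.name,
        sequence="".join(seq),
        cut_site=reference.cut_site,
        pam_strand=reference.pam_strand,
        snps=reference.snps,
        barcode_id=reference.barcode_id,
    )
    return modified, start


def write_references(
    references: Iterable[AmpliconReference], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write references as FASTA plus a JSON sidecar of annotations."""
    references = list(references)
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in references
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = {
        r.name: {
            "cut_site": r.cut_site,
            "pam_strand": r.pam_strand,
            "barcode_id": r.barcode_id,
            "snps": [
                {"position": s.position, "ref": s.ref_allele, "alt": s.alt_allele, "rsid": s.rsid}
                for s in r.snps
            ],
        }
        for r in references
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_references(fasta_path: str | Path, sidecar_path: str | Path) -> list[AmpliconReference]:
    meta = json.loads(Path(sidecar_path).read_text())
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = meta[rec.id]
        out.append(
            AmpliconReference(
                name=rec.id,
                sequence=str(rec.seq),
                cut_site=m["cut_site"],
                pam_strand=m.get("pam_strand", "plus"),
                snps=tuple(
                    Snp(s["position"], s["ref"], s["alt"], s.get("rsid", "")) for s in m.get("snps", [])
                ),
                barcode_id=m.get("barcode_id"),
            )
        )
    return out
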