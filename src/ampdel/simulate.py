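"""Synthetic nanopore-read generator with per-read ground truth.

Each simulated read is a full-length long-PCR amplicon copy: the sample
barcode followed by one allele sequence, with sequencing errors applied
to the whole molecule and the read emitted on either strand with equal
probability.  A TruthRecord per read carries the allele class and true
deletion size for recovery tests.

Also includes a small qPCR plate simulator for the mega-deletion
copy-number assay (Ct values under the 2^-ddCt model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dna
from .alleles import AlleleSpec, allele_sequence, apply_length_bias
from .errors import ErrorModel, apply_errors
from .references import AmpliconReference


@dataclass
class EditScenario:
    reference: AmpliconReference
    alleles: list[AlleleSpec]
    n_reads: int
    seed: int
    label: str = "sample"
    length_bias_beta: float = 0.0
    truncated_fraction: float = 0.0  # chimeric/truncated reads; default off


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    allele_class: str
    net_indel_bp: int
    largest_true_deletion_bp: int
    sample_label: str


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


def simulate_reads(
    scenario: EditScenario,
    error_model: ErrorModel,
    barcode: str = "",
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Generate reads and matching ground truth for one scenario.

    Deterministic for a fixed ``scenario.seed`` (byte-identical FASTQ and
    truth output across runs).
    """
    if scenario.n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not scenario.alleles:
        raise ValueError("empty allele table")
    rng = np.random.default_rng(scenario.seed)
    ref = scenario.reference
    biased = apply_length_bias(scenario.alleles, scenario.length_bias_beta, ref.length)
    freqs = np.array([a.frequency for a in biased])
    freqs = freqs / freqs.sum()

    allele_codes = [
        np.concatenate(
            [dna.encode(barcode), dna.encode(allele_sequence(ref, a))]
        )
        if barcode
        else dna.encode(allele_sequence(ref, a))
        for a in scenario.alleles
    ]

    n = scenario.n_reads
    choices = rng.choice(len(biased), size=n, p=freqs) if n else np.array([], int)
    flips = rng.random(n) < 0.5
    truncs = rng.random(n) < scenario.truncated_fraction if n else np.array([], bool)

    qchar = chr(error_model.q_const + 33)
    reads: list[SimRead] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        a = scenario.alleles[int(choices[i])]
        codes = apply_errors(allele_codes[int(choices[i])], error_model, rng)
        if truncs[i] and len(codes) > 400:
            keep = int(len(codes) * rng.uniform(0.2, 0.8))
            codes = codes[:keep]
        if flips[i]:
            codes = dna.revcomp_codes(codes)
        read_id = f"{scenario.label}_read{i:06d}"
        reads.append(SimRead(read_id, dna.decode(codes), qchar * len(codes)))
        truth.append(
            TruthRecord(
                read_id=read_id,
                allele_class=a.allele_class,
                net_indel_bp=a.net_indel,
                largest_true_deletion_bp=a.largest_deletion,
                sample_label=scenario.label,
            )
        )
    return reads, truth


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(SimRead(rec.id, str(rec.seq), quals))
    return out


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_label\tallele_class\tnet_indel_bp\tlargest_true_deletion_bp\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.sample_label}\t{t.allele_class}\t"
                f"{t.net_indel_bp}\t{t.largest_true_deletion_bp}\n"
            )


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

DETECTION_LIMIT_CT = 40.0


def simulate_qpcr_plate(
    clone_copies: dict[str, dict[str, int]],
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate Ct values for diploid copy-number clones.

    ``clone_copies`` maps sample_id -> {site_label: copies in {0, 1, 2}}.
    Under 100% amplification efficiency a sample with ``c`` copies at a
    site has ``Ct = base_ct - log2(c / 2) + noise``; the internal
    reference gene is fixed at 2 copies.  Sites with 0 copies report the
    detection-limit Ct (flagged in the ``at_detection_limit`` column).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id in sorted(clone_copies):
        sites = clone_copies[sample_id]
        for site in sorted(sites):
            copies = sites[site]
            if copies not in (0, 1, 2):
                raise ValueError("copy counts must be 0, 1 or 2")
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                ref_noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                if copies == 0:
                    tct, flag = DETECTION_LIMIT_CT, True
                else:
                    tct = base_ct - np.log2(copies / 2.0) + noise
                    flag = False
                rows.append(
                    {
                        "sample_id": sample_id,
                        "site_label": site,
                        "replicate": rep,
                        "target_ct": round(float(tct), 6),
                        "reference_ct": round(float(reference_ct + ref_noise), 6),
                        "at_detection_limit": flag,
                    }
                )
    return pd.DataFrame(rows)
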