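"""Small DNA utilities shared across the package.

Sequences are plain uppercase ``ACGT`` strings at module boundaries; the
simulator works internally on ``uint8`` arrays with the 2-bit code
A=0, C=1, G=2, T=3 (complement is then ``3 - code``).
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# ASCII -> 0..3 lookup (255 marks non-ACGT)
_ASCII2CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ASCII2CODE[ord(_b)] = _c
    _ASCII2CODE[ord(_b.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of 2-bit codes."""
    codes = _ASCII2CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a 2-bit code array back to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_dna(length: int, rng: np.random.Generator, gc_fraction: float = 0.5) -> str:
    """Random DNA with the requested expected GC content."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode(codes)


def hamming(a: str, b: str) -> int:
    """Hamming distance over the common prefix length plus the length gap."""
    n = min(len(a), len(b))
    return sum(x != y for x, y in zip(a[:n], b[:n])) + abs(len(a) - len(b))
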