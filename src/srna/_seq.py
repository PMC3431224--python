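"""Nucleotide-string helpers shared across the package.

Sequences are stored in the DNA alphabet (ACGT) internally and rendered in
the RNA alphabet (ACGU) on report; references and reads may arrive in either.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def to_dna(seq: str) -> str:
    """Normalize to the uppercase DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render in the uppercase RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def check_nucleotides(seq: str) -> str:
    s = to_dna(seq)
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string from a seeded generator."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3 as a uint8 array (input must be normalized DNA)."""
    table = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    arr = table[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr
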