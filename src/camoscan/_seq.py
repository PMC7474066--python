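"""Nucleotide encoding helpers shared by all stages.

Sequences are held as ``numpy.uint8`` arrays with A=0, C=1, G=2, T=3, N=4.
Soft-masked (lowercase) input is uppercased on encode; every letter outside
ACGT maps to N.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: IUPAC code for each biallelic (heterozygous) base pair.
IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
#: Reverse lookup: ambiguity code -> the two bases, alphabetically sorted.
HET_BASES = {code: tuple(sorted(pair)) for pair, code in IUPAC_HET.items()}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(code: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase string."""
    return _DEC[code].tobytes().decode("ascii")


def revcomp(code: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array (N stays N)."""
    rc = code[::-1]
    return np.where(rc < 4, 3 - rc, np.uint8(N)).astype(np.uint8)


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def gc_fraction(code: np.ndarray) -> float:
    acgt = code[code < 4]
    if acgt.size == 0:
        return float("nan")
    return float(np.mean((acgt == C) | (acgt == G)))
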