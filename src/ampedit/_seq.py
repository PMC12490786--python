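"""Low-level DNA helpers shared across modules.

Sequences are plain upper-case strings over {A,C,G,T,N}; hot paths encode
them as uint8 arrays (ASCII codes) for vectorised comparison.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMP = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

# ASCII-indexed complement table for uint8-encoded sequences
_COMP_U8 = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_U8[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_U8[arr][::-1]


def validate_dna(seq: str, *, allow_n: bool = True, what: str = "sequence") -> None:
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)!r}")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    if len(a) > 64:
        return int((encode(a) != encode(b)).sum())
    return sum(x != y for x, y in zip(a, b))


# IUPAC nucleotide codes -> set of matched bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def iupac_match(pattern: str, seq: str) -> bool:
    """True if `seq` matches the IUPAC `pattern` position by position."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC.get(p, "") for p, s in zip(pattern, seq))


def iupac_mask(pattern_char: str) -> np.ndarray:
    """Boolean lookup over ASCII codes: which uint8 base codes match the code."""
    mask = np.zeros(256, dtype=bool)
    for b in IUPAC.get(pattern_char, ""):
        mask[ord(b)] = True
    return mask
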