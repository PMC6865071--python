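"""Internal sequence codec helpers shared across modules.

Sequences are held in two forms: Python strings at module boundaries, and
uint8 code arrays (A=0, C=1, G=2, T=3, N=4) for vectorised inner loops.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement in code space; N -> N
_COMP_LUT = np.array([T, G, C, A, N], dtype=np.uint8)

_DNA_SET = frozenset("ACGT")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into a uint8 code array."""
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a string."""
    return _DECODE_LUT[codes].tobytes().decode()


def decode_rows(matrix: np.ndarray) -> list[str]:
    """Decode each row of a 2-D code matrix into a string."""
    raw = _DECODE_LUT[matrix].tobytes()
    w = matrix.shape[1]
    return [raw[i : i + w].decode() for i in range(0, len(raw), w)]


def revcomp(seq: str) -> str:
    return decode(_COMP_LUT[encode(seq)][::-1])


def revcomp_codes(matrix: np.ndarray) -> np.ndarray:
    """Reverse-complement each row of a code matrix."""
    return _COMP_LUT[matrix][..., ::-1]


def is_dna(seq: str) -> bool:
    """True if non-empty and over the strict {A,C,G,T} alphabet."""
    return len(seq) > 0 and set(seq) <= _DNA_SET


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
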