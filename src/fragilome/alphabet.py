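"""Base-level encoding of DNA sequences.

Genomes are strings over {A, C, G, T} with tolerated IUPAC ambiguity codes.
Internally sequences are handled as ``uint8`` code arrays with A,C,G,T ->
0,1,2,3 and every other character mapped to the sentinel :data:`NON_ACGT`.
The lexicographic base order A < C < G < T fixes the index order of every
serialized tuple-distribution vector (AA.. before AC.. etc.).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: Sentinel code for any character outside {A, C, G, T} (case-insensitive).
NON_ACGT: int = 255

_ENCODE_LUT = np.full(256, NON_ACGT, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence string to a uint8 code array (A,C,G,T -> 0..3)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a code array back to a string; non-ACGT codes render as ``N``."""
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = _DECODE_LUT[codes[ok]]
    return out.tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement a code array (A<->T, C<->G); non-ACGT stays non-ACGT."""
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return out


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a sequence string (non-ACGT -> N)."""
    return decode(complement_codes(encode(sequence))[::-1])
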