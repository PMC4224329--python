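"""Low-level sequence encoding helpers.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, ambiguity codes)
maps to 4.  Complement of a valid code is ``3 - code``; 4 is self-complementary.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASES_N = "ACGTN"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES_N.encode(), dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a base string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a base string."""
    return _DECODE[codes].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, N_CODE).astype(np.uint8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement_codes(codes)[::-1]


def revcomp(seq: str) -> str:
    """Reverse-complement a base string (N-preserving)."""
    return seq.translate(_COMP_TABLE)[::-1]
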