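"""Base encoding shared by the simulator and the error-rate statistic.

Bases are coded A=0, C=1, G=2, T=3; N (or any other symbol) codes as 4 and
is excluded from every numerator and denominator downstream.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

#: The 12 possible single-base substitutions, reference>observed, in the
#: canonical order A>C, A>G, A>T, C>A, C>G, C>T, G>A, G>C, G>T, T>A, T>C, T>G.
SUBSTITUTIONS: tuple[str, ...] = tuple(
    f"{r}>{o}" for r in BASES for o in BASES if o != r
)

_LUT = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to int8 codes (N and unknowns -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode int8 codes back to an ACGTN string."""
    return "".join("ACGTN"[c] for c in codes)


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def substitution_index(ref_codes: np.ndarray, obs_codes: np.ndarray) -> np.ndarray:
    """Map (ref, obs) code pairs to indices into SUBSTITUTIONS.

    Only valid where both codes are in 0..3 and differ.
    """
    return ref_codes * 3 + obs_codes - (obs_codes > ref_codes)


def substitution_name(ref_code: int, obs_code: int) -> str:
    return f"{BASES[ref_code]}>{BASES[obs_code]}"
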