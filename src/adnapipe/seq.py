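"""Nucleotide sequence utilities.

Sequences are handled internally as ``numpy.uint8`` code arrays with
A=0, C=1, G=2, T=3 and 4 reserved for the gap character ``-``.  The
complement of code ``c`` is ``3 - c``, which makes reverse complementing
a one-liner.  Transitions are A<->G and C<->T, i.e. the two codes of a
transition pair sum to 2 (A,G) or 4 (C,T) -- equivalently they have the
same parity.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
GAP_CODE = 4
_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = GAP_CODE


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT (optionally gapped) string into a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = chr(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[arr == 255][0])
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array (gap code 4 becomes ``-``)."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def is_transition(a: int, b: int) -> bool:
    """True for A<->G or C<->T code pairs (a != b assumed)."""
    return a != b and (a & 1) == (b & 1)


def is_transversion(a: int, b: int) -> bool:
    return a != b and (a & 1) != (b & 1)
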