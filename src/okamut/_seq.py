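"""Low-level sequence helpers shared across the package.

Sequences are plain uppercase DNA strings over {A,C,G,T,N}. For numeric
work they are encoded as int8 arrays with A=0, C=1, G=2, T=3 and N (or any
other symbol) = 4; two codes are Watson-Crick complementary iff they sum
to 3, which makes N unpairable by construction.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A0 C1 G2 T3, other 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def pairs(a: str, b: str) -> bool:
    """True iff single bases a and b are Watson-Crick complementary."""
    x, y = _CODE[ord(a)], _CODE[ord(b)]
    return int(x) + int(y) == 3


def identity(a: str, b: str) -> float:
    """Ungapped identity fraction between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("identity() requires equal-length strings")
    if not a:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)
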