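"""Low-level DNA sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")

# base -> 2-bit code; anything unexpected (N, etc.) maps to 255
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE[_b] = _i
    CODE[ord(chr(_b).lower())] = _i

BASES = "ACGT"
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 code array (A=0 C=1 G=2 T=3, 255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode(codes)


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc
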