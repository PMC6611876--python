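"""Low-level DNA helpers shared by the aligner and the simulator.

Sequences are handled either as Python ``str`` (uppercase A/C/G/T/N) or as
``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4); the 2-bit code form
is what the k-mer machinery operates on.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

#: byte value -> code lookup (A=0 C=1 G=2 T=3, N and anything else =4)
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _ENC[_b] = _c
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of a sequence.

    Returns ``(positions, kmers)`` where ``kmers[i]`` is the base-4 integer of
    the k-mer starting at ``positions[i]``; windows containing N are omitted.
    Requires k <= 31 (codes fit in uint64).
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    ok = np.ones(m, dtype=bool)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        window = c64[j : j + m]
        vals = vals * np.uint64(4) + np.where(window < 4, window, 0)
        ok &= window < 4
    pos = np.nonzero(ok)[0]
    return pos.astype(np.int64), vals[pos]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the given GC content."""
    at = (1.0 - gc) / 2.0
    gcp = gc / 2.0
    codes = rng.choice(4, size=length, p=[at, gcp, gcp, at]).astype(np.uint8)
    return decode(codes)
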