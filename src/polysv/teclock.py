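"""Kimura two-parameter divergence and LTR insertion-time dating.

K2P separates transitions (proportion P) and transversions (Q):
K = −½ ln((1−2P−Q)·sqrt(1−2Q)).  Insertion ages follow the molecular-clock
form t = K / (2r) with a substitution rate r per site per year (default
7e-9, the usual grass/cotton LTR rate).  This module consumes aligned or
alignable sequence pairs (5'/3' LTRs, or TE copy vs family consensus);
discovering full-length elements is upstream of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import align_ops

DEFAULT_RATE = 7e-9

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DivergenceRecord:
    element_id: str
    P: float
    Q: float
    K: float | None  # None when saturated
    age: float | None = None
    length: int = 0

    @property
    def saturated(self) -> bool:
        return self.K is None


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float | None]:
    """Transition/transversion proportions and the K2P distance.

    Columns where either sequence has a gap ('-') or N are excluded from the
    denominator.  Returns ``(P, Q, K)`` with ``K=None`` when the distance is
    saturated (1−2P−Q ≤ 0 or 1−2Q ≤ 0).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    counted = transitions = transversions = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        counted += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if counted == 0:
        raise ValueError("no comparable columns")
    P = transitions / counted
    Q = transversions / counted
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return P, Q, None
    return P, Q, -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(K: float, rate: float = DEFAULT_RATE) -> float:
    """Insertion age in years, t = K/(2r)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return K / (2.0 * rate)


def date_pair(element_id: str, seq_a: str, seq_b: str,
              rate: float = DEFAULT_RATE, aligned: bool = False
              ) -> DivergenceRecord:
    """K2P-date one sequence pair, aligning it first unless ``aligned``."""
    if not aligned:
        seq_a, seq_b = _gapped(seq_a, seq_b)
    P, Q, K = k2p_distance(seq_a, seq_b)
    age = insertion_time(K, rate) if K is not None else None
    n = sum(1 for x in seq_a if x != "-")
    return DivergenceRecord(element_id, P, Q, K, age, n)


def _gapped(a: str, b: str) -> tuple[str, str]:
    """Pairwise global alignment expanded to two gapped strings."""
    out_a, out_b = [], []
    ia = ib = 0
    for op, n in align_ops(a, b):  # a is the query, b the target
        if op in "=X":
            out_a.append(a[ia : ia + n])
            out_b.append(b[ib : ib + n])
            ia += n
            ib += n
        elif op == "I":
            out_a.append(a[ia : ia + n])
            out_b.append("-" * n)
            ia += n
        else:
            out_a.append("-" * n)
            out_b.append(b[ib : ib + n])
            ib += n
    return "".join(out_a), "".join(out_b)


def divergence_landscape(copies: list[tuple[str, str, str]],
                         bin_width: float = 0.01,
                         rate: float = DEFAULT_RATE) -> pd.DataFrame:
    """Genome-bp-weighted histogram of copy-to-consensus K2P divergence.

    ``copies`` holds (element_id, copy_sequence, family_consensus) triples.
    Each copy is aligned to its consensus and dated; histogram mass is the
    copy length in bp (a count-weighted column is included too, since both
    conventions appear in the literature).  Saturated copies land in an
    overflow bin.  Percentages sum to 100.
    """
    records = [date_pair(eid, c, cons, rate) for eid, c, cons in copies]
    finite = [r for r in records if not r.saturated]
    max_k = max((r.K for r in finite), default=0.0)
    n_bins = int(max_k // bin_width) + 1
    rows = []
    for i in range(n_bins):
        lo, hi = i * bin_width, (i + 1) * bin_width
        sel = [r for r in finite if lo <= r.K < hi]
        rows.append(dict(bin_low=lo, bin_high=hi,
                         bp=sum(r.length for r in sel), n=len(sel)))
    saturated = [r for r in records if r.saturated]
    if saturated:
        rows.append(dict(bin_low=float("inf"), bin_high=float("inf"),
                         bp=sum(r.length for r in saturated), n=len(saturated)))
    df = pd.DataFrame(rows)
    total_bp = df["bp"].sum()
    total_n = df["n"].sum()
    df["percent_bp"] = 100.0 * df["bp"] / total_bp if total_bp else 0.0
    df["percent_count"] = 100.0 * df["n"] / total_n if total_n else 0.0
    return df


def records_table(records: list[DivergenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(element_id=r.element_id, P=r.P, Q=r.Q,
              K=np.nan if r.K is None else r.K,
              age=np.nan if r.age is None else r.age,
              saturated=r.saturated, length=r.length)
         for r in records]
    )
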