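"""Global affine-gap (Needleman-Wunsch/Gotoh) alignment.

Scoring follows EMBOSS-needle defaults for DNA: match +5, mismatch −4,
gap open 10, gap extend 0.5, where a gap of length L costs
``gap_open + (L−1)·gap_extend`` (the first gap base is charged the open
penalty only).  `N` scores 0 against anything.

All penalties are multiples of 0.5, so float64 arithmetic is exact and the
dynamic program and its traceback are fully deterministic.  Traceback
preference: diagonal (match/mismatch) over gaps, and gap-in-query over
gap-in-reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import validate_dna

_NEG = -1e18  # effectively -inf but safe under addition


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: gapped query/reference strings + score."""

    aligned_query: str
    aligned_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_ref.replace("-", "")


def align_global(query: str, reference: str, *, gap_open: float = 10.0,
                 gap_extend: float = 0.5, match: float = 5.0,
                 mismatch: float = -4.0) -> Alignment:
    """Optimal global alignment of ``query`` against ``reference``.

    Returns the (deterministically tie-broken) optimal alignment under the
    affine gap model described in the module docstring.

    Raises
    ------
    ValueError
        If either sequence is empty or contains characters outside ACGTN.
    """
    if not query or not reference:
        raise ValueError("sequences must be nonempty")
    validate_dna(query, what="query")
    validate_dna(reference, what="reference")

    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(reference.encode(), dtype=np.uint8)
    n, m = len(q), len(r)

    # substitution score of q[i-1] vs every reference base, per row
    r_is_n = r == ord("N")

    # D: best ending in a diagonal step; U: ending in an up step (gap in
    # reference, query base consumed); L: ending in a left step (gap in
    # query, reference base consumed).
    D = np.full((n + 1, m + 1), _NEG)
    U = np.full((n + 1, m + 1), _NEG)
    L = np.full((n + 1, m + 1), _NEG)
    D[0, 0] = 0.0
    j_idx = np.arange(1, m + 1, dtype=np.float64)
    L[0, 1:] = -(gap_open + (j_idx - 1) * gap_extend)
    i_col = np.arange(1, n + 1, dtype=np.float64)
    U[1:, 0] = -(gap_open + (i_col - 1) * gap_extend)

    ext_idx = np.arange(m + 1, dtype=np.float64) * gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        if qi == ord("N"):
            s = np.zeros(m)
        else:
            s = np.where(r == qi, match, mismatch)
            s[r_is_n] = 0.0
        best_prev = np.maximum(np.maximum(D[i - 1], U[i - 1]), L[i - 1])
        D[i, 1:] = s + best_prev[:-1]
        U[i, 1:] = np.maximum(
            np.maximum(D[i - 1, 1:], L[i - 1, 1:]) - gap_open,
            U[i - 1, 1:] - gap_extend)
        # L row: L[i,j] = max_{k<j} max(D,U)[i,k] − open − (j−1−k)·extend,
        # computed with a running max over the transformed row.
        du = np.maximum(D[i], U[i])
        run = np.maximum.accumulate(du + ext_idx)
        L[i, 1:] = run[:-1] - gap_open - ext_idx[:-1]

    return _traceback(query, reference, D, U, L, gap_open, gap_extend,
                      match, mismatch)


def _traceback(query: str, reference: str, D, U, L,
               gap_open: float, gap_extend: float,
               match: float, mismatch: float) -> Alignment:
    n, m = len(query), len(reference)
    i, j = n, m
    # preference: diagonal, then gap-in-query (L), then gap-in-reference (U)
    score = max(D[n, m], L[n, m], U[n, m])
    if D[n, m] == score:
        state = "D"
    elif L[n, m] == score:
        state = "L"
    else:
        state = "U"

    aq: list[str] = []
    ar: list[str] = []
    while i > 0 or j > 0:
        if state == "D":
            aq.append(query[i - 1])
            ar.append(reference[j - 1])
            target = D[i, j] - _subst(query[i - 1], reference[j - 1],
                                      match, mismatch)
            i, j = i - 1, j - 1
        elif state == "L":
            aq.append("-")
            ar.append(reference[j - 1])
            target = None
            # origin of the left gap at (i, j-1)
            val = L[i, j]
            j -= 1
            if D[i, j] - gap_open == val:
                state = "D"
                continue
            if L[i, j] - gap_extend == val:
                state = "L"
                continue
            state = "U"
            continue
        else:  # U
            aq.append(query[i - 1])
            ar.append("-")
            val = U[i, j]
            i -= 1
            if D[i, j] - gap_open == val:
                state = "D"
                continue
            if L[i, j] - gap_open == val:
                state = "L"
                continue
            state = "U"
            continue
        if i == 0 and j == 0:
            break
        if D[i, j] == target:
            state = "D"
        elif L[i, j] == target:
            state = "L"
        else:
            state = "U"

    return Alignment("".join(reversed(aq)), "".join(reversed(ar)),
                     float(max(D[n, m], L[n, m], U[n, m])))


def _subst(a: str, b: str, match: float = 5.0, mismatch: float = -4.0) -> float:
    if a == "N" or b == "N":
        return 0.0
    return match if a == b else mismatch
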