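"""Independent reference implementations used only as test oracles.

Each oracle is deliberately written in a different style from the package
code it checks (top-down memoised recursion vs bottom-up vectorised DP,
character loops vs numpy scans) so agreement is informative.
"""

from __future__ import annotations

import sys
from functools import lru_cache

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def affine_score_recursive(q: str, r: str, gap_open: float = 10.0,
                           gap_extend: float = 0.5, match: float = 5.0,
                           mismatch: float = -4.0) -> float:
    """Optimal global affine-gap score by memoised top-down recursion.

    A gap of length L costs gap_open + (L-1)*gap_extend.
    """
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(q) and j == len(r):
            return 0.0
        options = []
        if i < len(q) and j < len(r):
            s = 0.0 if "N" in (q[i], r[j]) else \
                (match if q[i] == r[j] else mismatch)
            options.append(s + best(i + 1, j + 1, "D"))
        if i < len(q):
            cost = gap_extend if state == "U" else gap_open
            options.append(-cost + best(i + 1, j, "U"))
        if j < len(r):
            cost = gap_extend if state == "L" else gap_open
            options.append(-cost + best(i, j + 1, "L"))
        return max(options)

    return best(0, 0, "start")


def affine_score_enumerate(q: str, r: str, gap_open: float = 10.0,
                           gap_extend: float = 0.5, match: float = 5.0,
                           mismatch: float = -4.0) -> float:
    """Optimal score by brute-force enumeration of every alignment path.

    Exponential; only usable for very short sequences.  Used to validate
    the recursive oracle itself.
    """
    best_score = [-float("inf")]

    def walk(i: int, j: int, state: str, score: float) -> None:
        if i == len(q) and j == len(r):
            best_score[0] = max(best_score[0], score)
            return
        if i < len(q) and j < len(r):
            s = 0.0 if "N" in (q[i], r[j]) else \
                (match if q[i] == r[j] else mismatch)
            walk(i + 1, j + 1, "D", score + s)
        if i < len(q):
            walk(i + 1, j, "U",
                 score - (gap_extend if state == "U" else gap_open))
        if j < len(r):
            walk(i, j + 1, "L",
                 score - (gap_extend if state == "L" else gap_open))

    walk(0, 0, "start", 0.0)
    return best_score[0]


def naive_offtarget_scan(contigs: dict, spacer: str, pam: str,
                         max_mm: int) -> list[tuple]:
    """Position-by-position candidate-site scan, both strands.

    Returns sorted (contig, start, strand, site_seq, pam_seq, mismatch
    positions) tuples; N in the reference counts as a mismatch.
    """
    out = []
    for name, seq in contigs.items():
        L = len(seq)
        for i in range(L - 20 + 1):
            for strand in "+-":
                win = seq[i:i + 20]
                if strand == "+":
                    if i + 23 > L:
                        continue
                    site, p = win, seq[i + 20:i + 23]
                else:
                    if i < 3:
                        continue
                    site, p = rc(win), rc(seq[i - 3:i])
                mm = tuple(k + 1 for k in range(20)
                           if site[k] != spacer[k] or site[k] == "N")
                if len(mm) > max_mm:
                    continue
                if not all(b in IUPAC_SETS.get(c, "") for c, b in zip(pam, p)):
                    continue
                out.append((name, i, strand, site, p, mm))
    return sorted(out)


# transcription of the public MIT/Hsu hit-score formula, computed straight
# from the two sequences rather than from precomputed mismatch positions
_HIT_SCORE_M = [0, 0, 0.014, 0, 0, 0.395, 0.317, 0, 0.389, 0.079, 0.445,
                0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]


def calc_hit_score(guide: str, otseq: str) -> float:
    assert len(guide) == len(otseq) == 20
    mm_pos = [i for i in range(20) if guide[i] != otseq[i]]
    score1 = 1.0
    for pos in mm_pos:
        score1 *= 1 - _HIT_SCORE_M[pos]
    if len(mm_pos) == 0:
        return 100.0
    if len(mm_pos) == 1:
        return 100.0 * score1
    dists = []
    for i in range(len(mm_pos)):
        for j in range(i + 1, len(mm_pos)):
            dists.append(abs(mm_pos[i] - mm_pos[j]))
    avg_dist = sum(dists) / len(dists)
    score2 = 1.0 / (((19.0 - avg_dist) / 19.0) * 4.0 + 1.0)
    score3 = 1.0 / (len(mm_pos) ** 2)
    return 100.0 * score1 * score2 * score3
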