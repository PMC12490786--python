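"""Candidate off-target enumeration and MIT-style specificity ranking.

A 20-nt spacer is scanned against both strands of a reference sequence; a
window is a candidate when its Hamming distance to the spacer (no bulges)
is at most ``max_mismatches`` and the 3 nt immediately 3' of it match the
IUPAC PAM pattern (default ``NNN``, i.e. unconstrained).  Candidates are
ranked by the MIT (Hsu) specificity score; selection keeps every site with
fewer than the maximum number of mismatches and fills the remaining slots
with the best-scoring maximal-mismatch sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, iupac_mask, revcomp, validate_dna
from .locus import PROTOSPACER_LEN

#: Published 20-entry MIT/Hsu position weight vector (protospacer positions
#: 1..20, PAM-distal to PAM-proximal).  External constant from the
#: Hsu et al. specificity model as distributed with public scoring tools.
MIT_WEIGHTS = (
    0.0, 0.0, 0.014, 0.0, 0.0,
    0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass(frozen=True)
class SpacerQuery:
    """A spacer with its PAM pattern and mismatch budget."""

    spacer: str
    pam_pattern: str = "NNN"
    max_mismatches: int = 4

    def __post_init__(self) -> None:
        validate_dna(self.spacer, allow_n=False, what="spacer")
        if len(self.spacer) != PROTOSPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be ≥ 0")
        if len(self.pam_pattern) != 3:
            raise ValueError("pam_pattern must be a 3-mer")


@dataclass(frozen=True)
class CandidateSite:
    """One putative off-target locus."""

    contig: str
    start: int                # 0-based half-open interval start of the 20-mer
    strand: str
    site_sequence: str        # on the spacer-matching strand
    pam: str                  # 3 nt immediately 3' on that strand
    mismatch_count: int
    mismatch_positions: tuple[int, ...]   # protospacer positions, 1-based
    score: float

    def __post_init__(self) -> None:
        if self.mismatch_count != len(self.mismatch_positions):
            raise ValueError("mismatch count inconsistent with positions")
        if not 0.0 <= self.score <= 100.0:
            raise ValueError("score must lie in [0, 100]")


def score_mit(mismatch_positions: Sequence[int],
              weights: Sequence[float] = MIT_WEIGHTS) -> float:
    """MIT/Hsu specificity score in [0, 100] for a mismatch-position set.

    ``100·Π(1−W[p]) · 1/(((19−d̄)/19)·4+1) · 1/m²`` with mean pairwise
    mismatch distance ``d̄``; the distance and multiplicity terms are 1 for
    fewer than two mismatches, so a perfect match scores 100.
    """
    m = len(mismatch_positions)
    if m == 0:
        return 100.0
    score = 1.0
    for p in mismatch_positions:
        score *= 1.0 - weights[p - 1]
    if m > 1:
        pos = sorted(mismatch_positions)
        pairs = [(b - a) for i, a in enumerate(pos) for b in pos[i + 1:]]
        d_mean = sum(pairs) / len(pairs)
        score *= 1.0 / (((19.0 - d_mean) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (m * m)
    return 100.0 * score


def _scan_strand(contig: str, arr: np.ndarray, query: SpacerQuery,
                 strand: str) -> list[CandidateSite]:
    """Scan one strand; ``arr`` is the uint8 contig, coordinates kept on +."""
    L = len(arr)
    k = PROTOSPACER_LEN
    if L < k:
        return []
    spacer = query.spacer if strand == "+" else revcomp(query.spacer)
    sp = encode(spacer)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    n_is = arr == ord("N")
    n_win = np.lib.stride_tricks.sliding_window_view(n_is, k)
    mm = ((windows != sp) | n_win).sum(axis=1)

    # PAM lies 3' of the protospacer on the matching strand
    pam_pat = query.pam_pattern if strand == "+" else revcomp(query.pam_pattern)
    n_win_starts = windows.shape[0]
    ok = mm <= query.max_mismatches
    if strand == "+":
        valid = np.zeros(n_win_starts, dtype=bool)
        lim = L - k - 3 + 1
        if lim > 0:
            valid[:lim] = True
        pam_ok = np.ones(n_win_starts, dtype=bool)
        for off, ch in enumerate(pam_pat):
            mask = iupac_mask(ch)
            idx = np.arange(n_win_starts) + k + off
            in_range = idx < L
            pam_ok &= np.where(in_range, mask[arr[np.minimum(idx, L - 1)]], False)
        ok &= valid & pam_ok
    else:
        # matching strand runs right-to-left; its PAM occupies arr[i-3:i]
        valid = np.zeros(n_win_starts, dtype=bool)
        valid[3:] = True
        pam_ok = np.ones(n_win_starts, dtype=bool)
        for off, ch in enumerate(pam_pat):
            mask = iupac_mask(ch)
            idx = np.arange(n_win_starts) - 3 + off
            in_range = idx >= 0
            pam_ok &= np.where(in_range, mask[arr[np.maximum(idx, 0)]], False)
        ok &= valid & pam_ok

    sites = []
    sp_q = encode(query.spacer)
    for i in np.nonzero(ok)[0]:
        window = arr[i:i + k].tobytes().decode()
        if strand == "+":
            site_seq = window
            pam = arr[i + k:i + k + 3].tobytes().decode()
        else:
            site_seq = revcomp(window)
            pam = revcomp(arr[i - 3:i].tobytes().decode())
        site_arr = encode(site_seq)
        mism = tuple(int(p) + 1 for p in
                     np.nonzero((site_arr != sp_q) | (site_arr == ord("N")))[0])
        sites.append(CandidateSite(
            contig=contig, start=int(i), strand=strand,
            site_sequence=site_seq, pam=pam,
            mismatch_count=len(mism), mismatch_positions=mism,
            score=score_mit(mism)))
    return sites


def enumerate_candidate_sites(reference: Mapping[str, str] | str,
                              query: SpacerQuery) -> list[CandidateSite]:
    """Every PAM-adjacent ≤``max_mismatches`` site on both strands.

    ``reference`` is a contig-name → sequence mapping or a FASTA path.
    Windows whose PAM would run off the contig are skipped; ``N`` in the
    reference counts as a mismatch.  Output is sorted by (contig, start,
    strand) and contains each site exactly once.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        from Bio import SeqIO
        contigs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(reference), "fasta")}
    else:
        contigs = {k: v.upper() for k, v in reference.items()}
    if not contigs or all(len(v) == 0 for v in contigs.values()):
        raise ValueError("empty reference")

    sites: list[CandidateSite] = []
    for name in sorted(contigs):
        seq = contigs[name]
        validate_dna(seq, what=f"contig {name}")
        arr = encode(seq)
        sites.extend(_scan_strand(name, arr, query, "+"))
        sites.extend(_scan_strand(name, arr, query, "-"))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def rank_and_select(sites: Sequence[CandidateSite], k: int,
                    max_mismatches: int | None = None) -> list[CandidateSite]:
    """Top-``k`` sites: all sub-maximal-mismatch sites plus the best-scoring
    maximal-mismatch sites, ordered by (mismatches, score desc, coordinates).

    Raises
    ------
    ValueError
        If ``k`` cannot accommodate every site with fewer than
        ``max_mismatches`` mismatches.
    """
    if k < 0:
        raise ValueError("k must be ≥ 0")
    if max_mismatches is None:
        max_mismatches = max((s.mismatch_count for s in sites), default=0)
    low = [s for s in sites if s.mismatch_count < max_mismatches]
    high = [s for s in sites if s.mismatch_count == max_mismatches]
    if k < len(low):
        raise ValueError(
            f"k={k} cannot retain all {len(low)} sites below the mismatch maximum")
    coord = lambda s: (s.contig, s.start, s.strand)
    high_sorted = sorted(high, key=lambda s: (-s.score,) + coord(s))
    chosen = low + high_sorted[:k - len(low)]
    chosen.sort(key=lambda s: (s.mismatch_count, -s.score) + coord(s))
    return chosen


def sites_to_frame(sites: Sequence[CandidateSite]) -> pd.DataFrame:
    rows = [{
        "contig": s.contig, "start": s.start, "end": s.start + PROTOSPACER_LEN,
        "strand": s.strand, "site_sequence": s.site_sequence, "pam": s.pam,
        "mismatches": s.mismatch_count,
        "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
        "score": s.score,
    } for s in sites]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                       "site_sequence", "pam", "mismatches",
                                       "mismatch_positions", "score"])


def write_bed6(sites: Sequence[CandidateSite], path) -> None:
    """BED6 export (0-based half-open; score column holds the MIT score)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f"{s.contig}\t{s.start}\t{s.start + PROTOSPACER_LEN}\t"
                     f"site_{i}\t{s.score:.2f}\t{s.strand}\n")
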