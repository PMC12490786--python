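"""Paired-read merging, quality filtering, and primer anchoring.

The processing order is merge → quality filter → primer anchoring:

1. Overlap-merge each read pair (R1 forward, R2 reverse-complemented),
   choosing the overlap that maximises base matches subject to a minimum
   overlap length and a maximum mismatch fraction; within the overlap the
   base with the higher Phred score wins and the consensus quality is the
   maximum of the two.
2. Discard merged reads with more than ``max_low_q_bases`` bases below the
   ``low_q_threshold`` Phred score.
3. Anchor both primers by ungapped (Hamming) matching at the read ends,
   allowing up to ``max_mismatch`` substitutions and no indels, in either
   read orientation; the retained read is trimmed to the inter-primer
   segment and oriented to the reference strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from ._seq import encode, decode, revcomp, revcomp_arr, validate_dna
from .locus import AmpliconLocus


@dataclass
class ReadPair:
    """One raw paired-end read (R1/R2 with Phred quality arrays)."""

    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self) -> None:
        self.qual1 = np.asarray(self.qual1, dtype=np.int16)
        self.qual2 = np.asarray(self.qual2, dtype=np.int16)
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence and quality lengths differ")
        validate_dna(self.seq1, what="seq1")
        validate_dna(self.seq2, what="seq2")


@dataclass
class MergedRead:
    """A merged fragment with consensus qualities."""

    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int


@dataclass
class AnchoredRead:
    """Inter-primer segment of a merged read, reference-oriented."""

    id: str
    seq: str
    qual: np.ndarray
    orientation: str  # '+' if the merged read was already reference-oriented


@dataclass
class FilterReport:
    """Read-accounting over one processing run; ``total`` is conserved."""

    total: int = 0
    merged: int = 0
    failed_merge: int = 0
    failed_quality: int = 0
    failed_primer: int = 0
    retained: int = 0

    def validate(self) -> None:
        if self.total != (self.retained + self.failed_merge
                          + self.failed_quality + self.failed_primer):
            raise ValueError("filter report does not conserve reads")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("total", "merged", "failed_merge", "failed_quality",
                 "failed_primer", "retained")}


class AmbiguousOrientationError(ValueError):
    """Both read orientations matched the primer pair (malformed amplicon)."""


def merge_read_pair(pair: ReadPair, min_overlap: int = 10,
                    max_overlap_mismatch_frac: float = 0.25) -> Optional[MergedRead]:
    """Merge R1 with reverse-complemented R2 on their best overlap.

    Among overlap lengths ``o`` with ``min_overlap ≤ o ≤ min(len1, len2)``
    whose mismatch fraction is ≤ ``max_overlap_mismatch_frac``, the one with
    the most matching bases is chosen (ties toward the longer overlap).
    Returns ``None`` when no acceptable overlap exists.
    """
    a1 = encode(pair.seq1)
    a2 = revcomp_arr(encode(pair.seq2))
    q1 = pair.qual1
    q2 = pair.qual2[::-1]
    l1, l2 = len(a1), len(a2)

    best: Optional[tuple[int, int]] = None  # (matches, overlap)
    for o in range(min_overlap, min(l1, l2) + 1):
        matches = int((a1[l1 - o:] == a2[:o]).sum())
        if (o - matches) / o > max_overlap_mismatch_frac:
            continue
        if best is None or matches >= best[0]:
            best = (matches, o)
    if best is None:
        return None

    _, o = best
    left_seq, left_q = a1[:l1 - o], q1[:l1 - o]
    ov1, ovq1 = a1[l1 - o:], q1[l1 - o:]
    ov2, ovq2 = a2[:o], q2[:o]
    take2 = ovq2 > ovq1  # higher Phred wins; ties toward R1
    cons = np.where(take2, ov2, ov1)
    consq = np.maximum(ovq1, ovq2)
    right_seq, right_q = a2[o:], q2[o:]

    seq = decode(np.concatenate([left_seq, cons, right_seq]))
    qual = np.concatenate([left_q, consq, right_q])
    return MergedRead(pair.id, seq, qual, o)


def filter_by_quality(read: MergedRead, low_q_threshold: int = 20,
                      max_low_q_bases: int = 2) -> bool:
    """True (pass) unless *more than* ``max_low_q_bases`` bases are low quality."""
    return int((read.qual < low_q_threshold).sum()) <= max_low_q_bases


def _ends_match(arr: np.ndarray, fwd: np.ndarray, rev_rc: np.ndarray,
                max_mismatch: int) -> bool:
    lf, lr = len(fwd), len(rev_rc)
    if len(arr) < lf + lr:
        return False
    return (int((arr[:lf] != fwd).sum()) <= max_mismatch
            and int((arr[-lr:] != rev_rc).sum()) <= max_mismatch)


def anchor_primers(read: MergedRead, fwd_primer: str, rev_primer: str,
                   max_mismatch: int = 2) -> Optional[AnchoredRead]:
    """Anchor the primer pair at the read ends and trim to the interior.

    The forward primer must match (ungapped, ≤ ``max_mismatch``
    substitutions) at the 5' end and the reverse complement of the reverse
    primer at the 3' end, in exactly one of the two read orientations.

    Raises
    ------
    AmbiguousOrientationError
        If both orientations match the primer pair.
    """
    fwd = encode(fwd_primer)
    rev_rc = encode(revcomp(rev_primer))
    arr = encode(read.seq)
    rc = revcomp_arr(arr)

    plus = _ends_match(arr, fwd, rev_rc, max_mismatch)
    minus = _ends_match(rc, fwd, rev_rc, max_mismatch)
    if plus and minus:
        raise AmbiguousOrientationError(
            f"read {read.id}: primers match in both orientations")
    if not plus and not minus:
        return None
    lf, lr = len(fwd), len(rev_rc)
    if plus:
        seq = read.seq[lf:len(read.seq) - lr]
        qual = read.qual[lf:len(read.qual) - lr]
        orient = "+"
    else:
        seq = decode(rc[lf:len(rc) - lr])
        qual = read.qual[::-1][lf:len(read.qual) - lr]
        orient = "-"
    return AnchoredRead(read.id, seq, qual, orient)


def process_read_pairs(
        pairs: Iterable[ReadPair], locus: AmpliconLocus, *,
        min_overlap: int = 10, max_overlap_mismatch_frac: float = 0.25,
        low_q_threshold: int = 20, max_low_q_bases: int = 2,
        max_primer_mismatch: int = 2,
        premerged: bool = False) -> tuple[list[AnchoredRead], FilterReport]:
    """Run merge → quality filter → primer anchoring over a read stream.

    With ``premerged=True`` the ``seq1``/``qual1`` of each pair is taken as an
    already-merged read and the merge step is skipped.
    """
    report = FilterReport()
    retained: list[AnchoredRead] = []
    for pair in pairs:
        report.total += 1
        if premerged:
            merged = MergedRead(pair.id, pair.seq1, pair.qual1, 0)
        else:
            merged = merge_read_pair(pair, min_overlap, max_overlap_mismatch_frac)
            if merged is None:
                report.failed_merge += 1
                continue
        report.merged += 1
        if not filter_by_quality(merged, low_q_threshold, max_low_q_bases):
            report.failed_quality += 1
            continue
        try:
            anchored = anchor_primers(merged, locus.fwd_primer,
                                      locus.rev_primer, max_primer_mismatch)
        except AmbiguousOrientationError:
            anchored = None
        if anchored is None:
            report.failed_primer += 1
            continue
        report.retained += 1
        retained.append(anchored)
    report.validate()
    return retained, report


# -- FASTQ IO ---------------------------------------------------------------

def iter_fastq(path) -> Iterator[tuple[str, str, np.ndarray]]:
    """Yield (id, seq, phred array) records from a (optionally gzipped) FASTQ."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            phred = np.array(rec.get_quality_array(), dtype=np.int16)
            yield rec.name, rec.sequence.upper(), phred


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate matched R1/R2 FASTQ files as :class:`ReadPair` objects."""
    for (id1, s1, q1), (id2, s2, q2) in zip(iter_fastq(r1_path),
                                            iter_fastq(r2_path), strict=True):
        yield ReadPair(id1, s1, q1, s2, q2)
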