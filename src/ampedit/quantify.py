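"""Read classification and editing-outcome quantification.

Anchored reads are aligned to the inter-primer amplicon reference and each
read is placed in exactly one class:

* ``INDEL`` — the alignment contains a gap overlapping the protospacer
  ± ``indel_flank`` bp,
* ``EDIT`` — otherwise, if any named adenine of the protospacer carries an
  A→G substitution (the set of edited adenines is recorded),
* ``WT`` — no substitution at any protospacer position,
* ``SUBST_OTHER`` — protospacer substitutions that are not named-adenine
  A→G events (sequencing errors, cytosine deamination).

The classes partition the retained reads.  Per-position base counts exclude
indel-bearing reads (gapped columns have no well-defined positional base);
indel frequencies are computed over *all* retained reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, BASE_INDEX, complement, encode
from .align import Alignment, align_global
from .locus import PROTOSPACER_LEN, AmpliconLocus
from .reads import AnchoredRead


class EmptyTableError(ValueError):
    """Raised when a frequency table would be built from zero reads."""


@dataclass(frozen=True)
class IndelEvent:
    """One distinct indel allele, protospacer-relative.

    ``span`` is a 1-based inclusive interval in protospacer coordinates
    (positions ≤ 0 are 5' of the protospacer on the protospacer strand,
    > 20 are 3' of it).  For insertions the span is the single position the
    insertion follows.  ``duplication`` means the inserted sequence equals
    the adjacent reference k-mer (a tandem duplication).
    """

    type: str               # 'insertion' | 'deletion' | 'duplication'
    size: int
    span: tuple[int, int]
    sequence: str           # inserted or deleted bases (protospacer strand)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("indel size must be ≥ 1")


@dataclass(frozen=True)
class IndelRecord:
    """An :class:`IndelEvent` with its read count and frequency."""

    event: IndelEvent
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class ReadClass:
    """Mutually exclusive outcome class for one read."""

    kind: str                          # 'WT' | 'EDIT' | 'SUBST_OTHER' | 'INDEL'
    edited: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "EDIT" and not self.edited:
            raise ValueError("EDIT class requires a nonempty edited set")
        if self.kind != "EDIT" and self.edited:
            raise ValueError("only EDIT reads carry an edited set")

    @property
    def label(self) -> str:
        if self.kind != "EDIT":
            return self.kind
        return "+".join(sorted(self.edited, key=lambda l: int(l[1:])))


@dataclass
class ClassifiedRead:
    """Classification plus positional detail for one (unique) read sequence."""

    read_class: ReadClass
    proto_bases: Optional[str]          # 20-mer on protospacer strand; None for INDEL
    indels: tuple[IndelEvent, ...] = ()


@dataclass
class PositionFrequencyTable:
    """Per-protospacer-position base counts for one sample.

    ``counts`` is a (20, 4) integer array over bases A/C/G/T on the
    protospacer strand; coverage at a position is the row sum.
    """

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (PROTOSPACER_LEN, 4):
            raise ValueError("counts must be (20, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov[:, None] > 0, self.counts / cov[:, None], 0.0)

    def base_frequency(self, proto_pos: int, base: str) -> float:
        return float(self.frequencies[proto_pos - 1, BASE_INDEX[base]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, PROTOSPACER_LEN + 1))
        df["coverage"] = self.coverage
        for b in BASES:
            df[f"freq_{b}"] = self.frequencies[:, BASE_INDEX[b]]
        df.insert(0, "sample", self.sample_id)
        return df


# ---------------------------------------------------------------------------
# per-read classification

def classify_alignment(aln: Alignment, locus: AmpliconLocus, *,
                       indel_flank: int = 10) -> ClassifiedRead:
    """Classify one read from its global alignment to the interior reference."""
    lo, hi = locus.proto_interior_span
    win_lo, win_hi = lo - indel_flank, hi + indel_flank

    ref_pos = 0                      # interior reference index (0-based)
    proto = list(locus.interior[lo:hi])
    indels: list[IndelEvent] = []
    gap_in_window = False
    i = 0
    aq, ar = aln.aligned_query, aln.aligned_ref
    n = len(aq)
    interior = locus.interior
    while i < n:
        if ar[i] == "-":             # insertion relative to the reference
            j = i
            while j < n and ar[j] == "-":
                j += 1
            ins = aq[i:j]
            if win_lo <= ref_pos <= win_hi:
                gap_in_window = True
                indels.append(_insertion_event(ins, ref_pos, locus))
            i = j
            continue
        if aq[i] == "-":             # deletion relative to the reference
            j = i
            while j < n and aq[j] == "-":
                j += 1
            start, end = ref_pos, ref_pos + (j - i)   # half-open, interior
            if start < win_hi and end > win_lo:
                gap_in_window = True
                indels.append(_deletion_event(start, end, locus))
            ref_pos = end
            i = j
            continue
        if lo <= ref_pos < hi:
            proto[ref_pos - lo] = aq[i]
        ref_pos += 1
        i += 1

    if gap_in_window:
        return ClassifiedRead(ReadClass("INDEL"), None, tuple(indels))

    proto_ref = interior[lo:hi]
    bases = "".join(proto)
    if locus.strand == "-":
        bases_proto = complement(bases)[::-1]
    else:
        bases_proto = bases
    return ClassifiedRead(_substitution_class(bases_proto, locus), bases_proto)


def _substitution_class(proto_bases: str, locus: AmpliconLocus) -> ReadClass:
    """EDIT/WT/SUBST_OTHER from the read's protospacer-strand 20-mer."""
    edited = frozenset(
        label for label in locus.named_positions
        if label.startswith("A")
        and proto_bases[locus.named_positions[label] - 1] == "G")
    if edited:
        return ReadClass("EDIT", edited)
    if proto_bases == locus.protospacer:
        return ReadClass("WT")
    return ReadClass("SUBST_OTHER")


def _proto_span(locus: AmpliconLocus, interior_start: int,
                interior_end: int) -> tuple[int, int]:
    """Protospacer-relative 1-based inclusive span of an interior interval."""
    a = locus.proto_relative(interior_start)
    b = locus.proto_relative(interior_end - 1)
    return (a, b) if a <= b else (b, a)


def _orient(seq: str, locus: AmpliconLocus) -> str:
    if locus.strand == "-":
        return complement(seq)[::-1]
    return seq


def _insertion_event(ins: str, ref_pos: int, locus: AmpliconLocus) -> IndelEvent:
    """Insertion of ``ins`` before interior index ``ref_pos``.

    A tandem duplication is recognised when the inserted sequence equals the
    reference k-mer immediately on either side of the insertion point (gap
    placement under deterministic tie-breaking may sit on either side).
    """
    k = len(ins)
    interior = locus.interior
    left = interior[max(0, ref_pos - k):ref_pos]
    right = interior[ref_pos:ref_pos + k]
    kind = "duplication" if (ins == left or ins == right) else "insertion"
    # span = protospacer-relative position of the base immediately 5' of the
    # insertion on the protospacer strand
    p = locus.proto_relative(ref_pos - 1 if locus.strand == "+" else ref_pos)
    return IndelEvent(kind, k, (p, p), _orient(ins, locus))


def _deletion_event(start: int, end: int, locus: AmpliconLocus) -> IndelEvent:
    deleted = locus.interior[start:end]
    return IndelEvent("deletion", end - start, _proto_span(locus, start, end),
                      _orient(deleted, locus))


# ---------------------------------------------------------------------------
# sample-level quantification

_GAPPED_BOUND_MISMATCHES = 2  # ungapped optimal when Hamming ≤ 2 (9·2 < 2·gap_open − 2·gap_extend·0 − 5)


def classify_sequence(seq: str, locus: AmpliconLocus, *,
                      indel_flank: int = 10,
                      align_kwargs: Optional[dict] = None) -> ClassifiedRead:
    """Classify one anchored read sequence against the interior reference.

    Uses exact fast paths (reference-identical reads; equal-length reads
    within Hamming distance 2, where the ungapped alignment is provably
    optimal under the default scoring) and falls back to the full affine
    Needleman-Wunsch alignment otherwise.
    """
    interior = locus.interior
    if seq == interior:
        bases = locus.protospacer
        return ClassifiedRead(ReadClass("WT"), bases)
    if len(seq) == len(interior) and align_kwargs is None:
        d = int((encode(seq) != encode(interior)).sum())
        if d <= _GAPPED_BOUND_MISMATCHES:
            lo, hi = locus.proto_interior_span
            bases = _orient(seq[lo:hi], locus)
            return ClassifiedRead(_substitution_class(bases, locus), bases)
    aln = align_global(seq, interior, **(align_kwargs or {}))
    return classify_alignment(aln, locus, indel_flank=indel_flank)


@dataclass
class SampleQuant:
    """All per-sample editing summaries."""

    sample_id: str
    n_retained: int
    class_counts: Counter                # ReadClass.label -> reads
    position_table: PositionFrequencyTable
    indel_records: list[IndelRecord]
    n_indel_reads: int

    @property
    def cumulative_indel_frequency(self) -> float:
        return float(sum(r.frequency for r in self.indel_records))


def quantify_reads(reads: Iterable[AnchoredRead | str], locus: AmpliconLocus,
                   sample_id: str = "sample", *, indel_flank: int = 10,
                   align_kwargs: Optional[dict] = None) -> SampleQuant:
    """Align, classify and tabulate a sample's anchored reads.

    Identical sequences are classified once and weighted by multiplicity.
    """
    seq_counts = Counter(
        r.seq if isinstance(r, AnchoredRead) else r for r in reads)
    n_retained = sum(seq_counts.values())
    if n_retained == 0:
        raise EmptyTableError("no retained reads to quantify")

    class_counts: Counter = Counter()
    pos_counts = np.zeros((PROTOSPACER_LEN, 4), dtype=np.int64)
    indel_counter: Counter = Counter()
    n_indel_reads = 0

    base_row = {b: i for i, b in enumerate(BASES)}
    for seq, mult in seq_counts.items():
        cr = classify_sequence(seq, locus, indel_flank=indel_flank,
                               align_kwargs=align_kwargs)
        class_counts[cr.read_class.label] += mult
        if cr.read_class.kind == "INDEL":
            n_indel_reads += mult
            for ev in cr.indels:
                indel_counter[ev] += mult
            continue
        for p, b in enumerate(cr.proto_bases):
            if b in base_row:
                pos_counts[p, base_row[b]] += mult

    table = PositionFrequencyTable(sample_id, pos_counts)
    records = [IndelRecord(ev, c, c / n_retained)
               for ev, c in sorted(indel_counter.items(),
                                   key=lambda kv: (kv[0].span, kv[0].type,
                                                   kv[0].sequence))]
    return SampleQuant(sample_id, n_retained, class_counts, table,
                       records, n_indel_reads)


# ---------------------------------------------------------------------------
# tabulations mirroring the reported summaries

def tabulate_positions(quant: SampleQuant) -> pd.DataFrame:
    """Long-format per-position base counts/frequencies (indel reads excluded)."""
    return quant.position_table.to_frame()


def tabulate_combinations(quant: SampleQuant) -> pd.DataFrame:
    """Fraction of retained reads per editing-outcome combination.

    Rows cover each observed set of co-edited named adenines (e.g. ``A9``,
    ``A9+A12``) plus ``WT``, ``SUBST_OTHER`` and ``INDEL``; fractions sum
    to 1 over the retained reads.
    """
    rows = []
    for label, count in quant.class_counts.items():
        rows.append({"combination": label, "reads": count,
                     "fraction": count / quant.n_retained})
    df = pd.DataFrame(rows, columns=["combination", "reads", "fraction"])
    special = {"WT": 0, "SUBST_OTHER": 1, "INDEL": 2}
    df["_ord"] = df["combination"].map(lambda c: (1, special.get(c, 0), c)
                                       if c in special else (0, 0, c))
    df = df.sort_values("_ord").drop(columns="_ord").reset_index(drop=True)
    return df


def catalog_indels(quant: SampleQuant) -> pd.DataFrame:
    """Indel catalog: one row per distinct (type, span, sequence) allele."""
    rows = []
    for rec in quant.indel_records:
        ev = rec.event
        rows.append({
            "type": ev.type, "size": ev.size,
            "span_start": ev.span[0], "span_end": ev.span[1],
            "sequence": ev.sequence, "reads": rec.count,
            "frequency": rec.frequency,
        })
    return pd.DataFrame(rows, columns=["type", "size", "span_start",
                                       "span_end", "sequence", "reads",
                                       "frequency"])


def quantify_cytosine_deamination(table: PositionFrequencyTable,
                                  locus: AmpliconLocus) -> pd.DataFrame:
    """C>T / C>G / C>A frequencies at the named cytosine positions."""
    rows = []
    for label in locus.cytosine_labels:
        pos = locus.named_positions[label]
        if locus.proto_base(pos) != "C":
            raise ValueError(f"named position {label} is not a reference C")
        rows.append({
            "position": label,
            "C>T": table.base_frequency(pos, "T"),
            "C>G": table.base_frequency(pos, "G"),
            "C>A": table.base_frequency(pos, "A"),
        })
    return pd.DataFrame(rows, columns=["position", "C>T", "C>G", "C>A"])


def flag_above_background(post: PositionFrequencyTable,
                          controls: Sequence[PositionFrequencyTable],
                          locus: AmpliconLocus) -> pd.DataFrame:
    """Flag non-reference base frequencies above the control background.

    With two or more control (pre-treatment) samples a position/substitution
    is flagged when its frequency exceeds ``mean + 2·SD`` of the controls;
    with a single control, when it exceeds twice the control value.
    """
    if not controls:
        raise ValueError("at least one control table is required")
    ctrl = np.stack([c.frequencies for c in controls])   # (k, 20, 4)
    if len(controls) >= 2:
        thresh = ctrl.mean(axis=0) + 2 * ctrl.std(axis=0, ddof=1)
    else:
        thresh = 2 * ctrl[0]
    freqs = post.frequencies
    rows = []
    for p in range(1, PROTOSPACER_LEN + 1):
        ref_base = locus.proto_base(p)
        for b in BASES:
            if b == ref_base:
                continue
            f = freqs[p - 1, BASE_INDEX[b]]
            t = thresh[p - 1, BASE_INDEX[b]]
            rows.append({"position": p, "ref": ref_base, "alt": b,
                         "frequency": f, "threshold": t,
                         "flagged": bool(f > t)})
    return pd.DataFrame(rows)


def summarize_timecourse(samples: Sequence[tuple[str, PositionFrequencyTable]],
                         locus: AmpliconLocus) -> pd.DataFrame:
    """Editing frequency per named position per timepoint (long format).

    For adenine labels the reported value is the A→G frequency; for cytosine
    labels it is the total non-reference frequency at the position.
    """
    labels = [lab for lab, _ in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate timepoint labels")
    rows = []
    for tp, table in samples:
        for label, pos in sorted(locus.named_positions.items(),
                                 key=lambda kv: kv[1]):
            if label.startswith("A"):
                val = table.base_frequency(pos, "G")
            else:
                val = 1.0 - table.base_frequency(pos, locus.proto_base(pos))
            rows.append({"timepoint": tp, "position": label,
                         "edited_frequency": val})
    return pd.DataFrame(rows, columns=["timepoint", "position",
                                       "edited_frequency"])
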