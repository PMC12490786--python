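"""Clonal genotyping from Sanger-style base-proportion traces.

Chromatogram deconvolution is out of scope: the input is a per-position
table of A/C/G/T signal proportions (each row summing to 1) covering the
amplicon, as produced by trace-quantification tools.  From the
edited-signal fraction at a named adenine the colony genotype is called
against symmetric bands around the diploid expectations 0 / 0.5 / 1:
below ``lo`` → unedited, between → monoallelic, above ``hi`` → biallelic.
A separate degradation flag marks traces whose signal becomes mixed from
within the protospacer onward, the Sanger signature of an indel allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, BASE_INDEX, complement
from .locus import PROTOSPACER_LEN, AmpliconLocus

INDETERMINATE = "indeterminate"


@dataclass
class TraceProportions:
    """Per-position base-signal proportions for one colony trace."""

    colony_id: str
    proportions: np.ndarray        # (len(reference), 4) over A/C/G/T
    locus: AmpliconLocus

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.locus.reference), 4):
            raise ValueError("proportions must be (reference length, 4)")
        if (self.proportions < -1e-9).any() or (self.proportions > 1 + 1e-9).any():
            raise ValueError("proportions must lie in [0, 1]")
        if np.abs(self.proportions.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("each row must sum to 1")


@dataclass
class ColonyGenotype:
    """Genotype calls for one colony."""

    colony_id: str
    calls: dict                    # adenine label -> call string
    edited_fraction_a9: Optional[float]
    indel_flag: bool


def read_trace_csv(path, locus: AmpliconLocus) -> TraceProportions:
    """Read one trace table (columns: position, A, C, G, T; 1-based positions)."""
    df = pd.read_csv(path)
    df = df.sort_values("position")
    expected = np.arange(1, len(locus.reference) + 1)
    if not np.array_equal(df["position"].to_numpy(), expected):
        raise ValueError("trace must cover every amplicon position exactly once")
    mat = df[list(BASES)].to_numpy(dtype=float)
    import os
    colony_id = os.path.splitext(os.path.basename(str(path)))[0]
    return TraceProportions(colony_id, mat, locus)


def estimate_site_fraction(trace: TraceProportions, label: str) -> Optional[float]:
    """Edited-signal fraction G/(A+G) at a named adenine, protospacer strand.

    Returns ``None`` (indeterminate) when the combined A+G signal carries
    less than half of the total at the position — the signature of an indel
    or badly mixed trace.
    """
    locus = trace.locus
    pos = locus.named_positions[label]
    if locus.proto_base(pos) != "A":
        raise ValueError(f"named position {label} is not a reference adenine")
    idx = locus.ref_index(pos)
    row = trace.proportions[idx]
    a_base = "A" if locus.strand == "+" else complement("A")
    g_base = "G" if locus.strand == "+" else complement("G")
    a_sig = row[BASE_INDEX[a_base]]
    g_sig = row[BASE_INDEX[g_base]]
    if a_sig + g_sig < 0.5 * row.sum():
        return None
    if a_sig + g_sig == 0:
        return None
    return float(g_sig / (a_sig + g_sig))


def _band_call(fraction: Optional[float], lo: float, hi: float) -> str:
    if fraction is None:
        return INDETERMINATE
    if fraction < lo:
        return "unedited"
    if fraction > hi:
        return "biallelic"
    return "monoallelic"


def call_colony_genotype(trace: TraceProportions, lo: float = 0.2,
                         hi: float = 0.8) -> ColonyGenotype:
    """Call the colony genotype at every named adenine.

    The call bands are ``fraction < lo`` → unedited, ``lo ≤ fraction ≤ hi``
    → monoallelic, ``fraction > hi`` → biallelic; an indeterminate
    edited-signal fraction propagates to an indeterminate call.
    """
    locus = trace.locus
    calls = {}
    frac_a9: Optional[float] = None
    for label in locus.adenine_labels:
        frac = estimate_site_fraction(trace, label)
        calls[label] = _band_call(frac, lo, hi)
        if label == "A9":
            frac_a9 = frac
    return ColonyGenotype(trace.colony_id, calls, frac_a9,
                          flag_trace_indel(trace))


def flag_trace_indel(trace: TraceProportions, purity_threshold: float = 0.7,
                     run_length: int = 5) -> bool:
    """Flag a trace whose signal degrades within the protospacer.

    True when, starting at or after the protospacer start (reference
    orientation), at least ``run_length`` consecutive positions have their
    strongest base below ``purity_threshold`` of the total signal.
    """
    locus = trace.locus
    start = min(locus.ref_index(1), locus.ref_index(PROTOSPACER_LEN))
    purity = trace.proportions.max(axis=1) / trace.proportions.sum(axis=1)
    impure = purity[start:] < purity_threshold
    run = 0
    for flag in impure:
        run = run + 1 if flag else 0
        if run >= run_length:
            return True
    return False


def genotype_colonies(traces: Sequence[TraceProportions], lo: float = 0.2,
                      hi: float = 0.8) -> pd.DataFrame:
    """Genotype a set of colonies; one row per colony."""
    rows = []
    for trace in traces:
        g = call_colony_genotype(trace, lo, hi)
        row = {"colony": g.colony_id,
               "edited_fraction_a9": g.edited_fraction_a9,
               "indel_flag": g.indel_flag}
        row.update({f"call_{k}": v for k, v in sorted(g.calls.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_genotypes(genotypes: pd.DataFrame, label: str = "A9") -> dict:
    """Fractions of unedited/monoallelic/biallelic (and indeterminate) calls."""
    col = genotypes[f"call_{label}"]
    n = len(genotypes)
    return {cls: float((col == cls).sum()) / n
            for cls in ("unedited", "monoallelic", "biallelic", INDETERMINATE)}
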