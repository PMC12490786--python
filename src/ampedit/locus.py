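"""Amplicon locus model.

An :class:`AmpliconLocus` ties together the wild-type amplicon sequence, the
placement and strand of the 20-nt protospacer within it, the PAM, the PCR
primers that delimit the amplicon, and the named protospacer positions that
all editing quantification is reported against (the target/bystander
adenines A9/A12/A16/A18 and the deamination-prone cytosines C3/C5/C6/C8).

Protospacer positions are 1-based, 5'→3' on the protospacer strand, so for a
locus defined on the minus strand position 1 is the *last* base of the
reference-strand match and bases are complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from ._seq import complement, revcomp, validate_dna

PROTOSPACER_LEN = 20

#: Makassar-surrogate HBB protospacer targeted by ABE8e-NRCH
HBB_PROTOSPACER = "TTCTCCTCAGGAGTCAGATG"

#: Default named positions: edited/bystander adenines and flanking cytosines
DEFAULT_NAMED_POSITIONS: Mapping[str, int] = {
    "A9": 9, "A12": 12, "A16": 16, "A18": 18,
    "C3": 3, "C5": 5, "C6": 6, "C8": 8,
}


@dataclass(frozen=True)
class AmpliconLocus:
    """Reference amplicon with protospacer placement and named positions.

    Parameters
    ----------
    name:
        Locus label used in reports.
    reference:
        Wild-type amplicon sequence, 5'→3' on the reference (plus) strand,
        beginning with the forward primer and ending with the reverse
        complement of the reverse primer.
    protospacer_start:
        1-based inclusive offset of the 20-mer protospacer match within
        ``reference`` (of its reverse complement when ``strand == '-'``).
    protospacer:
        The 20-nt protospacer on its own strand.
    strand:
        '+' if the protospacer reads off the reference strand, '-' otherwise.
    pam:
        3-nt PAM immediately 3' of the protospacer (protospacer strand).
    fwd_primer, rev_primer:
        PCR primers; ``fwd_primer`` is a prefix of ``reference`` and
        ``rev_primer`` is the reverse complement of its suffix.
    named_positions:
        Map of position label → protospacer position (1–20).
    """

    name: str
    reference: str
    protospacer_start: int
    protospacer: str = HBB_PROTOSPACER
    strand: str = "+"
    pam: str = "AGG"
    fwd_primer: str = ""
    rev_primer: str = ""
    named_positions: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NAMED_POSITIONS))

    def __post_init__(self) -> None:
        validate_dna(self.reference, what="reference")
        validate_dna(self.protospacer, allow_n=False, what="protospacer")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        s = self.protospacer_start - 1
        if s < 0 or s + PROTOSPACER_LEN > len(self.reference):
            raise ValueError("protospacer does not fit inside the reference")
        window = self.reference[s:s + PROTOSPACER_LEN]
        expect = self.protospacer if self.strand == "+" else revcomp(self.protospacer)
        if window != expect:
            raise ValueError(
                f"reference window {window!r} does not match protospacer "
                f"on strand {self.strand!r}")
        for label, pos in self.named_positions.items():
            if not 1 <= pos <= PROTOSPACER_LEN:
                raise ValueError(f"named position {label} out of range: {pos}")
            if label[0] in "ACGT" and self.protospacer[pos - 1] != label[0]:
                raise ValueError(
                    f"named position {label} is {self.protospacer[pos - 1]} "
                    "in the protospacer")
        if self.fwd_primer and not self.reference.startswith(self.fwd_primer):
            raise ValueError("fwd_primer is not a prefix of the reference")
        if self.rev_primer and not self.reference.endswith(revcomp(self.rev_primer)):
            raise ValueError("rev_primer does not match the reference 3' end")
        if self.fwd_primer and self.rev_primer:
            f, r = len(self.fwd_primer), len(self.rev_primer)
            if not (f <= s and s + PROTOSPACER_LEN <= len(self.reference) - r):
                raise ValueError("protospacer must lie strictly between primers")

    # -- coordinate helpers -------------------------------------------------

    def ref_index(self, proto_pos: int) -> int:
        """0-based reference index of protospacer position ``proto_pos``."""
        s = self.protospacer_start - 1
        if self.strand == "+":
            return s + proto_pos - 1
        return s + PROTOSPACER_LEN - proto_pos

    def proto_base(self, proto_pos: int) -> str:
        """Reference base at a protospacer position, on the protospacer strand."""
        return self.protospacer[proto_pos - 1]

    def to_proto_strand(self, base: str) -> str:
        """Map a reference-strand base to the protospacer strand."""
        return base if self.strand == "+" else complement(base)

    @property
    def interior(self) -> str:
        """Amplicon sequence between (excluding) the primers."""
        f = len(self.fwd_primer)
        r = len(self.rev_primer)
        return self.reference[f:len(self.reference) - r] if (f or r) else self.reference

    def interior_index(self, proto_pos: int) -> int:
        """0-based index of a protospacer position within :attr:`interior`."""
        return self.ref_index(proto_pos) - len(self.fwd_primer)

    @property
    def proto_interior_span(self) -> tuple[int, int]:
        """0-based half-open protospacer span within the interior sequence."""
        s = self.protospacer_start - 1 - len(self.fwd_primer)
        return s, s + PROTOSPACER_LEN

    def proto_relative(self, interior_index: int) -> int:
        """Protospacer-relative 1-based position of an interior index.

        Positions inside the protospacer fall in 1..20; positions 5' of it
        (on the protospacer strand) are ≤ 0 and positions 3' are > 20.
        """
        lo, _hi = self.proto_interior_span
        if self.strand == "+":
            return interior_index - lo + 1
        return lo + PROTOSPACER_LEN - interior_index

    @property
    def adenine_labels(self) -> list[str]:
        return sorted((l for l in self.named_positions if l.startswith("A")),
                      key=lambda l: self.named_positions[l])

    @property
    def cytosine_labels(self) -> list[str]:
        return sorted((l for l in self.named_positions if l.startswith("C")),
                      key=lambda l: self.named_positions[l])

    def reverse_complemented(self) -> "AmpliconLocus":
        """The same locus described on the opposite reference strand."""
        n = len(self.reference)
        s = self.protospacer_start - 1
        return AmpliconLocus(
            name=self.name,
            reference=revcomp(self.reference),
            protospacer_start=n - (s + PROTOSPACER_LEN) + 1,
            protospacer=self.protospacer,
            strand="-" if self.strand == "+" else "+",
            pam=self.pam,
            fwd_primer=self.rev_primer,
            rev_primer=self.fwd_primer,
            named_positions=dict(self.named_positions),
        )


def hbb_demo_locus(flank_seed: int = 20250927) -> AmpliconLocus:
    """Synthetic HBB-like demonstration amplicon.

    Carries the real Makassar-surrogate protospacer with an NRCH-compatible
    PAM inside deterministic pseudo-random flanking sequence (synthetic — the
    true genomic flanks are not bundled); 170 bp total with 20-bp primers.
    """
    rng = np.random.default_rng(flank_seed)

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    fwd = rand_seq(20)
    pad1 = rand_seq(30)
    pad2 = rand_seq(57)
    rev_rc = rand_seq(20)  # reference-strand suffix
    reference = fwd + pad1 + HBB_PROTOSPACER + "AGG" + pad2 + rev_rc
    return AmpliconLocus(
        name="HBB_demo",
        reference=reference,
        protospacer_start=len(fwd) + len(pad1) + 1,
        protospacer=HBB_PROTOSPACER,
        strand="+",
        pam="AGG",
        fwd_primer=fwd,
        rev_primer=revcomp(rev_rc),
    )


def load_locus_yaml(path) -> AmpliconLocus:
    """Load a locus definition from YAML.

    Keys: ``name``, ``reference`` (inline) or ``reference_fasta`` (path; first
    record), ``protospacer_start``, ``protospacer``, ``strand``, ``pam``,
    ``fwd_primer``, ``rev_primer``, optional ``named_positions``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "reference" not in cfg:
        from Bio import SeqIO
        rec = next(SeqIO.parse(cfg["reference_fasta"], "fasta"))
        cfg["reference"] = str(rec.seq).upper()
    cfg.pop("reference_fasta", None)
    cfg.setdefault("named_positions", dict(DEFAULT_NAMED_POSITIONS))
    return AmpliconLocus(**cfg)


def dump_locus_yaml(locus: AmpliconLocus, path) -> None:
    data = {
        "name": locus.name,
        "reference": locus.reference,
        "protospacer_start": locus.protospacer_start,
        "protospacer": locus.protospacer,
        "strand": locus.strand,
        "pam": locus.pam,
        "fwd_primer": locus.fwd_primer,
        "rev_primer": locus.rev_primer,
        "named_positions": dict(locus.named_positions),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
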