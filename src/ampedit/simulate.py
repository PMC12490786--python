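"""Synthetic sequencing data with the generative structure the analysis assumes.

Three generators back the test surface of the package:

* :func:`simulate_amplicon_reads` — paired (or pre-merged) amplicon reads
  from a clonal allele model: per-adenine A→G editing with A12 linked to A9
  (``P(A12) = P(A9)·cond + (1−P(A9))·marginal``), rare cytosine deamination,
  whole-allele indels (e.g. 7–8 bp tandem duplications inside the
  protospacer), uniform per-base substitution error, and an independent
  low-quality-base process that exercises the quality filter.
* :func:`simulate_colonies` — Sanger-style base-proportion traces for clonal
  colonies drawn from an unedited/monoallelic/biallelic mix.
* :func:`simulate_panel` — multi-site longitudinal panel count tables with
  sequencing error, germline SNPs, and injected true edits appearing at a
  chosen post-treatment timepoint.

All generators are deterministic given their seed; read output is
byte-identical across runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import BASES, revcomp
from .locus import PROTOSPACER_LEN, AmpliconLocus, hbb_demo_locus
from .reads import ReadPair
from .sanger import TraceProportions
from .panel import PanelDataset, PanelSample, PanelSiteDef

_B2I = {b: i for i, b in enumerate(BASES)}
_I2A = np.frombuffer("ACGT".encode(), dtype=np.uint8)

PHRED_GOOD = 37
PHRED_LOW = 2


def _enc4(seq: str) -> np.ndarray:
    """Encode ACGT string to 0..3 codes."""
    return np.array([_B2I[c] for c in seq], dtype=np.int8)


def _dec4_rows(mat: np.ndarray) -> list[str]:
    ascii_mat = _I2A[mat]
    return [row.tobytes().decode("ascii") for row in ascii_mat]


@dataclass(frozen=True)
class IndelSpec:
    """A whole-allele indel to inject.

    ``kind`` is ``duplication`` (tandem copy of the reference segment at
    protospacer ``span`` inserted immediately 3' of it), ``deletion`` (the
    ``span`` is removed), or ``insertion`` (``sequence`` inserted after
    ``span[0]``).  Spans are 1-based inclusive protospacer positions.
    """

    kind: str
    span: tuple[int, int]
    frequency: float
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "deletion", "insertion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("indel frequency must be in [0, 1]")
        if self.kind == "insertion" and not self.sequence:
            raise ValueError("insertion spec requires a sequence")

    @property
    def size(self) -> int:
        if self.kind == "insertion":
            return len(self.sequence)
        return self.span[1] - self.span[0] + 1


@dataclass
class SimConfig:
    """Generative parameters for one amplicon sequencing sample."""

    locus: AmpliconLocus = field(default_factory=hbb_demo_locus)
    edit_rate_a9: float = 0.6
    conditional_rate_a12_given_a9: float = 0.08
    marginal_rate_a12_without_a9: float = 0.0
    edit_rate_a16: float = 0.0
    edit_rate_a18: float = 0.0
    cytosine_rates: dict = field(default_factory=dict)  # label -> {"C>T": rate, ...}
    indel_specs: tuple[IndelSpec, ...] = ()
    per_base_error: float = 1e-3
    low_q_rate: float = 1e-3
    depth: int = 10_000
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [self.edit_rate_a9, self.conditional_rate_a12_given_a9,
                 self.marginal_rate_a12_without_a9, self.edit_rate_a16,
                 self.edit_rate_a18, self.per_base_error, self.low_q_rate]
        rates += [r for subs in self.cytosine_rates.values()
                  for r in subs.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if sum(s.frequency for s in self.indel_specs) > 1.0:
            raise ValueError("indel frequencies exceed 1")
        for s in self.indel_specs:
            a, b = s.span
            if not (1 <= a <= b <= PROTOSPACER_LEN):
                raise ValueError(f"indel span {s.span} outside the protospacer")
        proto_end_ref = max(self.locus.ref_index(1),
                            self.locus.ref_index(PROTOSPACER_LEN)) + 1
        if self.read_length < proto_end_ref:
            raise ValueError(
                "read_length shorter than the primer+protospacer span")
        if self.read_length > len(self.locus.reference):
            raise ValueError("read_length exceeds the amplicon")

    @property
    def expected_overlap(self) -> int:
        return 2 * self.read_length - len(self.locus.reference)

    @property
    def p_a12(self) -> float:
        """Marginal A12 edit probability implied by the linkage structure."""
        return (self.edit_rate_a9 * self.conditional_rate_a12_given_a9
                + (1 - self.edit_rate_a9) * self.marginal_rate_a12_without_a9)


@dataclass
class TruthTable:
    """Realised allele composition of one simulated sample."""

    depth: int
    allele_counts: Counter            # combination label / indel label -> count
    edited_counts: dict               # adenine label -> alleles carrying the edit
    cytosine_counts: dict             # (label, substitution) -> alleles
    indel_counts: dict                # IndelSpec -> alleles

    def validate(self) -> None:
        if sum(self.allele_counts.values()) != self.depth:
            raise ValueError("allele counts do not sum to depth")

    def edited_fraction(self, label: str) -> float:
        return self.edited_counts.get(label, 0) / self.depth

    def to_frame(self):
        import pandas as pd
        rows = [{"allele": k, "count": v, "fraction": v / self.depth}
                for k, v in sorted(self.allele_counts.items())]
        return pd.DataFrame(rows, columns=["allele", "count", "fraction"])


def _apply_indel(reference: str, spec: IndelSpec, locus: AmpliconLocus) -> str:
    idx = sorted(locus.ref_index(p) for p in spec.span)
    lo, hi = idx[0], idx[-1] + 1            # half-open reference interval
    if spec.kind == "deletion":
        return reference[:lo] + reference[hi:]
    if spec.kind == "duplication":
        return reference[:hi] + reference[lo:hi] + reference[hi:]
    ins = spec.sequence if locus.strand == "+" else revcomp(spec.sequence)
    return reference[:hi] + ins + reference[hi:]


def simulate_amplicon_reads(config: SimConfig, *, paired: bool = True
                            ) -> tuple[list[ReadPair], TruthTable]:
    """Draw ``config.depth`` read pairs from the clonal allele model.

    Returns the reads together with a :class:`TruthTable` of realised allele
    counts.  With ``paired=False`` each returned :class:`ReadPair` holds the
    full merged fragment in R1 and an empty R2.
    """
    locus = config.locus
    rng = np.random.default_rng(config.seed)
    n = config.depth
    ref = locus.reference
    L = len(ref)
    rl = config.read_length

    # --- allele assignment ------------------------------------------------
    u = rng.random(n)
    indel_of = np.full(n, -1, dtype=np.int64)
    cum = 0.0
    for k, spec in enumerate(config.indel_specs):
        indel_of[(u >= cum) & (u < cum + spec.frequency)] = k
        cum += spec.frequency
    subst = indel_of < 0

    a9 = rng.random(n) < config.edit_rate_a9
    p12 = np.where(a9, config.conditional_rate_a12_given_a9,
                   config.marginal_rate_a12_without_a9)
    a12 = rng.random(n) < p12
    a16 = rng.random(n) < config.edit_rate_a16
    a18 = rng.random(n) < config.edit_rate_a18
    adenine_masks = {"A9": a9, "A12": a12, "A16": a16, "A18": a18}
    adenine_masks = {k: v & subst for k, v in adenine_masks.items()
                     if k in locus.named_positions}

    # substitution types at one position are mutually exclusive on an allele
    cyto_masks: dict[tuple[str, str], np.ndarray] = {}
    for label, subs in config.cytosine_rates.items():
        u_c = rng.random(n)
        cum_c = 0.0
        for sub, rate in subs.items():
            cyto_masks[(label, sub)] = (u_c >= cum_c) & (u_c < cum_c + rate) & subst
            cum_c += rate
        if cum_c > 1.0:
            raise ValueError(f"cytosine rates at {label} exceed 1")

    # --- truth table --------------------------------------------------------
    allele_counts: Counter = Counter()
    labels_sorted = sorted(adenine_masks, key=lambda l: int(l[1:]))
    combo_key = np.zeros(n, dtype=np.int64)
    for b, lab in enumerate(labels_sorted):
        combo_key |= adenine_masks[lab].astype(np.int64) << b
    for key, count in zip(*np.unique(combo_key[subst], return_counts=True)):
        labs = [labels_sorted[b] for b in range(len(labels_sorted))
                if key >> b & 1]
        allele_counts["+".join(labs) if labs else "WT"] = int(count)
    indel_truth = {}
    for k, spec in enumerate(config.indel_specs):
        c = int((indel_of == k).sum())
        indel_truth[spec] = c
        allele_counts[f"indel:{spec.kind}:{spec.span[0]}-{spec.span[1]}"] = c
    truth = TruthTable(
        depth=n,
        allele_counts=allele_counts,
        edited_counts={k: int(v.sum()) for k, v in adenine_masks.items()},
        cytosine_counts={k: int(v.sum()) for k, v in cyto_masks.items()},
        indel_counts=indel_truth,
    )
    truth.validate()

    # --- fragment construction (code space 0..3) ---------------------------
    ref4 = _enc4(ref)
    frag = np.tile(ref4, (n, 1))

    def edited_ref_base(proto_pos: int, alt_proto: str) -> tuple[int, int]:
        idx = locus.ref_index(proto_pos)
        alt_ref = alt_proto if locus.strand == "+" else \
            {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_proto]
        return idx, _B2I[alt_ref]

    for lab, mask in adenine_masks.items():
        idx, code = edited_ref_base(locus.named_positions[lab], "G")
        frag[mask, idx] = code
    for (lab, sub), mask in cyto_masks.items():
        idx, code = edited_ref_base(locus.named_positions[lab], sub[-1])
        frag[mask, idx] = code

    # reads for substitution alleles
    r1 = frag[:, :rl].copy()
    r2 = frag[:, L - rl:].copy()                  # still reference-oriented

    # indel alleles: per-spec fragments (few reads; small batches)
    indel_rows: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k, spec in enumerate(config.indel_specs):
        rows = np.nonzero(indel_of == k)[0]
        if rows.size == 0:
            continue
        frag_k = _enc4(_apply_indel(ref, spec, locus))
        Lk = len(frag_k)
        if rl > Lk:
            raise ValueError("read_length exceeds the indel allele fragment")
        r1[rows] = frag_k[:rl]
        r2[rows] = frag_k[Lk - rl:]

    # --- sequencing error and qualities ------------------------------------
    def corrupt(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        err = rng.random(mat.shape) < config.per_base_error
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
        mat = np.where(err, (mat + shift) % 4, mat).astype(np.int8)
        qual = np.full(mat.shape, PHRED_GOOD, dtype=np.int16)
        qual[rng.random(mat.shape) < config.low_q_rate] = PHRED_LOW
        return mat, qual

    r1, q1 = corrupt(r1)
    r2, q2 = corrupt(r2)

    pairs: list[ReadPair] = []
    empty_q = np.array([], dtype=np.int16)
    if paired:
        r2rc = 3 - r2[:, ::-1]                    # complement in 0..3 space
        s1 = _dec4_rows(r1)
        s2 = _dec4_rows(r2rc)
        q2rc = q2[:, ::-1]
        for i in range(n):
            pairs.append(ReadPair(f"sim_{i}", s1[i], q1[i], s2[i], q2rc[i]))
    else:
        # full-fragment single reads (error draws independent of the paired mode)
        full, qf = corrupt(frag)
        sf = _dec4_rows(full)
        indel_frags = {k: _enc4(_apply_indel(ref, spec, locus))
                       for k, spec in enumerate(config.indel_specs)}
        for i in range(n):
            if indel_of[i] >= 0:
                fr, qr = corrupt(indel_frags[int(indel_of[i])][None, :])
                pairs.append(ReadPair(f"sim_{i}", _dec4_rows(fr)[0], qr[0],
                                      "", empty_q))
            else:
                pairs.append(ReadPair(f"sim_{i}", sf[i], qf[i], "", empty_q))
    return pairs, truth


def write_fastq_pairs(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    """Write paired reads as two Sanger-Phred+33 FASTQ files."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.seq1}\n+\n"
                     f"{''.join(chr(q + 33) for q in p.qual1)}\n")
            f2.write(f"@{p.id}\n{p.seq2}\n+\n"
                     f"{''.join(chr(q + 33) for q in p.qual2)}\n")


# ---------------------------------------------------------------------------
# clonal colonies

def simulate_colonies(n: int, genotype_mix: Sequence[float], noise: float,
                      seed: int = 0, locus: Optional[AmpliconLocus] = None
                      ) -> tuple[list[TraceProportions], list[str]]:
    """Simulate Sanger base-proportion traces for ``n`` clonal colonies.

    ``genotype_mix`` gives the (unedited, monoallelic, biallelic) fractions
    of the A9 edit; the edited-G signal fraction at A9 is 0, 0.5 or 1 plus
    truncated Gaussian noise, and every position carries a small amount of
    background signal spread over the other bases.
    """
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    mix = np.asarray(genotype_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("genotype_mix must be three nonnegative fractions summing to 1")
    locus = locus or hbb_demo_locus()
    rng = np.random.default_rng(seed)

    genotypes = rng.choice(3, size=n, p=mix)
    target_frac = np.array([0.0, 0.5, 1.0])[genotypes]
    labels = [["unedited", "monoallelic", "biallelic"][g] for g in genotypes]

    ref = locus.reference
    Lr = len(ref)
    a9_ref_idx = locus.ref_index(locus.named_positions["A9"])
    a_base = ref[a9_ref_idx]                      # reference-strand image of A
    g_base = "G" if locus.strand == "+" else "C"  # reference-strand image of the edit

    traces: list[TraceProportions] = []
    base_idx = {b: i for i, b in enumerate(BASES)}
    for i in range(n):
        mat = np.zeros((Lr, 4))
        spread = np.clip(np.abs(rng.normal(0.0, noise, size=Lr)), 0.0, 0.3)
        for j, b in enumerate(ref):
            mat[j, base_idx[b]] = 1.0 - spread[j]
            for alt in BASES:
                if alt != b:
                    mat[j, base_idx[alt]] = spread[j] / 3
        g = float(np.clip(target_frac[i] + rng.normal(0.0, noise), 0.0, 1.0)) \
            if noise > 0 else target_frac[i]
        main = 1.0 - spread[a9_ref_idx]
        mat[a9_ref_idx, :] = spread[a9_ref_idx] / 3
        for alt in BASES:
            if alt not in (a_base, g_base):
                mat[a9_ref_idx, base_idx[alt]] = spread[a9_ref_idx] / 2
        mat[a9_ref_idx, base_idx[a_base]] = main * (1.0 - g)
        mat[a9_ref_idx, base_idx[g_base]] = main * g
        mat[a9_ref_idx] /= mat[a9_ref_idx].sum()
        traces.append(TraceProportions(f"colony_{i}", mat, locus))
    return traces, labels


# ---------------------------------------------------------------------------
# longitudinal off-target panel

@dataclass(frozen=True)
class SnpSpec:
    site: str
    position: int           # protospacer position 1..20
    base: str
    frequency: float


@dataclass(frozen=True)
class EditSpec:
    site: str
    position: int
    frequency: float
    onset: str               # timepoint label at which editing appears
    base: str = "G"
    trajectory: tuple[float, ...] = ()   # optional per-post-timepoint override


@dataclass
class PanelSimConfig:
    """Generative parameters for one longitudinal multi-site panel."""

    sites: Sequence[PanelSiteDef]
    timepoints: Sequence[str]
    pretreatment: str
    depth: int | dict = 5000
    snp_specs: Sequence[SnpSpec] = ()
    true_edit_specs: Sequence[EditSpec] = ()
    error_rate: float = 1e-3
    subject: str = "subject1"
    seed: int = 0

    def __post_init__(self) -> None:
        tps = list(self.timepoints)
        if tps.count(self.pretreatment) != 1 or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be unique with exactly one pre-treatment")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        pre_idx = tps.index(self.pretreatment)
        by_name = {s.name: s for s in self.sites}
        for spec in self.true_edit_specs:
            if spec.site not in by_name:
                raise ValueError(f"edit spec references unknown site {spec.site}")
            if tps.index(spec.onset) <= pre_idx:
                raise ValueError("edit onset at or before the pre-treatment timepoint")
            if not 0.0 <= spec.frequency <= 1.0:
                raise ValueError("edit frequency must be in [0, 1]")
            if by_name[spec.site].sequence[spec.position - 1] == spec.base:
                raise ValueError(
                    f"edit spec at {spec.site}:{spec.position} is a no-op "
                    "(alt equals the reference base)")
        for spec in self.snp_specs:
            if spec.site not in by_name:
                raise ValueError(f"SNP spec references unknown site {spec.site}")
            if not 0.0 <= spec.frequency <= 1.0:
                raise ValueError("SNP frequency must be in [0, 1]")
            if by_name[spec.site].sequence[spec.position - 1] == spec.base:
                raise ValueError(
                    f"SNP spec at {spec.site}:{spec.position} is a no-op "
                    "(alt equals the reference base)")

    def depth_for(self, site: str, timepoint: str) -> int:
        if isinstance(self.depth, dict):
            return int(self.depth.get((site, timepoint),
                                      self.depth.get(site, self.depth.get("default", 0))))
        return int(self.depth)


def random_panel_sites(n: int, seed: int = 0, prefix: str = "OT") -> list[PanelSiteDef]:
    """Random 20-mer candidate sites for panel simulations."""
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        seq = "".join(BASES[j] for j in rng.integers(0, 4, size=PROTOSPACER_LEN))
        sites.append(PanelSiteDef(name=f"{prefix}{i:03d}", sequence=seq,
                                  contig="chrS", start=1000 * (i + 1), strand="+"))
    return sites


def simulate_panel(config: PanelSimConfig) -> PanelDataset:
    """Multinomial per-position count tables for every (timepoint, site).

    Per position the allele mixture is reference + germline SNP (+ true edit
    from its onset timepoint onward); uniform sequencing error moves a
    fraction ``error_rate`` of calls to the other three bases.  Pre-treatment
    samples carry SNPs and error but never edits.
    """
    rng = np.random.default_rng(config.seed)
    tps = list(config.timepoints)
    pre_idx = tps.index(config.pretreatment)
    e = config.error_rate

    snp_by_site: dict[str, list[SnpSpec]] = {}
    for s in config.snp_specs:
        snp_by_site.setdefault(s.site, []).append(s)
    edit_by_site: dict[str, list[EditSpec]] = {}
    for s in config.true_edit_specs:
        edit_by_site.setdefault(s.site, []).append(s)

    samples = []
    for t_i, tp in enumerate(tps):
        site_counts: dict[str, np.ndarray] = {}
        site_reads: dict[str, int] = {}
        for site in config.sites:
            depth = config.depth_for(site.name, tp)
            allele = np.zeros((PROTOSPACER_LEN, 4))
            for p in range(PROTOSPACER_LEN):
                allele[p, _B2I[site.sequence[p]]] = 1.0
            for snp in snp_by_site.get(site.name, ()):
                ref_i = _B2I[site.sequence[snp.position - 1]]
                allele[snp.position - 1, ref_i] -= snp.frequency
                allele[snp.position - 1, _B2I[snp.base]] += snp.frequency
            if t_i > pre_idx:
                for ed in edit_by_site.get(site.name, ()):
                    onset_i = tps.index(ed.onset)
                    if t_i < onset_i:
                        continue
                    if ed.trajectory:
                        f = ed.trajectory[min(t_i - onset_i,
                                              len(ed.trajectory) - 1)]
                    else:
                        f = ed.frequency
                    ref_i = _B2I[site.sequence[ed.position - 1]]
                    allele[ed.position - 1, ref_i] -= f
                    allele[ed.position - 1, _B2I[ed.base]] += f
            if (allele < -1e-9).any():
                raise ValueError(
                    f"allele fractions at site {site.name} exceed 1")
            obs = allele * (1 - e) + (1 - allele) * (e / 3)
            obs /= obs.sum(axis=1, keepdims=True)
            counts = (rng.multinomial(depth, obs) if depth > 0
                      else np.zeros((PROTOSPACER_LEN, 4), dtype=np.int64))
            site_counts[site.name] = counts.astype(np.int64)
            site_reads[site.name] = depth
        samples.append(PanelSample(
            subject=config.subject, timepoint=tp,
            is_pretreatment=(tp == config.pretreatment),
            site_counts=site_counts, site_reads=site_reads))
    return PanelDataset(sites=list(config.sites), samples=samples)
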