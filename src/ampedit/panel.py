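"""Statistical off-target calling from multiplexed amplicon panels.

The caller mirrors the longitudinal design of multiplexed off-target
(rhAMPseq-style) experiments: each subject contributes one pre-treatment
sample and several post-treatment samples, each quantified as per-position
base counts over the 20-nt protospacer match of every panel site.

Pipeline per subject:

1. depth filter — only sites with **more than** ``min_reads`` reads are
   analysed in a given sample;
2. SNP exclusion — a (site, position, base) with pre-treatment frequency
   above 10% that stays present (≥ the presence floor) at every other
   timepoint is a germline SNP and is removed from all further steps;
3. background model — mean and sample SD of the per-position base error
   rates (1 − reference-base frequency) pooled over every protospacer
   position of every retained site in the pre-treatment sample;
4. candidate nomination — a substitution is a candidate when its frequency
   exceeds both ``mean + 2·SD`` and the absolute floor (default 0.5%) in at
   least one post-treatment sample;
5. per-candidate one-sided, one-sample t-test of the post-treatment
   frequencies against the subject's pre-treatment frequency
   (alternative: greater), significant at ``p < alpha``;
6. nearest-feature annotation of significant sites by interval query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES, BASE_INDEX
from .locus import PROTOSPACER_LEN


@dataclass(frozen=True)
class PanelSiteDef:
    """One panel locus: its protospacer-matching 20-mer and coordinates."""

    name: str
    sequence: str
    contig: str = "chrU"
    start: int = 0           # 0-based half-open start of the 20-mer
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.sequence) != PROTOSPACER_LEN:
            raise ValueError("panel site sequence must be 20 nt")


@dataclass
class PanelSample:
    """Per-site position × base counts for one sequencing sample."""

    subject: str
    timepoint: str
    is_pretreatment: bool
    site_counts: dict         # site name -> (20, 4) int array
    site_reads: dict          # site name -> total read count

    def __post_init__(self) -> None:
        for name, counts in self.site_counts.items():
            counts = np.asarray(counts, dtype=np.int64)
            if counts.shape != (PROTOSPACER_LEN, 4):
                raise ValueError(f"site {name}: counts must be (20, 4)")
            if (counts < 0).any():
                raise ValueError(f"site {name}: negative counts")
            self.site_counts[name] = counts
        for name, reads in self.site_reads.items():
            if reads < 0:
                raise ValueError(f"site {name}: negative read count")

    def frequencies(self, site: str) -> np.ndarray:
        counts = self.site_counts[site].astype(float)
        cov = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, counts / cov, 0.0)

    def error_rates(self, site: str, reference: str) -> np.ndarray:
        """Per-position base error rate: 1 − reference-base frequency."""
        freqs = self.frequencies(site)
        ref_idx = [BASE_INDEX[b] for b in reference]
        return 1.0 - freqs[np.arange(PROTOSPACER_LEN), ref_idx]


@dataclass
class PanelDataset:
    """A subject's panel: site definitions plus time-ordered samples."""

    sites: list
    samples: list

    def __post_init__(self) -> None:
        subjects = {}
        for s in self.samples:
            subjects.setdefault(s.subject, []).append(s)
        for subject, samples in subjects.items():
            if sum(s.is_pretreatment for s in samples) > 1:
                raise ValueError(f"subject {subject}: more than one pre-treatment sample")

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject, None)
        return list(seen)

    def subject_samples(self, subject: str) -> list[PanelSample]:
        return [s for s in self.samples if s.subject == subject]

    def site(self, name: str) -> PanelSiteDef:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class BackgroundModel:
    """Pre-treatment sequencing/PCR error background for one subject."""

    subject: str
    mean_error: float
    sd_error: float
    n_positions_used: int
    excluded_snp_positions: tuple

    def __post_init__(self) -> None:
        if self.mean_error < 0 or self.sd_error < 0:
            raise ValueError("background mean/SD must be nonnegative")

    @property
    def threshold(self) -> float:
        return self.mean_error + 2.0 * self.sd_error

    def as_dict(self) -> dict:
        return {"subject": self.subject, "mean_error": self.mean_error,
                "sd_error": self.sd_error, "threshold": self.threshold,
                "n_positions_used": self.n_positions_used,
                "excluded_snp_positions":
                    [list(x) for x in self.excluded_snp_positions]}


@dataclass
class CandidateCall:
    """Statistical call for one candidate (site, position, substitution)."""

    subject: str
    site: str
    position: int             # protospacer position 1..20
    ref: str
    alt: str
    frequencies: dict         # timepoint -> frequency (None where depth fails)
    pre_frequency: float
    threshold: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    significant: bool
    reason: str = ""


class NoPretreatmentError(ValueError):
    """The subject lacks the pre-treatment sample the SNP/background rules need."""


def compute_site_frequencies(count_tables: dict, site_reads: dict, *,
                             subject: str, timepoint: str,
                             is_pretreatment: bool,
                             sites: Sequence[PanelSiteDef]) -> PanelSample:
    """Assemble a validated :class:`PanelSample` from raw count tables."""
    known = {s.name for s in sites}
    unknown = set(count_tables) - known
    if unknown:
        raise ValueError(f"count tables for unknown sites: {sorted(unknown)}")
    return PanelSample(subject, timepoint, is_pretreatment,
                       dict(count_tables), dict(site_reads))


def filter_by_depth(sample: PanelSample, min_reads: int = 1000) -> set[str]:
    """Sites with strictly more than ``min_reads`` reads in this sample."""
    return {name for name, reads in sample.site_reads.items()
            if reads > min_reads}


def classify_snps(samples: Sequence[PanelSample], dataset: PanelDataset, *,
                  snp_threshold: float = 0.10, presence_floor: float = 0.10,
                  min_reads: int = 1000) -> list[tuple[str, int, str]]:
    """Germline SNPs for one subject's timecourse.

    A (site, position, base) is a SNP iff its pre-treatment frequency
    exceeds ``snp_threshold`` and its frequency is at least
    ``presence_floor`` at every other timepoint where the site passes the
    depth filter.
    """
    pre = [s for s in samples if s.is_pretreatment]
    if len(pre) != 1:
        raise NoPretreatmentError(
            "SNP classification requires exactly one pre-treatment sample")
    pre = pre[0]
    others = [s for s in samples if not s.is_pretreatment]

    snps: list[tuple[str, int, str]] = []
    pre_pass = filter_by_depth(pre, min_reads)
    for name in sorted(pre.site_counts):
        if name not in pre_pass:
            continue
        ref = dataset.site(name).sequence
        freqs = pre.frequencies(name)
        mask = freqs > snp_threshold
        ref_idx = np.fromiter((BASE_INDEX[b] for b in ref), dtype=np.int64)
        mask[np.arange(PROTOSPACER_LEN), ref_idx] = False
        for p, b_i in zip(*np.nonzero(mask)):
            b = BASES[b_i]
            present_everywhere = True
            for s in others:
                if name not in filter_by_depth(s, min_reads):
                    continue              # missing data, not absence
                if s.frequencies(name)[p, b_i] < presence_floor:
                    present_everywhere = False
                    break
            if present_everywhere:
                snps.append((name, int(p) + 1, b))
    return snps


def estimate_background(pre: PanelSample, dataset: PanelDataset,
                        snps: Sequence[tuple[str, int, str]], *,
                        min_reads: int = 1000) -> BackgroundModel:
    """Pooled mean/SD of pre-treatment base error rates (SNP positions excluded)."""
    snp_positions = {(site, pos) for site, pos, _base in snps}
    retained = filter_by_depth(pre, min_reads)
    pool: list[float] = []
    for name in sorted(retained):
        ref = dataset.site(name).sequence
        errs = pre.error_rates(name, ref)
        for p in range(PROTOSPACER_LEN):
            if (name, p + 1) in snp_positions:
                continue
            pool.append(float(errs[p]))
    if len(pool) < 2:
        raise ValueError("fewer than 2 positions in the background pool")
    arr = np.asarray(pool)
    return BackgroundModel(
        subject=pre.subject,
        mean_error=float(arr.mean()),
        sd_error=float(arr.std(ddof=1)),
        n_positions_used=len(pool),
        excluded_snp_positions=tuple(sorted(snp_positions)))


def call_candidate_positions(post_samples: Sequence[PanelSample],
                             dataset: PanelDataset, bg: BackgroundModel,
                             snps: Sequence[tuple[str, int, str]], *,
                             floor: float = 0.005,
                             min_reads: int = 1000
                             ) -> list[tuple[str, int, str, str]]:
    """Candidate (site, position, ref, alt) substitutions.

    A candidate must exceed both the background threshold (mean + 2·SD) and
    the absolute frequency floor in at least one post-treatment sample; SNP
    positions are never candidates.
    """
    snp_set = {(site, pos, base) for site, pos, base in snps}
    cut = max(bg.threshold, floor)
    found: dict[tuple[str, int, str, str], None] = {}
    for s in post_samples:
        passing = filter_by_depth(s, min_reads)
        for name in sorted(passing):
            ref = dataset.site(name).sequence
            freqs = s.frequencies(name)
            mask = freqs > cut
            ref_idx = np.fromiter((BASE_INDEX[b] for b in ref), dtype=np.int64)
            mask[np.arange(PROTOSPACER_LEN), ref_idx] = False
            for p, b_i in zip(*np.nonzero(mask)):
                b = BASES[b_i]
                if (name, p + 1, b) in snp_set:
                    continue
                found.setdefault((name, int(p) + 1, ref[p], b), None)
    return list(found)


def test_candidates(candidates: Sequence[tuple[str, int, str, str]],
                    samples: Sequence[PanelSample], dataset: PanelDataset,
                    bg: BackgroundModel, *, alpha: float = 0.05,
                    min_reads: int = 1000) -> list[CandidateCall]:
    """One-sided, one-sample t-tests of post frequencies vs the pre frequency.

    Candidates with fewer than two post-treatment observations (after the
    depth filter) yield an indeterminate, non-significant call.  When every
    post value equals the pre value the test statistic is 0 and p = 0.5 by
    convention; a zero-variance sample away from the pre value gives p = 0
    (above) or p = 1 (below).
    """
    pre = [s for s in samples if s.is_pretreatment]
    if len(pre) != 1:
        raise NoPretreatmentError("candidate testing requires one pre-treatment sample")
    pre = pre[0]
    post = [s for s in samples if not s.is_pretreatment]

    calls: list[CandidateCall] = []
    for site, pos, ref, alt in sorted(candidates):
        def freq_of(sample: PanelSample) -> Optional[float]:
            if site not in filter_by_depth(sample, min_reads):
                return None
            return float(sample.frequencies(site)[pos - 1, BASE_INDEX[alt]])

        pre_f = freq_of(pre)
        freqs = {s.timepoint: freq_of(s) for s in samples}
        obs = [f for s in post if (f := freq_of(s)) is not None]
        if pre_f is None:
            calls.append(CandidateCall(pre.subject, site, pos, ref, alt,
                                       freqs, math.nan, bg.threshold, None,
                                       None, False,
                                       reason="pre-treatment depth fail"))
            continue
        if len(obs) < 2:
            calls.append(CandidateCall(pre.subject, site, pos, ref, alt,
                                       freqs, pre_f, bg.threshold, None, None,
                                       False, reason="fewer than 2 post observations"))
            continue
        arr = np.asarray(obs)
        if arr.std(ddof=1) == 0.0:
            if arr[0] == pre_f:
                t, p = 0.0, 0.5
            elif arr[0] > pre_f:
                t, p = math.inf, 0.0
            else:
                t, p = -math.inf, 1.0
        else:
            res = stats.ttest_1samp(arr, popmean=pre_f, alternative="greater")
            t, p = float(res.statistic), float(res.pvalue)
        calls.append(CandidateCall(pre.subject, site, pos, ref, alt, freqs,
                                   pre_f, bg.threshold, t, p, bool(p < alpha)))
    return calls


@dataclass
class PanelResult:
    """Full per-subject analysis output."""

    subject: str
    background: BackgroundModel
    snps: list
    candidates: list
    calls: list

    @property
    def significant_calls(self) -> list[CandidateCall]:
        return [c for c in self.calls if c.significant]

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {"subject": c.subject, "site": c.site, "position": c.position,
                   "ref": c.ref, "alt": c.alt, "pre_frequency": c.pre_frequency,
                   "threshold": c.threshold, "t": c.t_statistic,
                   "p": c.p_value, "significant": c.significant,
                   "reason": c.reason}
            for tp, f in c.frequencies.items():
                row[f"freq_{tp}"] = f
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_panel(dataset: PanelDataset, *, min_reads: int = 1000,
                  snp_threshold: float = 0.10, presence_floor: float = 0.10,
                  floor: float = 0.005, alpha: float = 0.05,
                  bh_correct: bool = False) -> list[PanelResult]:
    """Run the full off-target calling pipeline for every subject.

    ``bh_correct`` applies an optional Benjamini-Hochberg adjustment to the
    candidate p-values before the significance cut (off by default).
    """
    results = []
    for subject in dataset.subjects:
        samples = dataset.subject_samples(subject)
        pre = [s for s in samples if s.is_pretreatment]
        if len(pre) != 1:
            raise NoPretreatmentError(
                f"subject {subject} lacks a pre-treatment sample; the SNP and "
                "background rules cannot be applied")
        snps = classify_snps(samples, dataset, snp_threshold=snp_threshold,
                             presence_floor=presence_floor, min_reads=min_reads)
        bg = estimate_background(pre[0], dataset, snps, min_reads=min_reads)
        post = [s for s in samples if not s.is_pretreatment]
        candidates = call_candidate_positions(post, dataset, bg, snps,
                                              floor=floor, min_reads=min_reads)
        calls = test_candidates(candidates, samples, dataset, bg,
                                alpha=alpha, min_reads=min_reads)
        if bh_correct and calls:
            tested = [c for c in calls if c.p_value is not None]
            if tested:
                ps = np.array([c.p_value for c in tested])
                from statsmodels.stats.multitest import multipletests
                rej, p_adj, *_ = multipletests(ps, alpha=alpha, method="fdr_bh")
                for c, r, pa in zip(tested, rej, p_adj):
                    c.p_value = float(pa)
                    c.significant = bool(r)
        results.append(PanelResult(subject, bg, snps, candidates, calls))
    return results


def annotate_nearest_gene(calls: Sequence[CandidateCall],
                          dataset: PanelDataset,
                          features: pd.DataFrame) -> pd.DataFrame:
    """Nearest annotated feature for each call's genomic position.

    ``features`` needs columns contig/start/end/name (0-based half-open) and
    optionally ``feature_type``.  Distance is midpoint-to-midpoint, 0 when
    the site overlaps the feature; overlapping exon features classify the
    region as exonic, other overlaps as intronic, no overlap as intergenic.
    Ties on distance report the lexicographically first feature name.
    """
    rows = []
    has_type = "feature_type" in features.columns
    for c in calls:
        site = dataset.site(c.site)
        s_lo, s_hi = site.start, site.start + PROTOSPACER_LEN
        s_mid = (s_lo + s_hi) / 2
        sub = features[features["contig"] == site.contig]
        if sub.empty:
            rows.append({"site": c.site, "position": c.position,
                         "nearest_feature": None, "distance": None,
                         "region": "intergenic", "tie": False})
            continue
        overlaps = sub[(sub["start"] < s_hi) & (sub["end"] > s_lo)]
        if not overlaps.empty:
            region = "exonic" if (has_type and
                                  (overlaps["feature_type"] == "exon").any()) \
                else "intronic"
            cand = overlaps.assign(_d=0.0)
        else:
            region = "intergenic"
            mids = (sub["start"] + sub["end"]) / 2
            cand = sub.assign(_d=(mids - s_mid).abs())
        dmin = cand["_d"].min()
        best = cand[cand["_d"] == dmin].sort_values("name")
        rows.append({"site": c.site, "position": c.position,
                     "nearest_feature": best.iloc[0]["name"],
                     "distance": float(dmin), "region": region,
                     "tie": len(best) > 1})
    return pd.DataFrame(rows, columns=["site", "position", "nearest_feature",
                                       "distance", "region", "tie"])


def summarize_panel(result: PanelResult, dataset: PanelDataset) -> pd.DataFrame:
    """Longitudinal frequency table for the significant calls.

    One row per (site, timepoint); frequencies are missing (NaN) at
    timepoints where the site fails the depth filter.
    """
    samples = dataset.subject_samples(result.subject)
    rows = []
    for c in result.significant_calls:
        for s in samples:
            f = c.frequencies.get(s.timepoint)
            rows.append({"subject": result.subject, "site": c.site,
                         "position": c.position, "alt": c.alt,
                         "timepoint": s.timepoint,
                         "is_pretreatment": s.is_pretreatment,
                         "frequency": math.nan if f is None else f})
    return pd.DataFrame(rows, columns=["subject", "site", "position", "alt",
                                       "timepoint", "is_pretreatment",
                                       "frequency"])


# -- IO ----------------------------------------------------------------------

def read_features_bed(path) -> pd.DataFrame:
    """BED(6) feature reader: contig/start/end/name(/score/strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "contig", 1: "start", 2: "end", 3: "name"})
    if 5 in df.columns:
        df = df.rename(columns={5: "strand"})
    return df[[c for c in ("contig", "start", "end", "name", "strand")
               if c in df.columns]]


def read_features_gff(path) -> pd.DataFrame:
    """Minimal GFF3 feature reader (gene/exon records, Name or ID attribute)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({"contig": f[0], "feature_type": f[2],
                         "start": int(f[3]) - 1, "end": int(f[4]),
                         "name": attrs.get("Name", attrs.get("ID", f[2])),
                         "strand": f[6]})
    return pd.DataFrame(rows, columns=["contig", "feature_type", "start",
                                       "end", "name", "strand"])


def read_count_table_tsv(path) -> tuple[np.ndarray, int]:
    """Read one site's position × base count TSV (columns position,A,C,G,T)."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    if not np.array_equal(df["position"].to_numpy(),
                          np.arange(1, PROTOSPACER_LEN + 1)):
        raise ValueError("count table must cover protospacer positions 1..20")
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    return counts, int(counts.sum(axis=1).max())


def write_count_table_tsv(counts: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(counts), columns=list(BASES))
    df.insert(0, "position", np.arange(1, PROTOSPACER_LEN + 1))
    df.to_csv(path, sep="\t", index=False)
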