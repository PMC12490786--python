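# Methods

This note documents the models, parameter choices and numerical conventions
behind `ampedit`, and what the synthetic-data generators do and do not
emulate.

## Amplicon model and coordinates

An `AmpliconLocus` is the wild-type amplicon (forward primer … reverse
primer reverse-complement) with a 20-nt protospacer placed on either
strand.  Protospacer positions are 1-based, 5′→3′ on the protospacer
strand; all editing quantities are reported in these coordinates, with
bases complemented for minus-strand loci.  The named positions default to
the Makassar-surrogate layout: target/bystander adenines A9, A12, A16, A18
and deamination-prone cytosines C3, C5, C6, C8 of
`TTCTCCTCAGGAGTCAGATG`.  The bundled demonstration locus embeds this real
protospacer in deterministic pseudo-random flanking sequence (synthetic;
the genomic flanks are not distributed with the package).

## Read processing

Merging chooses, among overlap lengths ≥ 10 with mismatch fraction ≤ 0.25,
the overlap with the most matching bases (ties toward the longer overlap);
within the overlap the higher-Phred base wins (ties toward R1) and the
consensus quality is the maximum of the two.  The published statistical
overlap test of dedicated mergers is intentionally not reimplemented; for
amplicon data with a fixed fragment length the max-match rule is
sufficient and fully deterministic.

The quality filter discards merged reads with strictly more than 2 bases
below Q20.  The low-quality cutoff is not dictated by the protocol being
reproduced; Q20 is the conventional choice and both the threshold and the
count are configurable.  The pipeline order is merge → quality filter →
primer anchoring.

Primer anchoring is ungapped (Hamming) matching of the forward primer at
the 5′ end and the reverse-complemented reverse primer at the 3′ end,
allowing ≤ 2 substitutions and no indels, in exactly one of the two read
orientations; matches in both orientations indicate a malformed
(palindromic-primer) amplicon and are rejected with a distinct error.

## Alignment

Global affine-gap alignment (Gotoh three-state DP) with EMBOSS-needle
default DNA scoring: match +5, mismatch −4, gap open 10, gap extend 0.5,
where a gap of length L costs `open + (L−1)·extend`.  `N` scores 0 against
anything.  All penalties are multiples of 0.5, so float64 arithmetic is
exact and ties can be broken deterministically (diagonal over gaps,
gap-in-query over gap-in-reference).  The implementation is row-vectorised;
the left-gap state within a row is computed with a running-maximum
transform rather than a sequential scan.

Two exact fast paths accelerate sample quantification: reads identical to
the reference, and equal-length reads within Hamming distance 2 of it,
where the ungapped alignment is provably optimal under the default scoring
(a gapped alignment of equal-length sequences carries two gap openings,
−20, while at most 2 mismatch→match conversions gain 18).  Identical read
sequences are classified once and weighted by multiplicity.  Neither
shortcut changes any result.

## Read classification

A read is INDEL when any alignment gap overlaps the protospacer ± 10 bp.
The flank mirrors how indels are reported relative to the protospacer; the
window necessarily covers the protospacer itself and the flank width is
configurable.  Otherwise the read is EDIT (named adenines with A→G), WT
(no protospacer substitutions) or SUBST_OTHER.  A→G at a named adenine
takes precedence over incidental substitutions elsewhere — such reads are
EDIT, with all substitutions still tabulated positionally.

Positional base counts exclude INDEL reads: a gapped column has no
well-defined per-position base.  Indel frequencies, by contrast, are
computed over **all** retained reads, so the two summaries have different
denominators by design.  Insertions whose sequence equals the reference
k-mer immediately adjacent on either side are classified as tandem
duplications (alignment tie-breaking can place the gap on either side of
the duplicated block, so both sides are checked).  Indel spans are
protospacer-relative, 1-based; positions ≤ 0 lie 5′ of the protospacer.

Under deterministic tie-breaking, the aligner places a tandem-duplication
gap at the 5′ end of the repeated block, so an injected duplication of
protospacer positions 5–12 is reported with its insertion point after
position 4; localisation statements are therefore about the protospacer
window, not a single fixed coordinate.  Rare merge or alignment artifacts
(an overlap shifted by a sequencing error) can produce single-read indel
records; at the default error rate these stay orders of magnitude below
genuine injected indel frequencies.

## Sanger-trace genotyping

Input is a per-position base-proportion table; chromatogram deconvolution
is out of scope, which keeps the module independent of trace file formats.
The edited-signal fraction at a named adenine is G/(A+G); if A+G carries
less than half the total signal the estimate is indeterminate (mixed or
indel-bearing trace).  Genotype bands are symmetric around the diploid
expectations 0 / 0.5 / 1: `< 0.2` unedited, `0.2–0.8` monoallelic,
`> 0.8` biallelic, both thresholds configurable.  The degradation flag
fires when ≥ 5 consecutive positions at or after the protospacer start
have their strongest base below 0.7 of the total — the Sanger signature of
a frame-shifting allele.  Indel-size decomposition of degraded traces is
deliberately not reimplemented.

## Off-target discovery

Candidate enumeration slides the 20-mer over both strands, counts
mismatches (no bulges, `N` counts as a mismatch), and requires the 3-nt
IUPAC PAM immediately 3′ of the match; windows whose PAM would run off the
contig are skipped.  Scoring uses the published 20-entry MIT/Hsu position
weight vector, with the distance and multiplicity terms equal to 1 for
fewer than two mismatches, so a perfect match scores exactly 100.
Selection keeps every site below the mismatch maximum and fills remaining
slots with the best-scoring maximal-mismatch sites; ties are broken by
genomic coordinate, a convention this package fixes since published
rankings do not state one.  Genome-scale search is out of scope — the
enumerator targets synthetic or extracted references.

## Off-target panel caller

Per subject and sample, each panel site is summarised as protospacer
position × base counts; the base error rate at a position is one minus the
reference-base frequency.  Sites need strictly more than 1000 reads.
Frequencies at timepoints where a site fails the depth filter are treated
as missing, never as zero — absence of data does not break a SNP's
"present at all timepoints" requirement, nor does it contribute a
spurious zero to a t-test.

A (site, position, base) is a germline SNP when its pre-treatment
frequency exceeds 10% and it remains at or above the presence floor
(default 10%, configurable) at every other depth-passing timepoint.  SNP
positions are excluded from the background pool and can never become
candidates.

The background model pools the error rates of every protospacer position
of every retained site in the subject's single pre-treatment sample and
reports their mean and sample (n−1) SD.  A substitution is a candidate
when its frequency exceeds **both** mean + 2·SD and the absolute 0.5%
floor in at least one post-treatment sample; the conjunction anchors the
floor to measured noise while keeping a hard lower bound.

Candidates are tested with a one-sided, one-sample t-test of the
post-treatment frequencies against the subject's pre-treatment frequency
(alternative: greater — editing can only add the alternative allele).
Zero-variance samples are handled by convention: all values equal to the
pre-treatment frequency gives t = 0, p = 0.5; a constant sample above
(below) it gives p = 0 (p = 1).  Fewer than two post-treatment
observations yield an indeterminate, non-significant call with a recorded
reason.  No multiple-testing correction is applied by default; an optional
Benjamini–Hochberg flag exists.  A pooled across-subject mode was
considered and left behind the per-subject default, which matches the
one-pre-sample-per-subject design.

Nearest-gene annotation is a midpoint-distance interval query over BED or
GFF3 features (distance 0 when overlapping; overlapping exon features
classify a call as exonic, other overlaps as intronic, no overlap as
intergenic; distance ties report the lexicographically first feature and
are flagged).

## Synthetic-data generators

`simulate_amplicon_reads` draws whole alleles per read pair: A9 ~
Bernoulli(0.60 by default); A12 conditional on A9 (8% conditional, 0%
marginal by default, so P(A12) = P(A9)·cond + (1−P(A9))·marginal); A16/A18
independent; cytosine substitutions mutually exclusive per position; and
whole-allele indels such as the default-style 7–8 bp tandem duplications
inside the protospacer.  Indels are clone-level events, matching the
biology of editing outcomes, not per-read artifacts.  Reads are emitted as
overlapping pairs (R1 forward, R2 reverse-complement) so the merger is
always exercised; a flag emits pre-merged single reads.  Sequencing error
is a uniform per-base substitution at 10⁻³ (the upstream protocol does not
state its error magnitude; this is an explicit, configurable placeholder),
silent in the quality string; an independent low-quality process (Phred 2
at 10⁻³) exists solely to exercise the quality filter.  All other bases
carry Phred 37.  The truth table records realised allele counts, which sum
to the configured depth.

`simulate_colonies` draws colonies from an (unedited, monoallelic,
biallelic) mix with edited-signal fractions 0 / 0.5 / 1 plus truncated
Gaussian noise and a small background spread at every position.

`simulate_panel` draws per-position multinomial counts from an allele
mixture of reference, germline SNPs, and true edits that appear at a
configurable onset timepoint (optionally with a per-timepoint trajectory),
convolved with uniform sequencing error.  The default panel — 16 samples
(one pre-treatment), 50 sites, 5000 reads per site, 10⁻³ error — is the
scale at which the caller's error control and power are verified.

What the generators do **not** emulate: PCR duplicates and chimeras, index
hopping, quality-score miscalibration, context-dependent error profiles,
coverage variation along the amplicon, and clonal outgrowth dynamics.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated generative assumptions, not robustness to every artifact
of real sequencing data.

## Problem sizes in the test and acceptance runs

Parameter-recovery tests run at depth 10⁴ (editing rates) and 10⁵ (rare
indels, estimator-consistency bounds of 3 binomial SDs); the off-target
caller's type-I and power properties use 200 simulated panels each; the
enumeration oracle comparison uses a 100 kb contig with planted
near-matches; colony recovery uses 300 colonies.  The acceptance script
repeats the same computations at the same scales (50 panels per rate
estimate) with sub-seeds derived from its `--seed`.

## Known limitations

* The merger assumes the fragment is at least as long as each read
  (no adapter read-through model).
* Equal-length fast-path bounds are specific to the default scoring;
  custom scoring parameters disable them automatically.
* Indel span coordinates of ambiguously placeable gaps (tandem repeats)
  depend on the deterministic tie-break and may differ between strand
  descriptions of the same locus; types, sizes and frequencies do not.
* The SNP rule cannot distinguish a germline variant from an edit that was
  already present pre-treatment; this mirrors the underlying study design,
  which defines background by the pre-treatment sample.
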