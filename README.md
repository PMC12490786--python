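# ampedit

Amplicon deep-sequencing analysis of adenine base-editing outcomes, written
for preclinical HSC gene-therapy studies of the *HBB* Makassar strategy:
an adenine base editor (ABE8e-NRCH) converts the sickle codon to the benign
Makassar variant, and in animal models without the sickle allele a silent
bystander edit (A9 of the protospacer `TTCTCCTCAGGAGTCAGATG`) is tracked as
a surrogate.  The package quantifies on-target and bystander A→G editing,
cytosine deamination, and indels from amplicon reads; genotypes clonal
colonies from Sanger-style traces; enumerates candidate off-target sites;
and calls statistically significant off-target editing from longitudinal
multiplexed amplicon (rhAMPseq-style) panels.  A synthetic-data module
generates reads, traces and panels with the generative structure the
analysis assumes, so the whole pipeline is testable without animal data.

## What it computes

**Read processing.** Paired reads are overlap-merged (best-matching overlap,
higher-Phred consensus), discarded if more than 2 bases fall below Q20, and
anchored by both primers with at most 2 substitutions and no indels.

**Editing quantification.** Anchored reads are globally aligned to the
wild-type amplicon with an affine-gap Needleman–Wunsch aligner
(match +5, mismatch −4, gap open 10, gap extend 0.5; a gap of length *L*
costs `open + (L−1)·extend`). Each read is classified as WT, EDIT (the set
of edited adenines among A9/A12/A16/A18), SUBST_OTHER, or INDEL (any gap
within the protospacer ±10 bp).  Outputs: per-position base-frequency
table, editing-combination table, indel catalog (with tandem-duplication
detection), cytosine-deamination (C>T/C>G/C>A at C3/C5/C6/C8), and
background flagging against unedited controls (mean + 2·SD).

**Clonal genotyping.** From per-position base-proportion traces, the
edited-signal fraction G/(A+G) at A9 calls each colony unedited (< 0.2),
monoallelic (0.2–0.8) or biallelic (> 0.8); trace degradation inside the
protospacer flags indel-bearing colonies.

**Off-target discovery.** Both-strand mismatch scan (no bulges, IUPAC PAM,
default `NNN`, ≤ 4 mismatches) ranked by the MIT/Hsu specificity score

        S = 100 · Π(1−W[p]) · 1 / (((19−d̄)/19)·4 + 1) · 1/m²

over mismatch positions *p*, mean pairwise mismatch distance *d̄* and
mismatch count *m*; selection keeps all sub-maximal-mismatch sites and the
top-scoring maximal-mismatch sites.

**Off-target calling.** Per subject: sites need > 1000 reads; germline SNPs
(pre-treatment frequency > 10%, present at every other timepoint) are
excluded; the pre-treatment sample yields a pooled background error model
(mean, SD over all protospacer positions); a substitution is a candidate
when its frequency exceeds both mean + 2·SD and 0.5% in a post-treatment
sample, and is called significant by a one-sided one-sample t-test of the
post-treatment frequencies against the pre-treatment frequency (p < 0.05).
Significant sites are annotated with their nearest gene by interval query.

## Worked example

```bash
ampedit simulate-reads --seed 42 --depth 10000 --out sim
ampedit quantify --r1 sim/R1.fastq --r2 sim/R2.fastq \
    --locus sim/locus.yaml --out quant
```

The simulator draws 10,000 read pairs from the default ex vivo editing
regime (60% A9 editing, A12 occurring only on A9-edited alleles at 8%
conditional rate, 10⁻³ per-base error).  `quant/summary.json` then reads:

```json
{
  "retained_reads": 9996,
  "editing_frequency": {
    "A9": 0.5884, "A12": 0.0471, "A16": 0.0001, "A18": 0.0006
  },
  "class_fractions": {
    "WT": 0.4030, "A9": 0.5410, "A9+A12": 0.0470, "SUBST_OTHER": 0.0082, ...
  },
  "cumulative_indel_frequency": 0.0
}
```

The A9 estimate (58.8%) recovers the configured 60% rate within binomial
noise; A12 appears almost exclusively together with A9 (`A9+A12` at 4.7%
vs `A12` alone at 0.01%), reproducing the linkage built into the
generative model; bystander editing at A16/A18 stays at the sequencing
error floor.  `quant/combinations.tsv`, `position_table.tsv`, `indels.tsv`
and `cytosine_deamination.tsv` hold the full tables.

The same flow drives the other subcommands: `ampedit simulate-panel` /
`ampedit panel` for longitudinal off-target calling, `ampedit colonies`
for clonal genotyping, and `ampedit discover` for candidate-site
enumeration on a FASTA reference.

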