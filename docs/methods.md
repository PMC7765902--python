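# Methods

## Problem and model

Genomic imprinting is parent-of-origin-dependent allelic expression. In a
reciprocal-cross design (A×B and B×A), reads covering parental SNPs can be
assigned to the maternal or paternal allele; the genomic expectation for a
non-imprinted gene is a maternal ASR share of 2/3 in the triploid
endosperm (two maternal genome copies, one paternal) and 1/2 in the
diploid embryo. The caller tests each gene's pooled (m, p) counts per
cross and tissue with a one-degree Pearson chi-square against that
expectation, with no continuity correction and no multiple-testing
correction (a switch exists but is off by default; the raw χ² > 3.84 rule
is the procedure being reproduced). On top of significance, fold-change
rules apply: MEG requires m/p > 4 in endosperm or > 2 in embryo, PEG
requires p/m > 1 in endosperm or > 2 in embryo; "or" is inclusive, and
endosperm evidence alone suffices. All thresholds are strict
comparisons. A call is made only when both reciprocal crosses satisfy the
same-tissue rule — a single cross can never produce a call, which is what
distinguishes imprinting from cis-regulatory allelic bias.

The PEG endosperm rule p/m > 1 is read literally (paternal exceeding
maternal, already a strong deviation from the expected 1:2). An
alternative reading (one fold beyond the 1:2 expectation, i.e. p/m > 2·½)
is accommodated by setting `peg_fold_endosperm` in the configuration.

If the MEG rule fires via one tissue and the PEG rule via the other
(possible only with discordant tissue evidence), the gene is left
uncalled with a `conflict` flag rather than arbitrating between them.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| chi2 critical | 3.8415 (exact df=1, α=.05 quantile) | — | compared with ">" |
| MEG fold (endosperm / embryo) | 4 / 2 | ratio m:p | caller definition |
| PEG fold (endosperm / embryo) | 1 / 2 | ratio p:m | caller definition (literal reading) |
| FPKM expressed threshold | 0.5 | FPKM | strict "more than" |
| `min_total_asr` | 10 | reads per cross×tissue | no published depth floor exists; 10 keeps the χ² approximation serviceable while testing shallow genes; configurable |
| permutation replicates | 10,000 | — | matches the published simulations |
| background genes | 37,852 | genes | the annotated rice gene universe; always an explicit input |
| BHR threshold | 0.95 | — | conserved-pair definition |

## Synthetic data generator

The generator defines the study conditions downstream stages are tested
under. Per gene and sample, total ASR is negative binomial with mean
`mean_depth` (default 100 reads/gene — a free choice, since no empirical
per-gene ASR depth distribution is published for this design) and
dispersion k = 10 (variance μ + μ²/k; Poisson as k → ∞), giving the
overdispersion that makes χ² behaviour realistic. The maternal count is
binomial at the gene's tissue-specific truth fraction, oriented by the
cross's female parent. Planted MEGs default to maternal fraction 0.95 and
PEGs to 0.10 in endosperm; embryo fractions of planted genes sit midway
between the 1/2 baseline and the endosperm fraction. Non-imprinted genes
carry the 2/3 and 1/2 baselines exactly.

Two detectability loss modes are planted as gene-level properties:
`p_gene_has_snp` (default 0.95; genes without a parental SNP can never
yield ASR) and `p_no_asr_given_snp` (default 0.07; SNPs exist but no read
covers them). The defaults approximate the proportions seen in a deeply
polymorphic inter-population cross, where ~5% of assessed genes lacked
SNPs and ~7% of SNP-bearing genes lacked covering reads; both are far
higher in closely related crosses, which is representable by raising the
parameters. Planted clusters are adjacent same-class (preferentially
maternal-only) pairs, disjoint, never crossing a chromosome boundary.

All randomness flows from a single seed; each stage derives a child
generator deterministically, so outputs are bit-identical for a fixed
seed. What the generator does **not** emulate: read-level alignment error,
mapping bias toward the reference allele, InDel-induced artifacts,
correlated expression between neighboring genes, or biological replicate
variance beyond NB sampling. Passing tests therefore validate the
statistical machinery, not robustness to alignment artifacts in real data.

## Permutation nulls

Both nulls draw uniformly without replacement and use the one-sided
empirical upper 95th percentile (`inverted_cdf`, no interpolation — the
smallest value covering ≥ 95% of replicates) with strict exceedance:
an observed value equal to the bound does not "exceed" it. This
convention reproduces the published pairwise overlap bounds 8/6/4 and the
three-way bound 0 for set sizes 546/286/211 on the 37,852-gene background,
and is fixed as the default; a two-sided variant is available through
`NullDistribution.percentile`.

- **Overlap null**: each replicate draws all sets independently from the
  background and records the requested intersection statistic (pairwise or
  k-way). A `fix_first` variant holds the first set constant —
  statistically near-identical (the conditional overlap distribution is
  the same hypergeometric), kept for comparison.
- **Neighbor null**: each replicate draws `n_select` genes from the ordered
  genome and records the fraction of drawn genes having at least one drawn
  immediate rank-neighbor on the same chromosome — genes in neighbor
  pairs, not pairs. Chromosome boundaries break adjacency. Mini clusters
  themselves are maximal runs of rank-consecutive imprinted genes
  ("tandemly located without an intervening gene" is interpreted as gene
  rank adjacency, not base-pair distance, which is robust to annotation
  density); singletons are excluded, and cluster type is maternal-only /
  paternal-only / maternal-paternal by member classes.

For genome-scale nulls where only gene order matters, a schematic ordered
genome (37,852 unit genes over 12 chromosomes, the rice karyotype) is
used; edge effects scale as the chromosome count over the gene count and
are negligible.

## Pseudo-genome and liftover

Variants must be homozygous differences between the two parents; the
builder validates every ref allele against the reference and rejects
overlapping variants rather than resolving them. Coordinates are 0-based
half-open internally; VCF I/O converts to 1-based. For an InDel the common
prefix of ref and alt (the VCF anchor base) keeps its 1:1 coordinate
mapping; the remainder of ref becomes a deleted interval, the remainder of
alt an inserted interval. Deleted/inserted positions lift to a `DELETED`
sentinel, never an exception; all other positions round-trip exactly
(property-tested on random variant sets). Gene models are not rewritten by
the builder; intervals are lifted on demand.

## BHR ortholog matching

The bidirectional hit rate for a candidate pair (a, b) is
BHR = Rf × Rr with Rf = score_f(a,b) / max_b′ score_f(a,b′) and
Rr = score_r(b,a) / max_a′ score_r(b,a′) — forward and reverse
similarity scores normalized by each gene's best hit, the construction
under which BHR ∈ (0,1] makes a 0.95 threshold meaningful (mutual best
hits score exactly 1). The module consumes precomputed score tables
(BLAST outfmt-6-style TSV) for determinism; it never runs an aligner.
Genes with no hits in one direction are excluded.

## Problem sizes

The package's own test and acceptance runs use 10,000 permutation
replicates at the full 37,852-gene background (seconds of runtime), the
caller-recovery study at 1,000 genes with 60 planted imprinted genes, and
smaller genomes (200–5,000 genes) elsewhere — sizes chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- Read-level assignment (`assign_reads`) is provided for completeness but
  the native input is the per-gene ASR table; alignment, deduplication and
  base trimming are out of scope.
- FPKM is computed from supplied fragment counts and gene lengths, not
  estimated from alignments.
- Heterozygous parental variants are rejected, not phased.
- The overlap null treats genes as exchangeable; expression-matched
  backgrounds are not implemented.
- Replicates are pooled by summation before testing; no per-replicate
  concordance test is offered.
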