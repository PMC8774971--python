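# Methods

## Candidate-site detection

Detection works directly on aligned reads, with no matched DNA: every
genomic position whose filtered read stack contains a non-reference base
is a candidate, and genetic variation is removed afterwards by catalog
filters rather than by genotype modelling.

A read contributes to a position's base distribution iff it is mapped,
not flagged duplicate, not secondary/supplementary (nor `NH > 1` when the
tag is present), properly paired, has mapping quality ≥ 60, aligns a
base (not an insertion/deletion/reference skip) at that position, and
that base has quality ≥ 30. All thresholds live in `FilterConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_base_quality` | 30 | phred cutoff per contributing base |
| `min_mapping_quality` | 60 | unique-mapping MAPQ for hisat2-style aligners; a minimum, not an equality, so aligner variants that emit higher values still pass |
| `min_coverage` | 1 | reads required to consider a position |
| `min_variant_reads` | 1 | reads required to support a substitution |
| `exclude_duplicates` / `exclude_multimappers` / `require_concordant_pairs` | on | flag-level read filters |

When both mates of a fragment cover a position the fragment contributes
once: the higher-quality base wins, ties keep read 1. Double-counting
overlapping mates would spuriously sharpen variant frequencies.

A call records the base distribution (A/C/G/T counts, coverage, mean
contributing base quality to 2 decimals), the substitutions in
descending-count order (alphabetical on ties), and the variant frequency
of the principal substitution. Positions with reference base N are
skipped.

**Strand assignment.** Strand inference from read orientation is not
possible for unstranded libraries, so the gene strand of the unique
overlapping annotated gene is used; positions covered by genes on both
strands, or by none, are left unresolved and excluded from the editing
analysis. On minus-strand genes the forward-reference T→C observation is
complemented to A→G. Only strand-resolved A→G calls count as A-to-I;
all substitution types are retained in the raw call table for
diagnostics.

## Filter cascade

Fixed order: A-to-I/strand classification → coding-region restriction →
SNV-position exclusion → known-site split. The filters commute; the
order is fixed only for reproducible logs. SNV exclusion is positional
by default (a catalogued position is genetic variation regardless of
allele) with an allele-aware option. A known-site match requires
position plus a compatible substitution (A→G after strand resolution);
catalog entries whose strand conflicts with the assigned strand are
treated as unmatched with a warning. Two branches leave the cascade:
known-matched sites feed per-site differential testing; the full coding
A-to-I set feeds the burden comparison (known-site matching protects the
per-site tests from rare uncatalogued SNVs, while the burden statistic
tolerates them because they affect both cohorts alike).

## Differential testing

A sample is "edited" at a site iff the site survived that sample's
calling and filtering — with the default thresholds a single variant
read suffices. Per site the edited/total counts per cohort form a 2×2
table tested with the two-sided Fisher exact test (point-probability
summation, the `fisher.test` convention; implemented via
`scipy.stats.fisher_exact` and cross-checked in the tests against exact
integer enumeration of all tables with the observed margins).

Multiplicity correction is Benjamini–Hochberg over the full tested site
set. `bh_adjust(p, m_total)` accepts an `m_total` larger than the list
when only the smallest p-values are supplied, enabling reproduction of
published adjusted columns from a table's top rows; Bonferroni is
available behind `method="bonferroni"`.

## Editing burden

Per sample, the raw burden is the size of its detected coding A-to-I
site set; because deeper libraries discover more sites, the normalized
burden is sites per million mapped reads (raw × 10⁶ / mapped reads).
Groups are compared with the two-sided Wilcoxon rank-sum test: exact
enumeration when the pooled sample is ≤ 25 and tie-free, otherwise the
normal approximation with tie and continuity correction. Both raw and
normalized p-values are always reported, since normalization choices are
themselves a degree of freedom.

## Synthetic cohorts

The simulator emulates the data-generating process the pipeline assumes:

- a small genome of single-exon genes on alternating strands, with
  intergenic spacers;
- editing sites planted inside coding regions, reference base A on plus
  genes and T on minus genes (minus-strand sites exercise the complement
  rule); each site has per-group prevalences π_ctrl, π_case (a sample is
  edited ~ Bernoulli(π_group)) and a per-read editing rate φ;
- SNV positions with hom-ref/het/hom-alt genotype frequencies; the alt
  allele mimics an editing substitution, so only the SNV filter removes it;
- reads as 2×100 nt proper pairs (MAPQ 60, all-match CIGAR, constant
  base quality 40), fragment length 250; editing and heterozygous-SNV
  alleles are drawn per cDNA fragment so mates agree; every base flips
  to a uniform wrong base with probability ε = 0.001 (typical short-read
  error scale);
- per-sample library sizes drawn as a uniform 0.7–1.3× factor around the
  configured mean coverage (default 50×).

Default cohort sizes are 44 controls vs 29 cases, the emulated study
design; desk-scale factories use 20+20 (recovery), 10+10 (all-null
calibration over 200 replicates) and 15+15 (burden directionality) so
the full test suite and the acceptance script run in minutes on one CPU.
Everything is deterministic given the seed.

What the simulator does **not** emulate: splicing, positional/GC
coverage bias, quality decay along reads, indels and soft-clipping,
strand-specific library chemistry, hyper-edited read clusters, and
correlated editing across sites. Passing tests therefore demonstrate
correctness of the counting and inference machinery under the stated
model, not robustness to alignment artefacts in real data.

## Numerical and design notes

- Coordinates are 1-based in every user-facing table; intervals are
  stored half-open 0-based internally, converted only at the I/O layer.
- Result tables print p-values at 3 significant digits and counts as
  `k/n`; rows sort by adjusted p, then raw p, then (chrom, position),
  making outputs byte-reproducible.
- Tested-site set for the differential table: the union of known-matched
  sites over all samples, with m_total equal to its size.
- The recovery scenario's null sites use prevalence 0.3 in both groups —
  an edited-but-non-differential background is the relevant null for FDR
  calibration; an all-zero background would never be tested at all.

## Known limitations

- A single-variant-read support threshold (`min_variant_reads = 1`) is
  error-sensitive at depth: with coverage c and error rate ε, an
  unedited sample is miscounted as edited with probability
  ≈ 1 − (1 − ε/3)^c (about 1.6% at c = 50, ε = 0.001). This inflates
  both cohorts' counts at weakly edited sites and measurably reduces the
  power of borderline contingency tables; raising `min_variant_reads`
  or adding a frequency floor trades this against sensitivity to rare
  editing.
- Strand assignment from annotation discards positions in bidirectionally
  transcribed regions.
- The exact Fisher test conditions on both margins; prevalence
  differences that manifest only through coverage differences are
  invisible to it.
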