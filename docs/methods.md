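# Methods

## Scope and data model

The package implements a five-stage dissection of a quantitative seedling
trait in a biparental cucumber cross: ordinal injury phenotyping, F2
interval mapping, in silico bulked-segregant analysis on a resequenced
germplasm panel, codon-level candidate annotation, and candidate validation
by expression and marker association. All stages run on synthetic data
generated by `ltqtl.sim`; every stochastic component takes an explicit seed
and one master seed derives per-stage streams (`numpy.random.SeedSequence`).

Genotype codes are 0 = AA (tolerant-parent homozygote), 1 = AB, 2 = BB
(sensitive-parent homozygote), −1 = missing, throughout. Genomic
coordinates are 1-based inclusive (GFF3/VCF convention). LTII is reported
on the 0–100 scale: the weighted-grade formula natively yields values in
[0, 1], but the reported parental and family indices (59.1, 14.9, 26.4, …)
are all on 0–100, so `compute_ltii` multiplies by 100.

## Injury index

Grades are restricted to {0, 1, 3, 5, 7, 9}; a phenotype file carrying any
other grade column is rejected rather than coerced, since a silent
reinterpretation of an ordinal scale would corrupt the index. Replicate
indices are averaged per family (unequal replicate counts allowed). The
between-experiment Pearson correlation requires at least three shared
families and nonzero variance.

## Cross simulator

Gametes are generated by a Markov walk along each chromosome: the allele at
the first locus is fair-coin, and between adjacent loci the allele flips
with probability r(d) from the map function (Haldane by default, Kosambi
selectable; the choice of map function is a modelling decision, and Haldane
— no crossover interference — is used consistently for simulation, map
building and the HMM). An F2 individual is the union of two independent
gametes. QTL positions are inserted into the walk so true QTL genotypes are
linked to flanking markers exactly as the map dictates.

F3 family phenotyping mirrors the field design: 3 replicates × 8 plants per
family. Per plant, each QTL genotype is drawn from the parent's selfing
distribution (AA→AA, BB→BB, AB→¼:½:¼) **independently across QTLs** —
within-family linkage between QTLs is ignored. This is an approximation:
the two linked QTLs on chromosome 6 would have correlated segregation
within heterozygous families. At the map distance involved (~50 cM) the
induced correlation is small and affects no quantity the pipeline reports.

Plant liability = μ + Σ_q [a_q·(x−1) + d_q·1(x=1)] + polygenic + N(0, σ_e),
with μ = 4.5, σ_e = 1.5 in grade units, and grade thresholds
(0.5, 2, 4, 6, 8) mapping liability onto {0, 1, 3, 5, 7, 9} — roughly
symmetric bins around the central grades. The sign convention makes the
sensitive-parent allele increase injury; dominance defaults to d = −a/2
(partial dominance of tolerance, matching an F1 that leans toward the
tolerant parent).

**Effect calibration.** `calibrate_family_variance` solves for the additive
effects and the family-level polygenic SD exactly, given target
family-mean variance fractions and a target between-experiment
repeatability. For family means over m plants, a QTL contributes
a²/2 + d²/16 among families and (a²/4 + d²/8) within heterozygous-parent
families; the grade quantisation adds ≈ bin²/12 = 1/3 per plant (the one
approximation in the algebra). Defaults: variance shares 10 % / 9 % / 25 %
for the three QTLs (chromosome 5 at 66.9 cM, chromosome 6 at 63.1 and
113.2 cM) and repeatability 0.87. The polygenic term is a property of the
F2 family (drawn once in `simulate_f2`), so it is shared across replicates
and experiments like the QTL genotypes are — without it, two experiments
would correlate only at the summed QTL shares (~0.44), far below what
replicated field phenotyping of the same families shows.

The default marker scaffold is 7 chromosomes × 27 markers at 5.4 cM
(189 markers, 982.8 cM, 200 kb/cM), matching the scale of a real
SSR-based cucumber map (190 markers, 990.8 cM, 5.2 cM mean spacing).

## Map building and QTL scanning

Adjacent recombination fractions are maximum-likelihood estimates via EM
over the nine two-locus F2 genotype classes (the hidden variable is the
number of recombinant gametes, ambiguous for the double heterozygote).
Marker order is *fixed to physical order and validated*, never searched;
apparently unlinked adjacent pairs (r → 0.5) are capped at 50 cM with a
warning. Mean inter-marker distance is defined as total length / marker
count (not length / (markers − chromosomes)), matching the arithmetic that
makes 190 markers over 990.8 cM average 5.2 cM.

Conditional genotype probabilities use a three-state forward–backward pass
with stationary F2 prior (¼, ½, ¼), transition matrix from two independent
meioses, and emission 1 − ε to the observed code (ε = 0.001 by default,
ε/2 to each other state; missing calls and pseudomarker grid points are
uninformative). The scan grid is the union of marker positions and a 1-cM
lattice. Missing genotypes are handled by the HMM, never imputed
destructively; missing phenotypes are dropped per scan.

Scans are Haley–Knott regressions. CIM is Haley–Knott with
forward-selected marker cofactors (additive + dominance pair per marker,
BIC stopping, at most 5) excluded within 10 cM of the test position; with
no cofactors it reduces identically to interval mapping. Per-position R²
is the model (IM) or partial (CIM) sum-of-squares fraction; the IM value
coincides with 100·(1 − 10^(−2·LOD/n)).

Permutation thresholds shuffle the phenotype only (genotypes fixed), take
the maximum LOD per shuffle over the whole grid, and use the conservative
empirical quantile (next order statistic at or above 1 − α), the standard
choice for a valid permutation test. A precomputed per-position SVD basis
makes each genome-wide maximum a single tensor contraction, so thresholds
and the type-I calibration run in seconds. `null_scan_calibration`
measures the realised genome-wide type-I error by giving each Gaussian
null replicate its own threshold.

2-LOD support intervals are the contiguous grid region around the peak
with LOD ≥ peak − 2 on the peak's chromosome, reported with the nearest
flanking markers at or outside its ends; peak ties break to the leftmost
position; an interval at a chromosome edge is one-sided. Reported
intervals always contain their peak (a printed source table in this
literature has a peak outside its own marker bracket; the implementation
does not emulate that). Loci are named `qLTT{chromosome}.{index}` in
positional order; peaks from different experiments are merged into one
locus when within 15 cM or with overlapping support intervals, and flagged
as repeatedly detected.

## Germplasm panel and concordance filter

The panel simulator plants `n_diagnostic_snps` (default 214) homozygous,
class-diagnostic SNPs uniformly inside the diagnostic window (defaults:
the 42-kb window 20,779,616–20,821,620 inside the region
20,591,185–21,186,690 on chromosome 6) and `n_background_snps` (default
600, ≈1 SNP/kb) class-independent SNPs across the region, with
heterozygous and missing calls injected at 2 % each outside the diagnostic
block. A background SNP that mimics the diagnostic pattern by chance
(probability ≈ 2·(½)^10·0.96^10 per SNP, about one per panel) is redrawn
by default, making the planted window the unique concordant signal; the
flag `exclude_concordant_background=False` restores pure chance
concordance for studying the filter's false-positive behaviour.

The filter itself: a SNP passes iff all evaluable calls in each bulk are
the same homozygous allele and the two bulk alleles differ. Strict policy
(default): any heterozygous call fails the SNP — these are inbred lines,
so a het indicates residual heterozygosity or a call error — and any
missing call fails it; `min_called` relaxes the missing rule per bulk.
Multi-allelic VCF records are split into biallelic SNPs on reading; calls
involving a different alternate allele become missing for the split row.
Interval spans are reported in whole kb by truncation, the arithmetic under
which both printed spans (595 kb and 42 kb) reproduce exactly.

Bulk construction takes explicit class labels when available; otherwise
the k lowest-injury lines are the resistant bulk and the k highest the
sensitive bulk, and ties straddling either cut raise an error rather than
resolving arbitrarily.

## Annotation

GFF3 coordinates are 1-based inclusive; only the first mRNA per gene is
used. The CDS is assembled in transcription order (minus-strand CDS
reverse-complemented; SNP alleles, given plus-strand as in VCF, are
complemented for minus-strand genes). The affected codon is mutated and
translated with the standard nuclear code; labels use three-letter amino
acid codes with the codon index (`Arg2Cys`), `Ter` marking stop
gained/lost (always non-synonymous). A reference-base mismatch between the
SNP record and the genome raises with the offending position; a SNP in an
incomplete terminal codon is flagged and not translated. SNPs within a
gene but outside its CDS are classed intronic (UTR exons are not
distinguished); outside any gene, intergenic.

## Validation

ΔCt = Ct_target − Ct_reference with technical replicates averaged before
any statistic; ΔΔCt subtracts the line's own mean calibrator ΔCt (0 h,
per-line self-calibration; a cross-line calibrator is a configuration
choice); fold = 2^−ΔΔCt, so the calibrator fold is 1 by construction and
folds are invariant to any constant added to all Ct values. Between-line
tests are Welch t on ΔCt (approximately normal; fold changes are not), per
timepoint, with stars at p < 0.05 / 0.01 / 0.001; timepoints with fewer
than two biological replicates are flagged untested.

Marker association: genotype classes a (resistant-parent homozygote),
b (sensitive), ab (het) from parental reference calls; one-way ANOVA of
family LTII across populated classes plus a 2-df chi-square of the class
counts against 1:2:1.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study-scale defaults
(n = 189 families, 3 × 8 plants, 189-marker map) for single runs, a
single-chromosome 21-marker map for the 50-replicate coverage study, and
200 replicates × 200 permutations for the type-I calibration — sizes
chosen so the full suite completes in about a minute while keeping the
Monte-Carlo error of each calibration check well inside its acceptance
band. Tie-breaks (leftmost peak), degenerate inputs (constant phenotype →
LOD ≡ 0 with a warning; collinear cofactors dropped with a warning) and
tolerances (probability normalisation to 1e-9; oracle equivalence of the
HK LOD to 1e-6) are fixed as stated.

## What the synthetic data does and does not show

The generator reproduces the *statistical geometry* of the study — map
scale, sample sizes, variance shares, repeatability, bulk design, a
diagnostic haplotype block of the right size in the right window — so
passing tests demonstrate that the estimators recover planted truths under
realistic noise. It does not emulate: genotyping-error structure of SSR
gels, segregation distortion, crossover interference, epistasis,
population structure in the germplasm panel, sequencing depth/allele
bias, or linkage between the panel's background SNPs (they are drawn
independently). Conclusions about real data should rest on the method
properties shown (calibration, coverage, oracle equivalence), not on the
synthetic effect sizes themselves. The toy annotated locus used by the
demo is a constructed 12-kb contig, not cucumber sequence.
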