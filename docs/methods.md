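# Methods

This note records the statistical models implemented by `triallele`,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions made
where the published procedure left the design open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention).
Formats that carry 1-based inclusive positions — the genotype-table
`pos` column and VCF `POS` — are converted at the I/O boundary, so an
interval printed as `chrIV:13950450–13973812` (1-based inclusive)
becomes `chrIV 13950449 13973812` internally and in BED output.
Missing allele frequencies are NaN, never 0: zero is a legitimate
frequency. VCF input uses only biallelic SNP rows; multi-allelic and
non-SNP rows are skipped with a logged warning, because the scan
operates on a single alternate-allele frequency per site.

## Triallelic scan

**Model.** Rows of the window matrix are populations described by
alternate-allele frequencies; per-individual dosage input (0/0.5/1) is
accepted through the same reader. Windows are 2,500 bp with a 500-bp
step, tiling each chromosome from position 0 to its last SNP; windows
with fewer than 3 SNPs or no variance are skipped (degenerate PCA and
clustering), and missing frequencies are mean-imputed per site within
the window.

**PCA filter.** PVE comes from the squared singular values of the
site-centred matrix with samples as observations. Thresholds are
inclusive (PC2 ≥ 20, PC1 + PC2 ≥ 75). Rationale: two population
clusters are collinear in sample space (all variance on PC1), while
three clusters in general position need two axes.

**k-means filter.** The genetic distance between two samples is the
per-site RMS frequency difference (Euclidean / √n_sites), which is
stable across windows of different SNP density; a per-site mean
absolute difference is available as an option. s(k) is defined as the
minimum, over partitions of the samples into k non-empty clusters, of
the summed average intracluster pairwise distance (singletons
contribute 0). The "reduction in s for k = 3" is measured against the
k = 1 baseline, the only k that makes "reduction" well defined for a
single clustering; thresholds are strict (> 0.65 and > 0.20).

*Optimisation.* For ≤ 9 samples the partition minimum is found by
exhaustive enumeration: the optimum frequently isolates outliers into
singleton clusters, which zero out their term in s and are not
reachable by centroid-based moves. For larger sample counts the
statistic is approximated by 20 seeded k-means++ restarts, each scored
by s (not inertia), followed by best-improvement single-point
relocation until no move lowers s; ties break to the lowest s and then
the lowest restart index, making the scan deterministic given its seed.

**Merging and intersection.** PCA-passing windows within 10 kb are
unioned, k-means-passing windows within 5 kb; the final call is the
base-pair intersection of the two merged tracks, so every call is
contained in both.

## Reciprocal ASE

Two F1 families share a marine dam; their sires carry the Long and
Short freshwater alleles. At heterozygous SNPs the reference/alternate
read ratio per library measures cis-regulatory divergence between the
parental alleles; a gene whose freshwater allele is up-regulated in one
cross and down-regulated in the other shows *reciprocal* ASE.

- **Eligibility.** Libraries are summed per fish; a fish is informative
  at a SNP if both alleles have ≥ 3 reads and each is ≥ 5% of the
  fish's total there; a SNP is eligible if ≥ ceil(20/24 · n) fish are
  informative, with n the number of distinct fish across both crosses.
  The library→fish map is an explicit column; by default each spine
  library is one fish (24 fish across the two crosses), matching the
  2 × 12 spine-library design.
- **Down-sampling.** Within each (cross, tissue) group, entries whose
  total exceeds the group median total are binomially thinned — each
  read kept with probability median/total — which preserves the
  expected allelic ratio and never increases a count. Down-sampling
  feeds the pooled Fisher test; the per-library log-ratio path uses raw
  counts, whose ratio statistics do not reward depth.
- **Tests.** Cross-vs-cross: two-sided Fisher exact on per-cross pooled
  ref/alt counts, and two-sided Mann–Whitney U on per-library log₂
  ratios (exact when the pooled sample is ≤ 20 and tie-free; the
  tie-corrected normal approximation otherwise). Within-cross: exact
  two-sided binomial test of pooled ref reads against 0.5.
- **Effect size.** `diff_ase` is the difference of cross-mean log₂
  allelic ratios (Long cross minus Short cross) — the only per-SNP
  effect size the test cascade computes, and the quantity bounded by
  ±1 in the control-tissue filter. Zero counts get a Haldane–Anscombe
  pseudocount of 0.5, applied only when a zero is present so nonzero
  ratios are unbiased; a library with both counts zero is excluded.
- **Cascades.** Spine candidates: exonic, total SNP depth (all
  libraries, all tissues) < 5,000 reads, both spine tissues (dorsal
  spine DS, pelvic spine PS) at unadjusted p < 0.05 with concordant
  sign of diff_ase, and both control tissues (pectoral fin PF, heart H)
  quiet (p > 0.05, |diff_ase| < 1). Reciprocal genes: in ≥ 1 tissue,
  both crosses' pooled ratios differ from 0.5 (binomial p < 0.05), the
  crosses differ from each other (Mann–Whitney and Fisher p < 0.05) and
  |diff_ase| ≥ 1 (two-fold); genes reported at 1-SNP and ≥ 2-SNP
  stringency. No multiple-testing correction is applied anywhere — the
  cascades filter on unadjusted p-values by construction.
- **Enrichment.** Observed = called genes within 50 kb of any region;
  null = the same count for 10,000 equal-size gene sets drawn uniformly
  without replacement; p = (1 + #{null ≥ obs})/(10,000 + 1), which is
  never anti-conservative.

## Spine association

Each spine trait is residualized separately on intercept + standard
length + sex by OLS; "combined major spine residuals" is the per-fish
sum of the DS1, DS2 and PS residuals. Sex is always included unless it
is collinear (e.g. a single-sex sample), in which case it is dropped
with a warning — conditioning the model on the covariate's own
significance is unstable and is deliberately not done. The quintile
scan ranks fish by residual and compares the first and last fifths at
each site with a two-sided Fisher exact test on 2×2 allele counts
(2 per homozygote, 1 per heterozygote); the test behind the original
quintile comparison is unnamed, and the allele-count Fisher was chosen
as the natural exact test for small extreme groups. Marker tests treat
genotype classes as an unordered factor: one-way ANOVA F with
(g−1, n−g) df, PVE = 100·SS_between/SS_total (equal to ANOVA R²), and
conditional tests first remove the control marker's class means before
re-testing every other marker. Missing phenotypes or genotypes are
dropped pairwise per test. Under the null E[PVE] ≈ 100·(g−1)/(n−1), so
at n = 700 with three classes the estimator's bias is ≈ 0.3 points.

## Allele clock

Sequences are globally aligned (match 1, mismatch −1, gap open −5, gap
extend −1); the substitution rate is the p-distance over aligned
columns, excluding gap and N columns from numerator and denominator —
the cloned alleles contain structural variants, and only aligned bases
can be counted. No multiple-hit correction is applied: at distances
near 0.02 the correction is smaller than the alignment-choice
uncertainty (±0.001 on reproduced rates). The sister pair is the pair
with the smallest distance (ties lexicographic); branches come from the
three-point formula, which reconstructs the inputs exactly; negative
implied branches are clamped to 0 with a warning. Clock dates use
t = d/(2r) with a user-supplied per-lineage rate (the calibration value
itself is an input, not derived here); the deeper split uses the mean
of the two outgroup distances, since their clock times coincide only
for ultrametric triples.

## Recombination contrasts

Window rates are ΔcM/Δ Mb with cM linearly interpolated at the edges of
non-overlapping 100-kb windows lying fully inside the map span; the sum
of rate × length per chromosome therefore conserves total map length up
to edge truncation. Group contrasts use the two-sided Mann–Whitney U
(robust to the heavy right tail of rate distributions; Welch's t is
available); the cross-species mode pairs windows through a user-provided
synteny table, drops zero-denominator pairs with a count, and contrasts
the per-pair rate ratios the same way.

## Synthetic data

- **Landscape.** SNP positions are uniform draws at the requested
  density. Background sites share one mean frequency per SNP across all
  populations. Planted windows exploit that SNPs are biallelic: a
  planted SNP separates a bipartition of the clusters whose sides
  differ by `divergence`. Two-cluster windows use the fixed
  marine/freshwater bipartition; three-cluster windows pick the
  separated cluster per SNP at random, so each cluster pair differs at
  ~2/3 of planted SNPs and the three clusters sit in general position
  (two PCA axes), as real haplotype classes do. Per-population jitter
  is Gaussian (`noise_sd`, default 0.05) with clipping to [0, 1].
  Defaults (15 populations: 5 marine + 10 freshwater; 0.02 SNPs/bp ≈
  50 SNPs per 2.5-kb window) reflect a multi-population survey of a
  variable genome region. Not emulated: linkage disequilibrium decay,
  admixed/heterozygous populations between clusters, and variable
  missingness — so passing tests show the scan recovers clean planted
  structure, not that it is robust to those complications.
- **ASE counts.** Depth per SNP × library is negative binomial (mean
  60, dispersion 10); ref reads are Binomial(depth, p) with the
  freshwater allele written as the reference allele. Planted reciprocal
  genes use freshwater-allele fractions 0.73 (Marine × Short) and 0.36
  (Marine × Long) in spine tissues — the fractions whose pooled ratios
  give the observed 2.7-fold up- and 1.8-fold down-regulation — and
  0.5 in control tissues; null genes are 0.5 everywhere. The library
  plan mirrors the study: per cross 12 DS + 12 PS (one per fish) and
  6 PF + 6 H. Overdispersion of allelic ratios beyond binomial is not
  modelled (a p-jitter hook exists in the design but defaults to off),
  so planted-recovery results bound performance under clean binomial
  sampling.
- **Phenotypes.** Spine length = intercept + 0.08·SL + 0.3·sex +
  γ[genotype] + N(0, 0.5 mm), with genotypes Hardy–Weinberg at
  Long-allele frequency 0.5 and body length 52 ± 7 mm (adult
  wild-caught scale). `gamma_for_target_pve` inverts
  PVE = 2q(1−q)d²/(2q(1−q)d² + σ²) to plant an additive effect with a
  chosen expected PVE.

All generators are deterministic given (spec, seed) and emit truth
tables, because the package's acceptance standard is parameter
recovery.

## Problem sizes and tolerances

The test-suite and acceptance-script problem sizes are chosen so each
stage's recovery statistic is estimated with low Monte-Carlo error: the
scan runs on a 520-kb chromosome with 10 planted triallelic and 4
marine/freshwater windows; ASE recovery uses 250 genes × 3 SNPs (50
planted); null calibrations use 1,000 p-values per statistic, checked
one-sidedly against anti-conservatism (discrete tests are allowed to be
super-uniform); PVE recovery takes the median of 100 cohorts of 700
fish. Sensitivity of the spine-candidate cascade at the SNP level is
bounded near 0.92 by design — the two control-tissue exclusions each
pass a truly reciprocal SNP with probability ≈ 0.96 at 6 + 6 libraries
— which is why gene-level recovery (any of a gene's SNPs) is the
headline statistic.

## Known limitations

- The scan reports which populations cluster together only
  descriptively via ecotype labels; it does not identify which allele
  is marine vs freshwater inside a call.
- The heuristic (large-n) path of the k-means filter can in principle
  return a local optimum of s; the relocation refinement removes all
  such cases observed at small n, where the exact answer is available
  for comparison.
- The Mann–Whitney normal approximation is used above pooled n = 20;
  at the study's 12 + 12 spine design its p-values are mildly
  conservative, consistent with the cascade's design intent.
- The clock module assumes a strict clock and a user-supplied
  calibration rate; rate variation among lineages is not modelled.
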