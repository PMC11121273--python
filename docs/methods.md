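# Methods

This note documents the statistical methods, the synthetic-data model,
the numerical choices and the known limitations of `popconserve`.

## Data model

The common currency is a samples × variants dosage matrix counting
copies of the alternate allele (0/1/2, −1 for missing) with a variant
map (chromosome label, 1-based bp position, alleles) and sample sex
labels. Coordinates follow the VCF / PLINK MAP convention (1-based,
inclusive). Chromosome labels are strings; the autosome label set is
configurable and defaults to "1".."30" (donkey). VCF parsing goes
through cyvcf2 (GT field only; multiallelic records are skipped with a
warning). PED/MAP text carries no ref/alt designation, so the reader
takes the minor-by-count allele as alternate (ties broken toward the
lexicographically later allele) and records that decision in the
matrix provenance; an explicit allele map can override it.

## Quality control

Order of operations: samples with genotype detection rate below 0.90
are removed first; each SNP criterion is then evaluated over the
remaining samples on the full input SNP set, and the union of failing
SNPs is dropped. Criteria and defaults: SNP call rate ≥ 0.90, MAF ≥
0.01 (computed on called genotypes; an all-missing locus counts as MAF
0), Hardy–Weinberg exact-test p ≥ 10⁻⁶ (autosomal loci only), and
autosomes-only. The per-criterion counts in the report are
*standalone* — they may overlap and need not sum to `total − retained`;
this matches how genotype-QC cascades are conventionally reported and
is the only reading consistent with overlapping filters. Read-level
criteria (sequencing depth, Q20) apply upstream of a genotype matrix
and are accepted in the config for provenance only. The cascade is
idempotent: re-running it on its own output changes nothing.

## Diversity statistics

For a biallelic locus with alt frequency p (q = 1 − p):
MAF = min(p, q); He = 1 − Σpᵢ² (the definitional form, no n/(n−1)
correction by default — a correction flag exists); Ho = fraction of
heterozygous calls; PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ² (Botstein);
Ae = 1/Σpᵢ². PN is the fraction of loci with MAF at or above a
threshold, default 0.05: after a MAF ≥ 0.01 QC filter a 0.01 threshold
would force PN = 1, so the conventional 0.05 cut is the default and the
threshold is configurable.

### Hardy–Weinberg exact test

The two-sided exact conditional test: given the observed allele counts,
the number of equally likely allele arrangements producing h
heterozygotes is n!/(n_AA! h! n_BB!)·2ʰ; the p-value is the total mass
of het counts no more probable than the observed one. The weights are
computed in exact integer arithmetic (memoized per sample-size/allele
count), so tie resolution carries no floating-point ambiguity; rounding
enters only in the final division.

A caution for testing such tests: the p-values of a discrete exact test
are *super-uniform*, not uniform — P(p ≤ α) ≤ α with a large atom at
p = 1 (at n = 32 the mean p under the null is ≈ 0.68). Distributional
correctness is therefore checked against the exact conditional null
(two-sample comparison), plus the validity bound P(p ≤ α) ≤ α; a naive
uniformity test would reject any correct implementation.

### Effective population size from LD

Sved's relation E[r²] = 1/(1 + 4Nc) is inverted using squared Pearson
correlations of dosages between loci within 500 kb (missing calls mean
imputed), the sample-size adjustment r²_adj = r² − 1/(2n) floored at
10⁻⁶, and per-pair recombination fractions c = bp·10⁻⁸ (1 cM/Mb) capped
at 0.5. Two estimators are exposed: the per-pair mean of
(1/4c)(1/r²_adj − 1), and a pooled inversion at the mean r²_adj and
mean c. The pooled form is what the population summary reports: with
weak LD roughly half of all pairs fall at the adjustment floor and the
per-pair mean is dominated by the floor constant rather than the data.
No attempt is made to reproduce any particular published Ne value; the
estimator family is standard but bin choices, MAF floors and sample
corrections differ between programs and are all configurable here.

## Runs of homozygosity and F_ROH

Detection is the PLINK `--homozyg` two-stage scheme. Stage 1: a window
of `window_snps` consecutive markers slides along each chromosome; a
window is homozygosity-compatible when it has at most
`window_het_allowance` (1) heterozygous and `max_missing_in_run` (4)
missing calls; a marker is eligible when more than
`window_hit_threshold` (0.05) of the windows covering it are
compatible. Stage 2: maximal runs of eligible markers, split at
inter-marker gaps above `max_gap_bp` (1 Mb), become segments when they
carry ≥ `min_snps` (15) markers, span ≥ `min_length_bp` (1 Mb) and
contain ≤ `max_het_in_run` (1) heterozygous calls; a run with more
heterozygotes is split at its het markers into het-free sub-runs, each
re-tested, and het endpoints are always trimmed. Segment length is the
inclusive marker span (first to last marker position), not padded to
unobserved flanks.

Defaults are deliberately GBS-scaled (≈20 markers/Mb): `window_snps`
20 and `min_snps` 15 rather than the dense-array conventions of 50 and
100 — a 50-marker window spans ~2.5 Mb at GBS density, longer than many
genuine runs, which would then have no compatible window at all; and a
1 Mb run cannot carry 100 GBS markers. The window missing allowance of
4/20 matches call rates near 0.90–0.95 (1–2 missing calls expected per
window); the array-data ratio of ~1/10 lets chance missing clusters
shatter real runs.

F_ROH = Σₖ length(ROHₖ)/L with L the autosomal genome length covered by
the genotype data, default 2,302,664.694 Kb (donkey); segment lengths
are converted to Kb so units are consistent. Raising the minimum
segment length can only remove segments, so F_ROH is monotonically
non-increasing in that parameter (property-tested).

Recovery benchmarks plant tracts of 2–8 Mb and set the detector floor
at 1.5 Mb / 25 SNPs, just below the smallest planted tract. This is an
analysis choice, not a tweak: with the 1 Mb default floor the detector
also (correctly) reports shorter chance homozygous runs, which any
finite population in Hardy–Weinberg proportions genuinely contains, and
which would be scored as false positives against planted-tract truth.
Under that benchmark, tract recall and precision are ≥ 0.95 at ≥ 50%
reciprocal overlap and planted autozygosity fractions of 0, 0.05 and
0.25 are recovered within ±0.02.

## Relatedness

**G matrix.** VanRaden's method 1, G = ZZ′/2Σpⱼqⱼ with Z = dosage − 2p,
computed with *pairwise-complete* denominators: each pair's numerator
and denominator run over the pair's mutually called polymorphic loci
(the PLINK `--make-rel`/GCTA convention). A global denominator with
mean imputation deflates kinship by roughly the square of the call
rate (~10% at a 0.95 call rate), which is material at GBS missingness.
Allele frequencies default to the analyzed sample's own; a base-
population frequency vector can be supplied. Two estimator properties
worth remembering: with sample frequencies the off-diagonal entries of
unrelated pairs shift by about −2/n (−0.06 at n = 32), and in a herd
where most animals are close relatives the frequency estimate itself
absorbs relatedness and deflates G further. Mendelian calibration
(parent–offspring ≈ 0.5, half-sibs ≈ 0.25, founders ≈ 0) therefore
holds against base-population frequencies in founder-dominated samples,
which is how the calibration tests are constructed.

**IBS distance.** D = 1 − (N_IBS2 + ½N_IBS1)/N over each pair's
mutually called loci, equivalently mean |a − b|/2 of dosages; pairwise-
complete deletion (PLINK behavior), no frequency weighting.

**PCA.** Loci are standardized to (d − 2p)/√(2pq) with missing calls
contributing zero; the samples × samples matrix XX′/m is
eigendecomposed and coordinates are eigenvectors scaled by √eigenvalue
(smartpca scaling). That matrix is exactly the "standardized" GRM
flavor the package also exposes, and the coordinates span its top-k
eigenspace to machine precision (tested via subspace angles). The
VanRaden-1 G has a slightly different eigenspace in finite samples; it
remains the kinship used for family decisions. PC signs are arbitrary.

## Trees and families

**Neighbor joining.** Saitou–Nei: join the pair minimizing
Q_ij = (n−2)d_ij − r_i − r_j, branch lengths by the three-point
formulas, new distances d_uk = (d_ik + d_jk − d_ij)/2. Ties in Q break
toward the smallest (i, j) pair in current node order, so results are
deterministic. Negative branch estimates are clamped to zero with the
deficit moved to the sister branch, preserving each pair's total. The
tree is unrooted; for Newick serialization it is rooted at the last
internal join (two-leaf trees split their single edge evenly). Branch
lengths print with 6 decimals. On additive matrices NJ provably
recovers the generating topology; the tests verify 100% recovery on
random additive 6–8-taxon trees and agreement with an independent NJ
implementation.

**Family partition.** Males with pairwise G ≥ threshold (default 0.1)
are linked; connected components are the families (transitive closure —
a male related to either of two linked males belongs with both).
Each female's kinship to a family is her maximum G over that family's
males; she joins the argmax family if that value reaches the threshold
(ties toward the lowest family id), otherwise "other". The partition is
invariant to sample ordering, and raising the threshold only refines
the male partition (property-tested).

## Synthetic populations

The simulator emulates the study design this package targets: a herd
of 4 males + 28 females genotyped by GBS at ~45,000 SNPs across 30
autosomes of 76,755,490 bp each (2,302,664,700 bp total, matching the
F_ROH genome-length constant), ~3 sire families, call rate 0.95.

* **Founders** get two independent haplotypes per chromosome with
  alt-allele frequencies drawn uniformly on [0.05, 0.5]; genotypes are
  therefore in exact Hardy–Weinberg proportions.
* **Pedigree**: males are split round-robin into families; the first
  male of each family is a founder, further males are his sons by one
  unsampled dam (so sons are full sibs); `n_daughters` females
  (default 3, the rest founders) are daughters of the family heads by
  distinct unsampled dams, i.e. paternal half-sibs.
* **Meiosis**: crossover counts per chromosome are Poisson with mean
  equal to the map length in Morgans at a uniform 1 cM/Mb, positions
  uniform, no interference (Haldane), random start phase.
* **Autozygosity** is planted as explicit tracts (lengths uniform on
  1–11 Mb by default) by copying one parental haplotype over both
  chromatids; the length remainder is folded into the last tract so the
  planted fraction equals `target_froh` exactly, and tracts keep ≥ 2 Mb
  of normal sequence between them on a chromosome so each is
  individually identifiable. Ground truth (pedigree, tract intervals,
  founder frequencies) is returned alongside the matrix.
* **Missingness** is i.i.d. per call at 1 − call_rate, with an optional
  per-sample rate override for QC tests; optional X/Y markers exercise
  the sex-chromosome filter.
* Everything is deterministic given the seed.

What the simulator does *not* model: coalescent ancestry, mutation,
selection, realistic background LD decay (only family structure and
linkage induce LD), locus- or region-specific missingness, genotyping
error. Passing recovery tests therefore demonstrates correctness of the
estimators under clean Mendelian inheritance with sparse markers and
missingness — not robustness to genotyping artifacts in real GBS data.

## Problem sizes used in tests

Unit tests run on matrices from a handful to a few thousand markers.
The recovery and calibration suites use 10 × 100 Mb genomes at 20,000
markers (ROH), 8 × 80 Mb at 10,000 markers (kinship, families) and the
32-sample study design throughout; the acceptance script runs the full
default scale (30 chromosomes, ~45,000 markers, ~6 s). These sizes were
chosen as the smallest at which the quantities under test (Mendelian
means, tract overlaps, paternity assignment) are statistically stable.

## Known limitations

* PED/MAP polarity is unrecoverable for loci where the alternate allele
  is the majority allele; round-tripping through PED preserves dosage
  only when alt is minor (the reader's inference rule), which the VCF
  path does not suffer from.
* The HWE filter tests females and males jointly on autosomes; no
  relatedness-aware HWE correction is attempted (QC in related herds
  conventionally ignores this).
* LD-based Ne for a ~32-animal herd is order-of-magnitude guidance at
  best; confidence intervals are not computed.
* ROH detection parameters trade sensitivity against chance-run noise;
  at GBS density, runs below ~1 Mb / 15 markers are not callable.
* The family rule is a threshold heuristic on G; it does not infer
  pedigrees, and females related to several families join only the
  closest one.
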