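# Methods

## Composite selection signals

The scan contrasts a *selected* cohort against a *reference* cohort of
phased diploid SNP genotypes and assumes biallelic autosomal SNPs sorted
by (chromosome, position), positions 1-based (VCF convention).

**Constituent statistics.**

* *F_ST*: Weir–Cockerham (1984) two-population single-locus θ in the
  allele-count (haploid ANOVA) form
  θ = (MSP − MSG) / (MSP + (n_c − 1) MSG) with
  MSP = Σᵢ nᵢ(pᵢ − p̄)², MSG = Σᵢ nᵢpᵢ(1 − pᵢ)/Σᵢ(nᵢ − 1) and
  n_c = N − Σᵢnᵢ²/N for allele totals nᵢ. Negative estimates are kept
  (the composite uses ranks); SNPs fixed for the same allele in both
  cohorts, or with fewer than two called alleles in either cohort, are
  flagged invalid and excluded from ranking.
* *ΔSAF*: frequency of a candidate allele in the selected cohort minus
  the reference cohort. The candidate allele defaults to the allele
  minor in the reference cohort (`ref_minor`), a derived-allele proxy
  that makes positive values mean "the candidate rose in the selected
  cohort"; a fixed alt-allele orientation (`alt_allele`) is available.
* *XP-EHH*: ln(iHH_sel / iHH_ref). EHH at offset x from a core SNP is
  the fraction of haplotype pairs identical over the entire span
  core→x; the pooled curve (pairs must also share the core allele,
  i.e. the two core-allele curves weighted by their pair frequencies)
  starts at the core homozygosity and is integrated by the trapezoid
  rule over physical distance on each side, stopping when the curve
  falls below `truncate_at` (default 0.05), at the chromosome end, or
  at an inter-SNP gap above `gap_cap_bp` (default 200 kb, bounding
  integration across SNP deserts; such cores are flagged). Physical
  distance substitutes for genetic distance, as no genetic map is
  assumed. Raw scores are standardised to mean 0, sd 1 over valid SNPs
  genome-wide. EHH requires complete haplotypes: SNP columns with any
  missing allele are excluded from the scan (the upstream study imputed
  to completeness; this package requires completeness instead of
  re-implementing imputation), and cores where either cohort's iHH is
  zero or undefined are dropped from the composite with m reduced
  accordingly.

**Composite.** Per constituent: rank the n valid SNPs ascending (ties
averaged, which keeps the mean fractional rank at 0.5), r′ = rank/(n+1)
∈ (0,1), z = Φ⁻¹(r′). Per SNP, mean the m available z-values; the
p-value is the upper tail of N(0, 1/m) (one-sided, since selection
evidence is high rank in every constituent by construction), computed in
log space so extreme scores do not underflow; CSS = −log₁₀ p. SNPs
missing some constituents are combined with the reduced m rather than
discarded, which retains chromosome-end SNPs where XP-EHH is undefined.

**Smoothing and regions.** CSS is averaged within a window of
half-width 500 kb centred on each SNP (total 1 Mb), never across
chromosomes; a centred window is order-independent, unlike tiled
windows. Top fractions use k = ceil(fraction × n_valid) with cutoff
ties included. Clusters are maximal runs of top-1% SNPs with
consecutive gaps ≤ 1 Mb, kept at ≥5 members and — in strict mode — ≥1
top-0.1% member ("surrounded by" is operationalised as run membership,
since no geometric definition is standard); runs < 1 Mb apart (strict
inequality) are merged. Regions span the min..max member positions, are
ranked by their best smoothed score, and genes (BED or GFF3 gene
features) overlapping region ± 500 kb by at least 1 bp (closed
intervals) are attached.

**Known limitation — the composite null is not calibrated.** The
N(0, 1/m) reference assumes the constituent ranks are independent. They
are not: F_ST is essentially a monotone function of |ΔSAF| (null rank
correlation ≈ 0.95 between F_ST and |ΔSAF| in simulation), and XP-EHH
is rank-correlated ≈ 0.34 with F_ST, so √m·mean-z has sd ≈ 0.89 and
skew ≈ 0.9 under the null instead of being standard normal. Composite
p-values should therefore be read as a ranking device, which is how the
method is used (top-percentile thresholds); their tail rates are close
to nominal (≈ 0.046 below 0.05, ≈ 0.02 below 0.01) but a
Kolmogorov–Smirnov uniformity test rejects decisively at genome scale.
The acceptance suite keeps a strict KS check and it fails by design of
the statistic, not of the implementation: the combiner passes the same
check when fed truly independent z-values.

## Quality control

SNPs need call rate ≥ 95% and minor allele frequency strictly > 0.01
(matching the strict inequality of the upstream protocol; MAF 0 is
reported as `monomorphic`, other failures as `low_maf` /
`low_call_rate`); individuals need call rate ≥ 95%. The filters are
iterated to a fixed point so the operation is idempotent even when
removing individuals changes SNP call rates. Multi-allelic and indel
records are dropped at read time, not split.

## Association stages

* **PCA** decomposes the correlation (default) or covariance matrix by
  eigen-decomposition; components are ordered by decreasing variance
  and signed so each component's largest-magnitude loading is positive.
  For the speed phenotype, PC1 of the six sprint indices (peak
  velocity, acceleration time, average sprint velocity and three
  6-second distances) is the phenotype and sex enters the GWAS as a
  covariate.
* **GWAS** fits per-SNP OLS `y ~ 1 + dosage + covariates` on 0/1/2
  alt-allele dosages, dropping individuals missing that genotype;
  reports the genotype β, its standard error and a two-sided t-test.
  Monomorphic SNPs are invalid; collinear covariates raise. Mixed
  models for relatedness are out of scope — plain OLS is the headline
  model.
* **Effective tests**: Me sums, per chromosome block, f(λ) = 1(λ ≥ 1) +
  (λ − ⌊λ⌋) over eigenvalues of the SNP–SNP dosage correlation matrix
  (Li & Ji 2005); thresholds are genome-wide 0.05/Me and suggestive
  1/Me. With sample correlation noise (n comparable to block size) Me
  underestimates the count for truly independent SNPs; it is a
  conservative substitute for the external calculator used upstream.
* **Regional allelic test**: after region QC (MAF > 0.05, call rate ≥
  95%), each SNP's 2×2 case/control × allele table gets a 1-df Pearson
  χ² (no continuity correction, matching the standard allelic test);
  odds ratios use the Haldane +0.5 correction only when a cell is zero;
  Bonferroni adjustment multiplies by the surviving regional SNP count,
  capped at 1.
* **IBS permutation test**: similarity between individuals is the mean
  shared-allele fraction 1 − |gᵢ − gⱼ|/2 over co-called SNPs; the
  statistic is mean between-group minus mean within-group similarity
  (negative under differentiation); the p-value is the add-one
  estimator (1 + #{permuted ≤ observed})/(n_perm + 1) over seeded
  label permutations, which cannot return 0.

## Synthetic data

The generator emulates the statistical structure the scan assumes, not
the demography of any real population. Ancestral frequencies are
Uniform(0.05, 0.95); cohort frequencies follow the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.05 by default (modest
differentiation between connected populations — consistent with
observing no extreme F_ST between cohorts that exchange breeding
stock). Haplotypes are mosaics of k = 20 founders with a per-SNP switch
probability of 0.02, giving LD that halves over roughly 0.4 Mb at the
default 10 kb SNP spacing. The founder pool carries each cohort
frequency exactly (stochastic rounding of k·p alt alleles assigned to
founders in random order) so the finite pool adds no founder-effect
drift and the realised mean F_ST tracks the generating F (0.047 at
10,000 SNPs). The default panel is one 10 Mb chromosome, 1,001 SNPs,
50 diploids per cohort — small enough that a full scan takes about a
second while leaving ten 1 Mb windows.

A planted sweep copies one donor haplotype over ±0.5 Mb around the core
into 80% of the selected cohort's haplotypes, with independent per-SNP
flips at rate 0.005 on each copy (never at the core, so the core allele
frequency is at least the sweep fraction). Phenotypes: a single
additive QTL with Gaussian noise and an alternating-sex effect; the six
speed indices come from one latent factor with equal loadings 0.759,
chosen so the generating model implies a PC1 share of
(1 + 5·0.759²)/6 ≈ 0.647, then shifted to plausible units (m/s, s, m).
All generators are pure functions of (config, seed).

What the generator does **not** model: bottlenecks, migration and
continuous gene flow, recombination-map heterogeneity, array
ascertainment bias, and genotyping error. Passing tests on these panels
demonstrate that the statistics behave as designed under their own
assumptions — drift-only nulls and clean sweeps — not that real data of
any particular population will separate as cleanly.

## Problem sizes and reproducibility

The test suite and the acceptance script use desk-scale sizes chosen to
exercise every code path in seconds-to-minutes: 5,000–10,000 SNPs for
calibration checks, 20 replicate panels of 1,001 SNPs for sweep
recovery, 20 permutation replicates for the GWAS type-I rate (single
permutations are noisy because SNPs in LD share rejections), and 500
samples for the speed-index PCA. Every random draw descends from an
explicit seed; `scripts/acceptance.py --seed N` derives all its
sub-seeds from N, and pipeline runs write a JSON manifest (config,
versions, seed) sufficient to reproduce outputs bit-for-bit.
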