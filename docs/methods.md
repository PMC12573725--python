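# Methods

This note documents the models, numerical choices, and open design
decisions behind `crowmeth`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic study

The generator (`crowmeth.simulate`) is built as the generative inverse of
the downstream analyses: every quantity the pipeline estimates is a
parameter the generator sets, so parameter recovery is a meaningful
acceptance surface. It emulates two designs — a common garden (ComGar: 8
individuals, 2 per taxon × sex cell, sampled at Chick/Yearling/Adult, 24
libraries) and a hybrid-zone transect (HybZon: 22 male chicks, hybrid
index h spanning 0–1 including purebreds at both ends, years
2008/2013/2014) — plus a 28-individual resequencing panel (14 per taxon)
that feeds the population-genetic estimators, mirroring the separation of
bisulfite and whole-genome cohorts in real studies of this kind.

**Genome.** Default: two 3-Mb chromosomes (`chr18` carrying a 1-Mb focal
block at 1.0–2.0 Mb, and `chr1`), a desk-scale rendering of a ~1-Gb genome
with a ~2-Mb focal region; all sizes are configuration, not estimates.
Background sequence is i.i.d. at 42% GC with CpG dinucleotides thinned to
0.01/bp (the C of surplus CpGs mutated to T), reproducing vertebrate CpG
depletion so that islands are compositionally distinct. Genes are placed
in non-overlapping slots with three 400-bp CDS exons; a configurable
fraction receives a designed CpG island (token-shuffled sequence with
exact GC and CpG O/E counts) in its strand-aware 2-kb upstream window.
Repeats avoid CDS. A declared sex chromosome is supported (sex effects are
then preferentially placed there); the default genome is autosomal because
the default acceptance checks target the focal-region machinery.

**Variation.** Per-SNP taxon allele frequencies follow the
Balding–Nichols construction: ancestral p ~ U(0.05, 0.95), taxon frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.05 genome-wide and F = 0.60
inside the focal block; half the focal SNPs are forced near-fixed
(|p₁ − p₂| ≥ 0.9). Two-thirds of SNPs are transitions and a small fraction
of those sit on (or within 1 bp of) a CpG cytosine as C→T variants.
Hybrid genomes are ancestry mosaics drawn Bernoulli(h) per 5-kb block per
haplotype, with the focal region inherited as a single block — reflecting
its suppressed recombination — and no finer recombination map.

**Methylation.** Coverage is negative-binomial (mean 30, shape 8) with a
1% outlier tail drawn at 10× the mean, so the top-1% coverage filter has
real work to do. The latent methylation proportion per CpG is a
feature-class baseline (promoter 0.08; repeat 0.80; CDS/intron 0.70;
intergenic 0.75 — the bimodal promoter-hypomethylation pattern of
vertebrate blood) plus N(0, 0.04) site jitter and planted effects; counts
are beta-binomial with dispersion φ = 0.05. Planted effects (age 300 sites
at ±0.30 on a 0/0.5/1 Chick/Yearling/Adult code; sex 200 at ±0.30; taxon
150 at ±0.40 with 70% inside the focal region, half of those tied to the
cis ancestry of the focal block; year 30 at ±0.25) take the sign under
which the full delta is realisable from the site's baseline without
clamping, so the truth table records the effect actually simulated.
Taxon effects are scoped `both`/`comgar`/`hybzon` to give the
cross-experiment intersection genuine decoys. CpGs carrying a C→T
transition report alt-haplotype reads as methylated (the apparent-
methylation artifact that motivates SNP masking). Entries go missing at
3%, and each experiment independently drops 8% of sites to create the
partial inter-experiment overlap that limits intersection, except that
`both`-scoped taxon sites are always assayed in both experiments.
RRBS promoter enrichment is emulated by 5× sampling weight for promoter
CpGs among the 20,000 assayed sites.

All randomness flows from one seed through named SHA-based child streams
(`_stream(config, name)`), so a fixed config reproduces the fixture bundle
byte-for-byte and stages can be re-run independently.

**What the generator does not emulate:** read-level artifacts (alignment,
M-bias, incomplete conversion), covariance between neighbouring CpGs,
repeat-driven mapping bias, batch effects between sequencing efforts, or a
recombination map. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated model,
not that the pipeline is robust to upstream artifacts it never sees.

## 2. Annotation

CpG islands are called by a 200-bp sliding window (step 1) requiring
GC > 0.50 and observed/expected CpG > 0.60 with no N; overlapping
qualifying windows are merged, and each merged interval is trimmed — first
stripping non-C/G terminal bases, then shrinking deterministically from
the start — until the whole interval satisfies all three criteria
(length strictly > 200 bp included). The trim step is essential: without
it, qualifying windows that partially overlap an island drag AT-rich flank
into the merged interval and the whole-interval re-check rejects every
flanked island. This threshold-plus-trim detector deliberately replaces an
HMM-based caller: the published thresholds, not the HMM, define which
islands are retained downstream.

Promoters are islands overlapping (≥ 1 bp) the strand-aware
[TSS − 2000, TSS) window (reverse strand: the 2 kb beyond the annotated
end); each island is reported once regardless of how many genes it serves.
The feature track assigns every base exactly one label by the priority
promoter > repeat > CDS > intron > intergenic; the partition property
(full cover, no overlap) is asserted by sweep in the tests. Coordinates
are 0-based half-open internally; 1-based only in file formats (Bismark
coverage, VCF). Terminal partial windows are retained with their true
length so 5-kb window tilings stay partitions.

## 3. Population genetics

Fixed 5-kb coordinate windows with a minimum of 1000 genotyped
(variant + invariant) sites; on synthetic data every base is callable, so
the genotyped count defaults to the window length. Estimators, pooled or
per-population as noted:

- **Hudson F_ST** as a ratio of averages, 1 − mean(π_w)/mean(π_b), with
  π_w the average of the two populations' *unbiased* heterozygosities
  (2p̂q̂·n/(n−1)) and π_b = p̂₁(1−p̂₂) + p̂₂(1−p̂₁). The unbiased form makes
  the estimator mean-accurate for the Balding–Nichols F (recovered within
  ±0.03 at 10k SNPs in the acceptance tests); its one quirk is an exact
  −1/(n−1) value when the two samples are literally identical, which the
  tests pin down. A Weir–Cockerham option is not provided; Hudson was
  chosen for robustness to unequal sample sizes and oracle simplicity.
- **D_XY** = Σ_s [p̂₁(1−p̂₂) + p̂₂(1−p̂₁)] / L over genotyped sites L —
  invariant sites contribute zero to the numerator and length to the
  denominator, giving a per-bp divergence.
- **Tajima's D** and **Fu & Li's D\*** pooled across all haplotypes, with
  the standard normalising constants; both are reported missing (not 0)
  when a window has no segregating sites, to avoid biasing window means —
  downstream imputation handles the gaps. Both statistics are ratios
  normalised by an S-estimated standard deviation and carry a small
  negative null mean (≈ −0.05 at n = 20; the tskit reference
  implementation reproduces it), which the neutral-calibration test
  accounts for explicitly.
- **Haplotype diversity** Hd = n/(n−1)(1 − Σ f_k²) over distinct window
  haplotypes; phased input is required (synthetic data is phased; unphased
  input would report Hd missing rather than pseudo-phase).

The focal region is delineated as the span from the first to the last
window with F_ST strictly > 0.3 on the chromosome carrying the most such
windows, with on- and off-chromosome counts reported; zero qualifying
windows is a result, not an error.

Variant hard filters: biallelic SNPs, QUAL strictly > 20, site depth in
(0, 2 × mean]; genotypes with per-sample depth < 3 are set missing; sites
called in < 90% of samples are dropped. Transition (C↔T, A↔G) coordinates
are exported for methylation masking.

## 4. Methylation filtering

Counts are destranded: the forward-strand C and reverse-strand G of each
CpG dyad are summed into one unit keyed by the forward C. Destranding
maximises per-unit coverage and is exposed as a choice (`destrand` is a
separate step) since CpG methylation is strand-symmetric. The filter
cascade then runs in a fixed order: (1) drop sites off the assembly
chromosomes; (2) drop sites whose dyad (either position) overlaps a
transition SNP; (3) blank entries with < 10 reads; (4) blank entries above
the 99th coverage percentile of retained entries (threshold recorded in
the report); (5) drop sites missing in more than 3 samples. The "< 10
reads" rule is applied per entry (feeding the missingness rule) rather
than per site — the only reading under which the separate missingness
filter has work to do. The cascade is idempotent and its report counts
reconcile exactly; both properties are tested.

A site is **invariable** when the observed methylation-proportion range
across non-missing samples is strictly below 10%; sites with fewer than
two observations are indeterminate-input and belong to neither class.

## 5. Differential methylation

The per-site model is a beta-binomial regression with an arcsine link,
fitted in closed form rather than by iterative likelihood maximisation:
y_i = arcsin(2(m_i + ½)/(n_i + 1) − 1) (the ½/1 pseudocounts keep the
transform finite at p ∈ {0, 1}) has approximate variance
(1 + (n_i − 1)φ)/n_i, so weighted least squares with
w_i = n_i/(1 + (n_i − 1)φ̂) is an asymptotically efficient fit. φ̂ comes
from the residual variance of a preliminary unweighted fit by method of
moments, floored at 0 and capped at 0.99; the floor shrinks the median φ̂
slightly below the generating value, which is visible and harmless. Sites
are processed in vectorised batches grouped by missingness pattern; a
pattern leaving the design rank-deficient (or below the minimum sample
count) is skipped with a reason code.

The transparent WLS scheme was chosen over re-implementing a specific
shrinkage estimator because its contract can be verified: the acceptance
suite checks Spearman > 0.95 agreement of Wald statistics with an exact
beta-binomial maximum-likelihood oracle (numeric optimisation, logit
link) and 100% sign agreement for clear signals.

**Reference distribution.** Wald statistics are referred to Student-t
(per column) and F (joint, for multi-column covariates such as the
three-level age factor) with the residual degrees of freedom, not to the
Gaussian/χ². At n = 22 with four design columns the Gaussian reference is
light-tailed enough to push the realised FDR among hybrid-index DMPs to
~20% at nominal q < 0.01; the t/F reference restores calibration at a
power cost that mainly affects the small HybZon design — an asymmetry
(many ComGar taxon DMPs, few HybZon ones) that mirrors the intrinsic
power difference between a balanced purebred contrast and a 22-sample
ancestry gradient.

FDR is Benjamini–Hochberg per covariate across sites. Classification:
invariable flag wins; otherwise a covariate label is assigned iff its
q < 0.01, every other covariate's q is strictly > 0.01 (q = 0.01 exactly
disqualifies), and — for factor covariates only — the maximum absolute
pairwise group-mean proportion difference (unweighted sample means of
m/n per level) is strictly > 0.25. Continuous covariates (hybrid index)
need only the q conditions. Anything else is indeterminate; every site
gets exactly one label.

Cross-experiment validation intersects ComGar `taxon` sites with HybZon
`hybrid_index` sites at identical (chrom, pos) and reports both effect
directions. Repeated measures on the 8 ComGar individuals are modelled
with fixed effects only (no random intercept) — a fidelity caveat, noted
as such.

## 6. Resampling machinery

- **Chromosome enrichment**: exact binomial test of the DMP count per
  chromosome against the assayed-CpG proportion, Clopper–Pearson 95% CI;
  enriched iff the CI lower bound exceeds the expected proportion. The
  same routine serves the sex-DMP/Z-chromosome question when a sex
  chromosome is simulated.
- **Focal bootstrap**: per feature class, B = 1000 means of n_focal
  autosomal background CpGs sampled with replacement; default significance
  is the focal observed mean falling outside the background [2.5, 97.5]
  percentile band. The "two CIs do not overlap" phrasing is ambiguous when
  the focal side is a single mean; an optional `method="overlap"` also
  bootstraps the focal side and requires disjoint bands. The band rule is
  near-nominal when the background pool is much larger than the focal set
  (the study-like regime, verified at 5% ± 2 SE over 500 null datasets)
  and mildly anticonservative when the pool is small, since the pool-mean
  uncertainty is not in the band.
- **SNP-adjacent exclusion** removes CpG units with either dyad position
  within 1 bp of any SNP (transitions and transversions), intended to
  precede a bootstrap re-run.
- **Bootstrapped Spearman**: per metric, B = 1000 replicate rank
  correlations between window methylation divergence and the metric,
  resampling focal windows (inside) and equally many background windows
  (outside); significant iff the [2.5, 97.5] interval excludes zero.
  Vectorised rank arithmetic keeps 500-dataset calibrations cheap.
- **Methylation LD**: per site, individuals are encoded to binary
  methylation states by one-dimensional 2-means solved exactly as the
  best cut in sorted order (the optimum is always an interval split),
  removing Lloyd-initialisation nondeterminism; ties break to the lower
  cluster and the higher-centre cluster is state 1. D = f₁₁ − p_A p_B and
  D′ = |D|/D_max with the standard frequency bounds; D′ = 0 when D = 0 by
  convention, and monomorphic state vectors yield a flagged undefined
  result. States are per individual, not per gamete — a documented
  divergence from gametic LD, since methylation is measured per
  individual.

## 7. Ordination and window-level prediction

**dbRDA.** The sample distance matrix (Euclidean by default; any pdist
metric or a precomputed matrix) is Gower-double-centered and
eigen-embedded; constraints are per-term treatment-coded, centered, and
standardised ("scaled" ordination); the constrained fit is the projection
of the coordinates onto the sequentially orthonormalised term blocks
(Type-I). R² = constrained/total inertia; adjusted R² by the Ezekiel
formula 1 − (1 − R²)(n − 1)/(n − 1 − m). Per-term and overall F use
unrestricted row permutations of the response with p = (1 + #{F* ≥ F})/
(B + 1). With Euclidean distances the whole construction is numerically
identical to classical RDA on the centered data matrix — the module's
primary oracle (eigenvalues within 1e-8 in the tests) — and permutation p
is uniform under the null (rejection 0.05 ± 2 SE over 500 runs at 999
permutations). Negative eigenvalues from non-Euclidean metrics are
dropped.

**Window feature table.** Response: log(aggregate |taxon Wald statistic|
per 5-kb window + ε), ε = 1e-6, aggregate mean by default with a max
variant; predictors: GC, chromosome length, relative position, the five
feature-class fractions, and the five population-genetic metrics. Missing
metrics are imputed from the nearest populated window on the same
chromosome (midpoint distance, ties to the left; never across
chromosomes), with the imputed fraction recorded. Windows without assayed
CpGs are excluded; a missing site statistic in the input is an upstream
inconsistency and raises.

**Permutation importance.** Per replicate seed: 75/25 split, random grid
search with 5-fold cross-validation on the training fold (random forest
or gradient-boosted trees; grids in `features._GRIDS`), test RMSE, then
per predictor the mean RMSE increase over 10 random permutations of that
predictor's test column, floored at 0 and scaled to sum to 1 within the
replicate (so profiles are comparable across engines). A classification
variant (response binarised at the median, accuracy loss) is exposed as a
flag. Replicate count defaults to 10; the acceptance script uses 3 to
stay inside its time budget — a problem-size choice, recorded in the
output's `n` fields.

## 8. Problem sizes and determinism

Defaults throughout are the study-shaped desk-scale conditions: 2 × 3 Mb
chromosomes, 12k SNPs, 20k assayed CpGs, 24 + 22 + 28 individuals. The
test suite completes in about two minutes and `scripts/acceptance.py` in
under one; both are seed-deterministic. Monte-Carlo calibration tests use
500 replicate datasets (bootstrap and permutation nulls) and 500 neutral
coalescent windows, with tolerances stated as multiples of the binomial
standard error of the rate being checked.
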