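# Methods

## The analysis this package implements

The package quantifies how well volumetric sex differences in the brain are
conserved between humans and mice, and whether the regions where they are
conserved are also the regions whose gene-expression profiles are most
similar between the species.

**Standardized sex effects.** For each regional volume (and for total tissue
volume, TTV), an ordinary least-squares model is fitted to the z-scored
response:

```
z(vol) ~ 1 + b1*sex + b2*(age - mean age) + b3*TTV + b4*QC
```

Sex is coded female = 0 / male = 1, so b1 > 0 means male-biased; because the
response is z-scored, b1 is a unitless standardized effect size. The QC term
is a numeric surface-reconstruction quality index for human-style cohorts
(subjects below a threshold, default -200, are excluded first) and a
treatment-coded background-strain factor for mouse-style cohorts. TTV is
dropped as a covariate when the response is TTV itself, and can be dropped
globally (`include_ttv: false`) to reproduce the no-global-scaling
sensitivity analysis. Inference is the usual two-sided t test with n - k
residual degrees of freedom; p-values across regions are adjusted with
Benjamini-Hochberg FDR at q = 0.05. Sex differences in *variance* are tested
with the classic Levene test (one-way ANOVA on absolute deviations from the
group mean) applied to volumes residualized for TTV, age and QC. The mean
center is the default because the procedure is then the textbook Levene
statistic; the center is configurable.

**Cross-species congruence.** Sixty homologous regions (28 bilateral pairs
plus 4 midline structures) are aligned into a pair table of (human b1,
mouse b1). Agreement is measured with the percentage-bend correlation with
bend constant 0.2: for each variable, a robust scale estimate (the m-th
order statistic of absolute deviations from the median, m = floor(0.8 n +
0.5)) and a bend-adjusted location are computed, deviations are standardized
and clamped to [-1, 1], and a product-moment statistic is formed from the
clamped scores; the t-based p-value uses n - 2 degrees of freedom. Relative
to Pearson's r this bounds the influence of extreme regions (the bed nucleus
of the stria terminalis, with betas near 1, is the canonical example) while
using all of them. Two-sided p-values are reported.

**Per-region similarity scores.** The anatomical sex-effect similarity score
is the product (human b1)x(mouse b1): positive when the species agree on the
direction of the sex bias, with magnitude growing in the joint effect size.
The transcriptional similarity score is the Pearson correlation, per region,
between the two species' expression profiles over homologous genes, computed
on matrices that have been z-scored per gene across regions. The two scores
are themselves correlated across regions (percentage-bend again), overall
and within compartments.

**Gene-subset nulls.** When similarity is computed on a gene subset
(X-linked, hormone-signaling, ...), the observed score-vs-score correlation
is compared against a null of the same statistic over randomly drawn gene
sets of the same size (default 10,000 resamples, drawn uniformly without
replacement from the homologous-gene universe). The p-value uses the
add-one Monte-Carlo estimator p = (1 + #{null at least as extreme}) /
(n_resamples + 1), which can never return 0; two-sided p doubles the smaller
tail and caps at 1. Random subsets are *not* stratified by expression level
or chromosome — a documented simplification.

**Batch harmonization.** Multi-cohort tables are harmonized with a
parametric empirical-Bayes location-scale adjustment in the ComBat family:
each region is standardized on a fit that keeps sex and age effects,
per-batch means and variances are shrunk toward across-region empirical
priors (normal for locations, moment-matched inverse-gamma for scales,
solved jointly by iteration), and the shrunken batch effects are removed
before the preserved effects are restored. The implementation agrees with
Bioconductor's `sva::ComBat` to ~1e-14 on synthetic cohorts (this is a test
in the suite). A single batch is returned unchanged, and a batch with zero
within-batch variance in a region contributes no scale correction there
(the 0/0 case of any location-scale harmonizer).

## The bundled effect-size table and the compartment split

The package ships the published table of 60 paired standardized sex effects
with per-species significance flags, exactly as printed (three decimals).
On that table the percentage-bend correlation is r = 0.298 over all 60
regions.

The cortical/non-cortical split used for stratified analyses assigns the 13
bilateral cortical areas (agranular insula, anterior cingulate, entorhinal,
perirhinal, piriform, posterior parietal association, primary auditory,
motor, somatosensory and visual, retrosplenial, temporal association,
ventral orbital; 26 rows) to cortex and everything else — hippocampal
subfields, subiculum, cerebellar cortex, subcortical nuclei and midline
brainstem — to non-cortex (34 rows). This is the standard anatomical
reading, but the upstream study did not itemize its cortex membership, and
under this assignment the stratified correlations are r = 0.218 (cortex)
and r = 0.175 (non-cortex) rather than the originally reported 0.33 / 0.16.
A search over alternative memberships shows the reported cortical value is
only reachable by counting structures such as the subiculum or hippocampus
as cortex while dropping the insula, which we do not consider defensible;
we therefore keep the anatomical assignment and report the discrepancy
rather than tune the split. The assignment is data, not code: it lives in
the bundled region-map TSV and can be overridden via `region_map` in the
config. (Note also that the source's own figure caption prints the cortical
value as 0.31 where its text prints 0.33.)

## Synthetic data: what it emulates and what it does not

`simulate_cohort` draws per-subject sex, uniform age, Gaussian TTV with an
optional standardized sex shift, round-robin batch labels, and region
volumes of the form `baseline*(TTV/mean TTV) + sex shift + age trend +
batch offset + heteroscedastic Gaussian noise`. The raw sex shift is
calibrated by fixed-point iteration so that the shift expressed in
marginal-SD units of the volume equals the requested standardized beta —
this is what makes unbiased recovery of the planted effect a meaningful
test. Defaults mirror the qualitative species contrast of the data the
package models: the human-style spec plants a TTV sex shift of 1.28
standardized units and male residual-SD inflation of 1.15 with cohort sizes
597 F / 496 M and ages 22-35 y; the mouse-style spec plants neither, with
213 F / 216 M, postnatal-day ages 56-90, TTV ~450 mm^3, and strain/cohort
batch structure. Baseline regional volume defaults to 0.5% of TTV with
residual coefficient of variation 5% — round values of realistic order, not
fitted to any dataset.

`simulate_expression_pair` gives each region a shared latent gene profile;
each species' expression row loads sqrt(|rho_r|) on the latent profile and
sqrt(1-|rho_r|) on an independent one, plus optional noise, so the expected
cross-species correlation per region is rho_r (attenuated by noise as
rho/(1+noise_sd^2/shared_sd^2)). Gene symbols are upper-case for the human
matrix and title-case for the mouse matrix, joined by an identity homolog
map.

Deliberately not simulated: spatial covariance between regions, non-Gaussian
expression distributions, donor structure in expression sampling, and any
image-level processes. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to everything real data can do (a t3-tailed noise option exists
for exercising the robust-vs-Pearson contrast).

## Numerical choices and edge cases

- z-scoring uses the sample SD (ddof = 1); a constant response is a hard
  error, never silently zero.
- The percentage-bend order statistic takes the sorted value at index m
  with ties left as-is; pairs with a missing member are deleted before
  correlation and the retained n is reported.
- Correlations of |r| = 1 report p = 0 and an infinite t rather than
  dividing by zero.
- Gene subsets drawn in the permutation null are sorted before the
  statistic is computed so that identical sets give bit-identical values;
  the degenerate draw of the whole pool reproduces the observed statistic
  exactly and yields p = 1.
- Constant genes are dropped (with a logged count) before z-scoring;
  z-scoring requires at least 3 regions.
- One-per-family subsampling and every simulator are driven by
  `numpy.random.default_rng` seeds and are bit-reproducible.

## Problem sizes used in the checks

The test suite runs everything at desk scale: estimator bias and RMSE use
200 replicates of n = 400 (and n = 100 for the RMSE comparison);
correlation recovery uses 500 replicates of 60-region tables; the
permutation null is validated against the exact 20-subset enumeration of a
6-gene pool at 10,000 resamples; Levene calibration uses 2,000 replicates
of 50-per-group samples; p-value uniformity uses 500 null runs at 500
resamples each; harmonization checks use a 60-region, 300-subject,
3-batch cohort. These sizes were chosen to pin each property with
comfortable Monte-Carlo margins while keeping the whole suite under two
minutes.

## Known limitations

- The package consumes region-level tables and matrices; it does not touch
  images, segmentations, or raw atlas samples.
- Mixed-effects family modeling is out of scope; family structure is
  handled only by the seeded one-per-family subsampling sensitivity.
- The hormone/X-linked gene lists are inputs, not derived by the package.
- Percentage-bend inference assumes exchangeable pairs; regions are treated
  as independent observations, as in the original analyses, although
  bilateral homologs are clearly correlated.
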