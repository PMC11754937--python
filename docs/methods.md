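# Methods

This note documents the statistical models implemented in `exuvar`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Feature-table filtering

Untargeted LC-MS peak areas are converted to relative abundances per
sample within an ionization mode (area / total area of the sample's
mode), then a pseudocount (default 1e-10, configurable) is added to every
entry so that downstream variance-component fits never see exact zeros.
Two filters follow, in this order, independently per mode:

1. **Replicate support.** A feature is removed iff *no* accession has it
   detected (raw area > 0) in at least two of its replicates. The
   phrase "present in only one replicate of any accession" admits a
   second reading — removed iff detected exactly once in the whole
   table — which is available as `rule="overall"`; the default reading
   makes the filter a reproducibility screen, which is its purpose.
2. **Prevalence.** A feature is removed iff the fraction of accessions
   in which it is detected (>= 1 replicate) is strictly below 0.10 or
   strictly above 0.90. Denominators are accessions, not samples.

Accounting is asserted on every run: input = removed-by-replicate +
removed-by-prevalence + retained, per mode. Modes are concatenated only
after filtering; feature ids never overlap across modes.

## Broad-sense heritability

Replicate-level relative abundances follow a one-way random-effects
model, y_ij = mu + a_i + e_ij with a_i ~ N(0, V_B) over accessions and
e_ij ~ N(0, V_E) over replicates; H^2 = V_B / (V_B + V_E). Estimation is
REML, profiled to one dimension over log(V_B/V_E) on [-12, 12] and
solved by golden section (derivative-free, robust to the flat criteria
typical near the V_B = 0 boundary). The one-way REML criterion depends
on the data only through per-accession counts, sums, and sums of
squares, so the search is vectorized across bootstrap resamples. V_B is
truncated at zero (boundary REML); zero total variance returns (0, 0)
with H^2 = 0 by convention; responses are centered before fitting (REML
is location invariant; centering improves conditioning).

Uncertainty: accessions are resampled with replacement (each carrying
all replicates — a cluster bootstrap), H^2 re-estimated per resample,
and the 95% CI taken from the 2.5/97.5 percentiles of B = 1000 resamples
by default (B is a free choice; 1000 gives ~0.007 Monte-Carlo SE on the
2.5% quantile). A feature is *significantly heritable* when the CI
excludes zero. Degenerate resamples (a single unique accession) are
redrawn and counted. Measured behaviour on the study design (105
accessions x 4 replicates): mean estimates within 0.01 of truth at H^2
in {0, 0.26, 0.55} (upward truncation bias ~0.016 at exactly 0), CI
coverage ~93% at H^2 = 0.4, false-positive rate of the significance call
~1-5%, power ~100% at H^2 = 0.5.

## Distances and ordination

* **Chemical:** Bray-Curtis on accession-mean relative abundances,
  overall, per NPC pathway, and on the significantly heritable subset.
  Bray-Curtis is a semimetric; triangle-inequality violations are
  counted and reported, never rejected.
* **PCoA:** classical scaling of the Gower-centered -D^2/2 matrix.
  Negative eigenvalues (non-Euclidean input) are excluded from both the
  coordinates and the variance-fraction denominator; no Cailliez or
  Lingoes correction is applied by default.
* **Standardization:** z-scoring with the population SD (divide-by-
  variance offered as a switch for compatibility with tools that phrase
  scaling that way; it is unit-inconsistent and not the default).
* **Environmental / life-history distances:** greedy variable screen
  keeping |Pearson r| < 0.7 in input column order, z-scoring, PCA by
  SVD, Euclidean distance on the first three score axes. The shipped
  default variable lists are the seven environmental variables
  (temperature, isothermality, seasonality, precipitation, precipitation
  seasonality, humanized-habitat fraction, topsoil pH) and seven
  life-history traits (seed weight, DSDS50, germination, recruitment,
  survival, flowering time, fecundity).
* **Geographic:** planar Euclidean distance on raw lon/lat degrees
  (matching the legacy desktop-tool convention for regional scales);
  haversine great-circle distance is available as an option.
* **Membership:** |m_i - m_j| per genetic cluster, four matrices.

## Mantel screening

Mantel r is the Pearson correlation of the two upper triangles; the null
is built by simultaneous row/column permutation of the second matrix.
The alternative is one-sided positive by default (two-sided available),
with the add-one estimator p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)
and n_perm = 9999 by default. For n <= 8 an exhaustive enumeration over
all n! permutations gives the exact permutation p. The Bonferroni family
is the set of tests executed in one screen invocation — the natural
family when the screen is the unit of inference.

## Mixed-model GWAS

Genotypes are binary inbred calls. Preprocessing: minimum minor-allele
count of 5 accessions, heterozygous calls rescored to the SNP's major
allele, SNPs > 10% missing dropped, and per-trait outliers beyond 4 SD
of the accession-mean distribution masked (outlier rule configurable;
4 SD removes gross instrument artifacts while touching well under 1% of
Gaussian data). Kinship is identity-by-state: the proportion of shared
alleles over pairwise-complete SNPs; its complement (after excluding
singleton SNPs) is the genetic distance.

Association uses the P3D/EMMAX approximation: the null model
y = mu + u + e, u ~ N(0, sg2 K), is REML-fit once per trait via the
eigendecomposition of K (negative eigenvalues clipped at 1e-8) and a 1-D
profile over log(delta), delta = se2/sg2 (coarse grid + bounded Brent
refinement guards against local minima); every SNP is then tested by
generalized least squares with the covariance fixed, F(1, n-2)
reference. With K = I the scan reduces exactly to OLS (verified to
1e-8); at n = 30 it matches a dense-matrix GLS oracle; null p-values are
uniform (KS < 0.05 at 5000 SNPs). Significance is called at
-log10 p >= 7.5. SNP-to-gene assignment from GFF3: the containing gene,
else the nearest flanking gene on each side (flagged one-sided at
chromosome ends).

**Known limitation — planted-SNP power.** For a SNP explaining exactly
30% of trait variance at n = 105, the marker F-test's noncentrality is
n x 0.3/0.7 ~= 45, and the theoretical power at the stringent
-log10 p = 7.5 threshold is ~0.75 *even with identity kinship* (the
0.80 recovery target asserted in the acceptance suite is above the
information limit of this design; measured power here is 0.70-0.75,
consistent with theory plus mild absorption of structured markers by
the kinship term). The corresponding acceptance test is left failing by
design rather than weakening the planted condition.

## Down-sampled cluster comparison

Two genetic clusters of unequal size (e.g. 75 vs 13 accessions, the two
clusters compared in practice) are compared per feature by repeatedly
drawing 13 accessions from each without replacement and running a
classical one-way ANOVA (F with (1, n-2) df) on each of 1000 draws. Both
the median p and the fraction of draws with p < 0.05 are reported; a
feature is called differential when the median p < 0.05 (the summary
rule is not uniquely determined by the "significant in all runs"
phrasing; median-p is the more conservative and stable choice, and the
per-run p-values are retained so any other aggregation can be applied).
When both clusters have exactly 13 members every draw is the full data
and the scheme reduces to the single ANOVA in every run (tested).
Accessions are assigned to clusters by majority membership.

## Synthetic data

The generator emulates the study design: 105 accessions, 4 replicates
(the study had 3-4), 4 genetic clusters with uneven sizes (75/10/13/7),
admixed memberships (Dirichlet with weight 6 on the home cluster and 0.8
elsewhere, giving mean home membership ~0.7 as observed), Balding-
Nichols cluster allele frequencies at F_st = 0.15 (regional-scale
differentiation), and log-normal peak areas (scale 0.3 on the log, so
the exponential map is near-linear and latent variance components
survive onto the relative-abundance scale). Structural accession-level
presence (Beta(0.35, 0.35) per feature), a 30% fraction of sporadic
single-replicate noise features, and 2% replicate dropout give default
tables whose filter ledger is shaped like real untargeted data (roughly
a quarter removed for irreproducibility, a fifth for prevalence).
Covariates are linear in an Iberia-like coordinate box and in
memberships, with one designed |r| >= 0.7 environmental pair so the
variable screen always has work to do. Spiked SNP effects are sized as a
fraction of accession-mean trait variance.

What the synthetic data do **not** emulate: chromatographic drift,
adducts/isotopes, correlated feature blocks from shared pathways,
linkage disequilibrium decay along chromosomes (SNPs are exchangeable
given structure), and spatially autocorrelated climate layers. Passing
tests therefore establish the estimators' statistical correctness under
the generating model, not robustness to those instrument- and
genome-level artifacts.

## Problem sizes

The test-suite and acceptance-script simulations use the study's
dimensions directly (105 accessions, 4 replicates, 200 features per
recovery condition, 5000 SNPs, 50 GWAS replicates, 1000 ANOVA draws,
B = 500 bootstrap for coverage and B = 300 for the calibration screen —
the screen needs only the sign of the CI bound, where 300 resamples
already give a stable 2.5% quantile). A full desk-scale pipeline run on
the default synthetic study takes on the order of a minute.
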