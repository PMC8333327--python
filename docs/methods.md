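# Methods

`zoomacro` re-implements, as a tested library, a macroecological analysis
chain for net-sampled, image-measured zooplankton communities: per-object
size measurements become per-station community metrics, which are screened
against environmental covariates, modelled with penalized-spline additive
models, and finally clustered by the shape of their fitted response curves.
Because the original ocean data cannot be redistributed with the package,
the first stage is a synthetic "virtual transect" generator that emulates
the statistical structure of such data with full ground-truth bookkeeping,
so every downstream stage can be tested for recovery of known structure.

## The virtual transect generator

The generator emulates a one-time global transect: `n_stations` (default
168) stations with latitudes drawn unevenly (65% in the northern
hemisphere, mimicking the unequal coverage of real expeditions) and the
following covariate structure:

- **Temperature** is a smooth decreasing function of |latitude| plus noise
  (range about -1.8 to 31 degC).
- **Oxygen** is a decreasing affine function of temperature plus noise whose
  standard deviation is solved from the configured rank-correlation target
  (default Spearman rho about -0.97). This plants the
  temperature-oxygen anticollinearity that forces the downstream analysis
  into two parallel model variants.
- **Nutrients**: NO2NO3 is exactly lognormal; PO4 and SiO2 are shifted
  noisy power laws of NO2NO3 with noise solved from correlation targets
  (defaults 0.95 and 0.87). The additive shifts are monotone, hence
  Spearman-neutral, but push PO4/SiO2 away from lognormality so that NO2NO3
  is reliably the most normal of the trio under its best transform and
  survives the collinearity filter, as a nutrient representative should.
- **Phytoplankton size fractions** are a softmax composition (closing to
  100% by construction) whose micro/pico scores are tilted in opposite
  directions by a noisy temperature channel: %Pico rises and %Micro falls
  with temperature, and the pair is strongly anticorrelated (|rho| > 0.9),
  exercising the filter. The pico score carries a skewed noise term so the
  more normal member of the pair tends to be retained.
- **Chlorophyll a, bbp470, PAR, MLD, salinity** are built from latitude,
  temperature and nutrient channels with enough independent noise that all
  remaining pairwise |rho| stay below the 0.7 filter threshold.
- **Distance to coast** is the minimum haversine distance (R = 6371 km) to
  a fixed synthetic archipelago. Island vertices are scattered uniformly
  per unit area; a purely meridional coastline would make distance to
  coast a deterministic function of latitude (longitude degrees shrink
  poleward) and thus collinear with temperature, which real coast
  geometries are not.

**Communities.** Every leaf taxon of the registry carries a planted
response family: a combination of covariate response shapes (null, linear,
saturating monotone, unimodal) with amplitudes in log-abundance units per
covariate standard deviation. Four families are planted by default,
differing in the sign and shape of the temperature/oxygen response and in
which secondary covariates (PAR, NO2NO3, MLD, chlorophyll, bbp470,
salinity, distance to coast) they respond to. Within a family, groups share
the response syndrome but differ in amplitude (lognormal jitter, sigma 0.15)
and in curve geometry (per-group tanh steepness, bump width/centre,
linear-curvature mix). Log abundance is the group intercept plus the summed
responses plus Gaussian noise (sigma 0.5); intercepts are calibrated
against the realized signal so that mean group shares hit a target
composition, with copepod leaves summing to the dominance target (default
74% of total abundance).

Amplitudes (0.6-0.85 log units per covariate standard deviation) were
chosen so that every planted term is reliably detected at about 120
stations while the log-additive community stays close to additive after
the cube-root abundance transform used downstream; much larger amplitudes
make the exp/cbrt mismatch reallocate fitted amplitude between correlated
covariates and blur the planted families. In recovery designs (synthetic
flat registries) the group base sizes draw from 600-1500 um, comfortably
above the finest mesh: otherwise the temperature-size rule couples
strongly with mesh retention and convolves a large shared
declining-temperature thinning term into every abundance response. The
recovery experiment also models the planted leaf groups only -- the
total-community rollup is a composite of all four families and has no
planted label.

**Individuals.** Each station x net draw is Poisson in the candidate count
(true abundance x filtered volume), lognormal in individual size around a
group median following the temperature-size rule ln(median ESD) = a - b*T
(default |b| = 0.025 per degC, reversed for the warm-affinity family), and
Bernoulli-thinned by the logistic mesh-retention curve centred on the mesh
size (steepness 5/mesh, so retention at twice the mesh exceeds 0.99).
Ellipse axes are emitted as major = ESD*sqrt(r), minor = ESD/sqrt(r) with
aspect ratio r uniform in [1, 4]; only their product matters downstream.
Poisson counts and lognormal sizes are generator conveniences, not claims
about field data. Filtered volumes (default about 3 m3) are
aliquot-equivalent: they play the role of volume divided by the counted
aliquot fraction, keeping object tables at a tractable size.

**What the generator does not emulate:** seasonality, spatial
autocorrelation beyond the latitude gradients, tow-geometry differences
(only the depth-range label differs between nets), taxonomic
misclassification, and the possibility that real response families are not
discrete. Passing recovery tests therefore shows the pipeline recovers the
structure this generator plants, not that real oceans contain four
families.

## Ingestion and community metrics

ESD is the area-equivalent diameter of the fitted ellipse,
`sqrt(major * minor)` -- the standard ZooScan convention; every size result
depends on this definition. Objects roll up through the nested registry
(36 groups by default: total zooplankton, 8 broad groups, 5 copepod
orders, families, and two "unidentified" buckets), so a parent's count is
the sum over its subtree. Abundance is count / filtered volume; the median
ESD of a station x group x net sample is reported only when at least 20
individuals were measured (even-length medians average the two central
order statistics). A (group, net) enters size-structure modelling when at
least 30 stations meet the 20-individual rule, and abundance modelling
when at least 30 stations record the group at all. Latitudinal composition
summaries use tropical (|lat| <= 30), temperate (30 < |lat| <= 60) and
polar (> 60) bands -- stations exactly on an edge go to the lower band --
and lump taxa under 1% into "other"; unidentified buckets are excluded
from family-level composition.

## Screening

Transform selection offers square root, natural log, log10 and cube root
(no identity option; "cubic" is read as cube root, since a literal cube
worsens the right skew it is meant to fix) and picks the transform with the
highest Shapiro-Wilk p; ln and log10 always tie by affine invariance of W,
and the tie resolves to the earlier entry of the fixed priority list
(sqrt, ln, log10, cbrt). In the pipeline, abundances are cube-root
transformed, median ESD log transformed, nutrients cube-root and
chlorophyll log transformed, matching the transform-selection outcome on
their generated marginals. Stations with zero abundance are excluded from
log-transformed series (count logged).

Spearman correlations use mid-ranks with the t-approximation for p values
(an exact permutation oracle backs this in tests at small n); significance
labels are *** / ** / * / ns at 0.001 / 0.01 / 0.05, on raw p values (no
multiplicity correction across correlation screens). The collinearity
filter resolves |rho| >= 0.7 pairs, largest first, dropping the member
whose best-transform Shapiro-Wilk p is lower (near-ties, delta p < 1e-6,
break on missing-value counts). The temperature-oxygen pair is never
resolved against itself; instead two parallel covariate sets are emitted.
Forced-pair members are also never dropped against third covariates -- an
incidental small-sample rho of 0.7 with, say, a nutrient must not delete
the axis the whole analysis is built around; the third covariate is
dropped instead.

## The additive-model engine

The Gaussian additive model `y = b0 + sum_j f_j(x_j) + e` uses, per term,
a B-spline basis (cubic for k >= 4) on quantile-spaced knots with a
second-difference coefficient penalty. This P-spline construction replaces
thin-plate splines: downstream stages consume only curve shapes, which the
two bases agree on. A sum-to-zero constraint per term is absorbed by
reparameterization (so edf <= k - 1 per term and curves are centred). The
basis dimension follows k = max(3, floor(n / p)) per term, capped at one
less than the number of distinct covariate values. Quantile knots make the
fit equivariant under affine rescaling of any covariate -- which is why the
1-100 range-scaled curve grid loses nothing.

Shrinkage ("extra penalties") gives each term a second penalty: the
projector on the null space of its curvature penalty, with its own
smoothing parameter. A single shared parameter was tried first and rejected:
it couples curvature smoothing to slope shrinkage, visibly biasing smooth
sloped signals (a sine fit at n = 200 inflated from about 13 to about 119
effective degrees of freedom because the restricted likelihood preferred
undersmoothing to slope shrinkage). With both penalties driven to
infinity a term vanishes entirely, which is what makes term removal by the
smoothness selection possible.

Smoothing parameters minimize the profiled Gaussian restricted likelihood

    (n - M) log(RSS + penalty) + log|X'X + S| - log|S|+

coordinate-wise over a 40-point log-spaced grid per penalty (1e-6 to 1e10),
two sweeps, with all grid evaluations for one coordinate batched through a
stacked Cholesky factorization. GCV is available as a cheaper alternative.
A weak tilt of 0.02 likelihood units per decade of lambda is added toward
smoother models: for terms with no signal the restricted likelihood is
near-flat in lambda, and the tilt resolves such plateaus toward removal
(null-response mean total edf about 1.8 instead of 2.2) without moving
sharp interior optima.

Per-term significance is a Wald-type F: the squared norm of the fitted term
values over its effective degrees of freedom, scaled by the residual
variance, referred to an F distribution with (edf, n - total edf) degrees
of freedom. The numerator df is floored at 1 because fractional df under
heavy shrinkage makes vanishing terms look spuriously significant. This
approximation is used for ranking and backward selection; no exact
reference distribution is attempted. Backward selection iteratively refits,
removing the single least significant term with p >= 0.05 until all
remaining terms are significant; removed terms keep zero curves. Curves are
extracted after removal. %Dev is 1 - RSS/TSS (Gaussian deviance), adjusted
R2 uses the effective degrees of freedom. Missing data are handled
complete-case per model.

## Response-shape clustering

Models with %Dev above the threshold (default 0.40; the alternative 0.50
reading for size-structure models is a config value) contribute their
covariate curves as the dimensions of a 100-step multivariate series,
covariate order fixed across the comparison set, absent covariates
zero-filled. The default standardization z-scores each curve and then
rescales it by its amplitude relative to the model's strongest curve,
where a term's amplitude is the standard deviation of its fitted values
over the *observed* covariate values -- its contribution to the response
variation. (The curve's spread over the uniform grid is a poor amplitude
measure: it over-weights the data-sparse extremes of heavy-tailed
covariates and the junk wiggles that live there.) Pure per-curve z-scoring
(the obvious "shapes only" choice, available as `standardize="zscore"`)
was rejected as the default after it amplified barely-wiggling spurious
curves to unit variance, which made the validity indices oversplit planted
families; amplitude weighting keeps the comparison about shape while
weighting each term by how much response it actually carries.
`standardize="raw"` disables standardization.

DTW uses dependent-dimension alignment: one shared warping path with
Euclidean local cost across dimensions, the symmetric step pattern, no
window, no path normalization (all configurable in principle; the
defaults are what the distance matrix module tests). DTW distances may
violate the triangle inequality; nothing downstream assumes it.

PAM runs a greedy BUILD phase then steepest-descent SWAP to a local
optimum, taking the best of 10 restarts (restart 0 from BUILD,
the rest from seeded random medoid sets). On small instances (n <= 8,
k <= 3) the result is verified against exhaustive medoid search. Cluster
number is chosen over k = 2..10 by five indices -- Calinski-Harabasz,
Dunn, mean silhouette (maximized), classic and modified Davies-Bouldin
(minimized; the modified variant is the max-separation DB*) -- each voting
for its best k, plurality deciding, ties going to the smallest k.
Silhouette and Dunn work directly on the distance matrix; the
centroid-based indices use classical (Torgerson) MDS coordinates in
min(n - 1, 5) dimensions, with negative eigenvalues clipped to zero and
counted. The 2-D MDS embedding is the visualization product.

## Cross-model statistics and recovery evaluation

Kruskal-Wallis (tie-corrected, reported with its chi-square reference df)
compares %Dev across nets or across the temperature/oxygen variants, with
Dunn's z tests (tie-corrected variance) and Bonferroni adjustment (capped
at 1) as the post hoc. Cross-net agreement is the per-group Spearman
correlation of station-matched metrics between nets. Recovery against the
synthetic truth reports: the adjusted Rand index between the PAM partition
at the chosen k and the planted family labels; the rate at which the
fitted temperature curve's endpoint difference matches the planted
temperature-direction abundance sign (oxygen-axis responses folded into
the temperature direction with flipped sign; unimodal truths excluded);
and the analogous temperature-size-rule sign recovery on median-ESD
models.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at 120
stations with 24 planted groups (6 per family, one net), the scale at
which every planted term is detectable and a suite run stays comfortably
inside a half-hour on one core: recovery is checked over five seeds in the
tests and one seed in the acceptance script, the null-shrinkage simulation
uses 40 seeds at n = 100, and transform selection uses 100 trials at
n = 200. Dominance and cross-net agreement are measured on a default-
registry transect at the full 168 stations (those stages do not fit
models and are cheap). The covariate correlation structure is measured at
500 stations, where sampling noise on Spearman rho is about 0.02.

## Known limitations

- The REML grid search is robust but not exact: lambdas land on a 40-point
  grid, so effective degrees of freedom can differ from a continuous
  optimizer's by a few percent.
- The F approximation for penalized terms is monotone-consistent for
  ranking but not calibrated in the tails; backward selection inherits
  this.
- The generator's families are discrete and balanced; real communities
  need not cluster cleanly, and the validity-index vote is known to
  fragment when within-family structure is clumpy.
- Cube-root analysis of log-additive abundances is mildly misspecified by
  construction (as it is for any real data); amplitudes are kept moderate
  so the additive approximation holds, and the recovery tests quantify the
  residual distortion.
- No tensor-product smooths, interactions, non-Gaussian families, or
  spatial autocorrelation terms.
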