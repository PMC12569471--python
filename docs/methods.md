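# Methods

This note documents the statistical models implemented in `nestarch`,
the assumptions they make, the tunable parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices taken where the design was genuinely open.

## Trait coding

Five nominal nest traits describe each species: nest type
(cavity/non-cavity), structure (scrape/platform/cup/enclosed), site
(ground/vegetation/cliff/underground after recoding), attachment
(basal/lateral/pensile) and height class (ground/low/medium/high) — 17
states in total.

Nest height enters as the geometric mean √(h_min·h_max) of the recorded
range (metres). A zero minimum annihilates the product, so species with
h_min = 0 are ground-class even when h_max > 0; this is deliberate — a
species recorded nesting at ground level uses the ground. Height cut
points are the 10th and 90th percentiles of the geometric means of the
*non-ground* species only, with linear interpolation between order
statistics (the common statistical default; quantile-type conventions
differ across software and none is stated for this kind of analysis).
Intervals are closed on the right: a height exactly at a cut point falls
in the lower class. Rare site states are merged before ordination (ant
nest → vegetation, water body → ground) because very sparse states
produce unstable ordination axes. Records with missing or invalid fields
are excluded and reported, never imputed: imputation of nominal traits
is high-variance and would contaminate the morphospace.

## Morphospace

For all-nominal data the Gower coefficient reduces to simple matching:
d(i,j) = (number of mismatching traits)/5. The binary cavity trait is
treated as a symmetric nominal variable (a mismatch contributes 1/5 like
any other trait) since both of its states are informative.

Principal coordinates analysis double-centres the squared
dissimilarities, B = −½ J D∘D J, and eigendecomposes B. Axes with
eigenvalue > 1e−8 × λ_max are retained ("non-zero" axes); for t nominal
traits with s total states the positive rank is at most s − t = 12.
Simple-matching dissimilarities are generally non-Euclidean, so negative
eigenvalues occur; no Lingoes/Cailliez correction is applied — negative
eigenvalues are reported in the variance table (which gives shares under
both the positive-sum and absolute-sum denominators) but excluded from
coordinates. Eigenvector signs follow a deterministic convention (the
largest-magnitude loading of each axis is positive) so repeated runs are
byte-identical.

## Phylogenetic covariance and whitening

Under Brownian motion on a rooted tree, cov(y_i, y_j) = depth of
MRCA(i,j) and var(y_i) = root-to-tip depth. GLS operations whiten data
with the symmetric inverse square root P = C^(−1/2) (eigendecomposition).
Zero-length terminal branches are allowed; a hard error is raised only
when C becomes numerically singular (condition number > 1e12), with a
suggested ridge of 1e−10 × trace/n that is off by default. Tip labels are
matched by exact string comparison after whitespace trimming.

## Multivariate phylogenetic regression with RRPP

The model regresses all retained morphospace axes jointly on six
predictors (climate PC1, climate PC2, predator diversity, island
endemism, NDVI, geometric-mean body mass), each scaled and centred
(sd with the n−1 denominator). The binary island flag is scaled like the
continuous predictors; this affects only coefficient scale, never
SS/F/p. The intercept is whitened together with the data (a GLS
intercept). No model simplification is performed: the point of the
analysis is each variable's relative contribution.

Sums of squares are sequential (type I) in formula order; a term's SS is
the reduction in tr(R′R) of whitened residuals between nested models,
and its marginal R² is SS_term/SS_total. F_term = (SS_term/df_term) /
(SS_res/df_res) with the full-model residual in the denominator.
Significance comes from residual randomization (RRPP): rows of the
reduced-model whitened residuals are permuted, reduced-model fitted
values are added back, and F is recomputed; one permutation index set is
shared by all terms within an iteration, and the observed arrangement
counts, so p ∈ [1/(n_perm+1), 1]. The effect size Z is the standard
deviate of log F within its permutation distribution (log guards against
the right skew of F); when the permuted log F has zero spread, Z is
reported as missing rather than infinite. Type III SS and other Z
transforms exist in the literature; sequential SS in formula order is
this package's fixed convention, stated here so results are
interpretable.

Variance inflation factors are computed non-phylogenetically
(VIF_j = 1/(1−R²_j) from OLS of predictor j on the rest) as a screening
diagnostic only.

A closed-form univariate GLS (`gls_univariate`) with parametric t-tests
covers scalar phylogenetic regressions, e.g. validating a predation
proxy against direct predation-rate estimates.

## Regression scores and association classes

For predictor q with coefficient row b (length k = number of axes), the
score of species i is (Y_i − Ȳ)·b/‖b‖. Centring Y makes "score zero =
no association" literally true (the full-sample mean score is 0), and
dividing by ‖b‖ makes scores invariant to the coefficient vector's
scale; neither choice affects the sign-based classes. A state is
strong_positive/negative when *all* of its species score strictly on one
side of zero (an exact zero blocks "strong"), tendency_± when the
[Q1, Q3] interval (linear-interpolation quartiles) lies strictly on one
side, otherwise none.

## Multivariate phylogenetic signal

K_mult = [tr(E′E)/tr(E′C⁻¹E)] ÷ [(tr C − n/(1′C⁻¹1))/(n−1)], where
E = Y − 1â and â is the GLS (phylogenetic) grand mean. K is invariant to
orthogonal rotation of the trait columns and to column shifts, equals
univariate Blomberg's K at k = 1, and equals exactly 1 on star
phylogenies. The permutation test shuffles whole species rows across
tips (preserving within-species trait covariance); the observed
arrangement is iteration 1 of n_perm, so the smallest attainable p is
1/n_perm (0.001 at the default 1000 iterations). The test is defined
against a Brownian-motion null only.

## Phylogenetic logistic regression

Each trait state's 0/1 indicator is modelled with an exactly logistic
mean, P(y_i = 1) = expit(x_i′β), and a working covariance
V = W^(1/2) R(s) W^(1/2), where W = diag(p(1−p)) and
R(s) = I + s(Ĉ − I) mixes the identity with the tree's Brownian
correlation matrix Ĉ (covariance scaled to unit diagonal). The signal
weight s ∈ [0, 1] plays the role of a Pagel's-λ-like parameter on the
latent correlation. β solves a Firth-bias-adjusted quasi-score equation
(hat-value adjustment h(½ − p) generalized through R^(−1/2)); at s = 0 —
and on any star tree, where Ĉ = I exactly — the iteration *is* Firth
penalized logistic regression, which keeps estimates finite under
complete separation. s is chosen by maximizing a REML-type Gaussian
pseudo-likelihood of the Pearson residuals over a coarse grid
(0 … 0.99, listed in `DEFAULT_S_GRID`) with golden-section refinement;
exact ties prefer the smallest s, so structureless data reduce
deterministically to the Firth fit. The compact grid bound (s ≤ 0.99)
avoids the flat-likelihood divergence of an unbounded signal parameter
and is recorded in each fit. Exact likelihood integration over the
latent field is out of scope; this estimator is the quasi-likelihood
approximation family commonly used for phylogenetic binary data. Wald z
and p come from the inverse quasi-information; raw p-values are
reported (with a Holm-adjusted column per predictor, across the 17
models, alongside for convenience).

## Synthetic-data generator

The generator is the package's ground-truth surface:

* **Tree**: birth–death (default pure-birth, rate 1) conditioned on the
  tip count via general-sampling, depth normalized to 1 so that sigmas
  are comparable across runs.
* **Covariates**: NDVI, predator diversity and log body mass are
  Brownian on the tree (sd 1 by default); five climate columns load on
  two latent Brownian factors with iid noise (sd 0.1), so a PCA
  concentrates > 80% of their variance on two axes; the island flag
  thresholds an independent Brownian latent at the 85% quantile
  (≈15% island endemics).
* **Traits**: each trait's liability is Σ_j coupling_j × (standardized
  covariate_j) + Brownian noise (sd 1), discretized at empirical
  quantile cut points chosen to give realistic state frequencies (e.g.
  30% cavity, 35% ground-height). Liability thresholding — rather than
  Mk with covariate-dependent rates — is used because it gives a
  well-defined true effect per covariate for recovery tests. Heights are
  log-normal in the height liability with a seeded min/max spread, so
  the geometric-mean binning is exercised; a small fraction of species
  receives the rare site states that recoding folds back in.

The whole dataset is a pure function of the `SimConfig` (one seed, one
byte-identical dataset). The generator emulates the *statistical
structure* of real comparative data — phylogenetic signal in traits and
covariates, correlated climate variables, a known causal coupling — but
not taxon sampling, empirical trait frequencies, geography or
measurement error; passing tests therefore demonstrate correctness and
calibration of the methods, not conclusions about real birds.

## Problem sizes and calibration checks

The test suite verifies, among others: exact Gower/PCoA oracle
equivalence (30 random fixtures ≤ 50 species); OLS reduction of the
multivariate PGLS on star phylogenies (1e−8); RRPP per-term type-I error
within [0.03, 0.07] under a Brownian null (64 tips, 6 predictors, 12
axes, 199 permutations, 500 replicates); K_mult = 1 exactly on star
trees, mean within [0.9, 1.1] over 200 Brownian simulations on 128 tips,
and univariate equality to an independent scalar implementation
(1e−10); ≥ 80% recovery of a planted NDVI → cavity coupling (liability
effect 3.0, 192 tips, 50 replicates) in both the permutation test and
the association sign; Firth-oracle reduction of the logistic model to
1e−4 on star trees with finite estimates under separation; and
byte-identical outputs across reruns with the same seed. The acceptance
script uses a 512-species study with 999/1000 permutation iterations.
These sizes were chosen to make Monte-Carlo error small relative to the
asserted bands while keeping the default run quick on a single CPU.

## Known limitations

* Brownian motion only: no Pagel's λ or OU optimization in the
  multivariate model, and the signal test is defined only against a BM
  null.
* Sequential SS means term order matters; the printed formula order is
  part of the model definition.
* The logistic estimator is a quasi-likelihood approximation; its signal
  weight s is comparable across fits but is not a consistently estimated
  evolutionary parameter, and agreement with other phylogenetic logistic
  implementations is expected in sign and significance rather than to
  the digit.
* Negative PCoA eigenvalues are dropped from coordinates; strongly
  non-Euclidean dissimilarity structures lose that part of the
  variation (it is reported in the variance table).
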