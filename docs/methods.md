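# Methods

## Generative model

`bwasim.synthpop` draws populations from a latent factor model with
explicit measurement reliability. For participant i and feature j:

    g_i ~ N(0, I_K)                                   K = 15 factors
    t_i = w·g_i + e_i,            Var(t) = 1          stable cognition trait
    y_i = √rel_y · t_i + √(1−rel_y) · η_i             observed composite
    u_ij = λ_j·g_i + ε_ij,        Var(u_j) = 1        stable feature trait
    x_ij = √rel_x · u_ij + √(1−rel_x) · ξ_ij          observed feature

All observed variables have unit variance, and the observed-scale true
effect of feature j on the composite is the attenuated latent one:

    ρ_j = (λ_j·w) · √(rel_x · rel_y)

Defaults: n = 3,928 participants; p = 7,140 features (the edge count of
120 synthetic ROIs; the full-scale 77,421-edge layout is one parameter
away); ‖w‖ = 0.40 (the brain-explained share of the trait's standard
deviation); rel_x = 0.48 (test–retest reliability of connectivity edges
in the reference child cohort); rel_y = 0.90 (cognition composite) and
0.94 (psychopathology composite, matching questionnaire reliability
figures). The psychopathology trait is independent of the brain factors
by default, mirroring the weaker associations observed for questionnaire
phenotypes. Subscale batteries are noisy indicators of their trait
(loadings 0.75 for the 10 cognition subscales, 0.65 for the 20
psychopathology subscales) and exist mainly to feed CCA.

### Effect-spectrum calibration

The published quantities are features of the *observed* full-sample
spectrum — median |r| ≈ 0.01, 99th percentile ≈ 0.06, maximum ≈ 0.16 —
not of any generative law. We therefore specify effects on the observed
scale and derive loadings by disattenuation. The spectrum is a
two-component mixture: a fraction π₀ = 0.90 of features is exactly null;
non-null magnitudes are half-normal. The analytic scale constant
σ = 0.06/Φ⁻¹(0.95) puts the 0.90 quantile of non-null magnitudes — the
99th percentile over all features — at 0.06; each realization is
rescaled to hit that anchor exactly and its largest magnitude is pinned
to 0.16. `scripts/calibrate_spectrum.py` validates the anchors and
parameter recovery (sample r within 0.01 of ρ_j at n = 100,000) by Monte
Carlo. The median |r| then emerges rather than being imposed: under a
90%-null spectrum it sits at the null median 0.6745/√(n−3) ≈ 0.011 at
the default n, matching the published value.

Signs of non-null effects are random; loadings point along w
("aligned" rule), making the brain signal effectively rank one. This is
the simplest structure consistent with the published anchors, which
constrain only the univariate spectrum.

### Families, sites, split

A `family_fraction` of 0.20 places 20% of participants into two-person
family clusters (labels only; members are statistically independent,
since the analyses under study only require that splits respect
clusters). Sites are constant (single-site emulation). The
discovery/replication split shuffles clusters with a seeded generator,
sorts by size (stable) and assigns greedily to the smaller half: no
family is ever split, and half sizes differ by at most one whenever
cluster sizes permit (defaults: 1,964 + 1,964). The nine-covariate
matching of the reference cohort's split is reduced to family
preservation + size balance; the other covariates have no synthetic
counterpart.

### Seeding

One master seed; every random component (effect spectrum, factor scores,
feature noise, phenotype noise, split, each resampling bin, each
multivariate stage) derives its own `numpy` generator from
`default_rng([stream_id, seed])` with fixed stream identifiers, so
components are independently reproducible and `true_effect_spectrum` is
a deterministic function of the spec alone.

## Univariate engine

`mass_correlate` computes Pearson r of every feature against a phenotype
and two-tailed p-values from t = r√((n−2)/(1−r²)) on n−2 df (a
permutation option is unnecessary at the sample sizes studied; the t
reference is exact under bivariate normality). Constant features yield a
NaN sentinel, never a silent zero; a constant phenotype is an error.

`resample_bins` draws participants **with replacement** at every bin of
the 16-interval log-spaced grid (n = 25 … population size) — including
the last bin, which is therefore a bootstrap rather than the identity.
Degenerate draws (constant phenotype at tiny n) are recorded as missing,
not redrawn, to avoid biasing the bootstrap distribution. Estimates are
stored as (feature × bin × iteration) arrays; the pipeline stores them
in float32 to keep the desk-scale run (7,140 features × 16 bins × 200
iterations) under 1.5 GB.

Note a finite-population subtlety the tests respect: bootstrapping a bin
of size n from a finite realization of size N inflates estimator
variance by roughly 1 + n/N, so calibration checks (e.g. type-I rates)
use N ≫ n.

## Error calculus

Ground truth is the realized full-sample result (mask per α, strictly
nested across the default grid 0.05 … 10⁻⁷). Per (bin, α), pooled over
eligible (feature, iteration) cells:

* **FN** — among full-sample-significant features, fraction of
  non-significant subsample cells; **power** = 1 − FN identically;
* **FP** — among full-sample-non-significant features, fraction
  significant;
* **sign** — among subsample-significant cells, fraction with sign
  opposite to the full sample;
* **inflation** — among subsample-significant, same-sign cells of
  full-sample-significant features, fraction with |r_sub|/|r_full| − 1
  above 0.5/1.0/2.0. Opposite-sign significant cells are counted as sign
  errors, not inflation; subsample-significant cells of full-sample
  non-significant features are excluded from inflation denominators.

Empty cells are reported as missing (NaN), never zero.

`replication_rate` bootstraps discovery draws at each bin, applies the
same α in discovery and the full replication half, and reports both the
sign-matched rate ("same sign, both significant" — the default) and the
significance-only rate. Because the generator also records true effects,
error rates against ρ_j are available — something the reference study's
real data could not provide.

### A known deviation at large bins

Tightening α lowers replication at typical BWAS sizes (n < 500), as
published. At large bins the pattern inverts here: the calibration pins
the *true* maximum effect at ρ = 0.16, whose replication-half
(n = 1,964) power at α = 10⁻⁷ is ≈ 0.97, so the strict-α discovery pool
— dominated by that feature — replicates more often than the lenient
pool, which is diluted by null discoveries replicating at ≈ α/2. In real
data the printed maximum was itself a selection-inflated realization
from millions of associations, with lower true replication power. The
corresponding all-bins test is kept and fails by design; see the test
docstring.

## Analytic power

Fisher z approximation: power = Φ(|atanh ρ|·√(n−3) − z₁₋α/₂) +
Φ(−|atanh ρ|·√(n−3) − z₁₋α/₂). `required_n` inverts it by bisection
(floor-clamped at n = 4, overflow above a configurable cap). An
`exact_t` variant derives the rejection region from the exact null t
distribution for n below ~30, where the normal approximation degrades.
"Bonferroni" defaults to α/77,421 (the full edge count); the rounded
10⁻⁷ used in the reference analyses is available as an explicit
threshold. Under the defaults: n = 2,179 (≈ 2,200) for ρ = 0.06 at
α = 0.05 and 80% power; ≈ 9,400 under the Bonferroni correction.

## Multivariate models

Training always happens on (bootstrap subsamples of) the discovery half;
evaluation always on the untouched, full replication half — an
asymmetric design (documented because it differs from symmetric
split-half testing). Features are standardized and PCA-reduced with
training statistics only; retained components are the smallest prefix
reaching the variance threshold (50% for SVR, 20% for CCA), capped below
the training rank, with a deterministic sign convention
(largest-magnitude loading element positive).

SVR is linear ε-insensitive with fixed hyperparameters C = 1, ε = 0.1
(tuning was reported not to change out-of-sample estimates appreciably;
an inner 10-fold grid search sits behind `tune_hyperparameters`). The
default solver is liblinear (`LinearSVR`), which optimizes the same
objective as the libsvm dual but runs orders of magnitude faster at
n ≈ 10³; `svr_solver="libsvm"` selects the exact dual solver (the two
agree to ~1e-3 in r_pred on the default population). Out-of-sample
strength is r_pred = corr(predicted, observed) on the replication half.

CCA's first canonical pair is solved by the whitened-SVD (generalized
eigenvalue) formulation on PCA-reduced brain data against the raw
battery, with no additional regularization (PCA handles conditioning;
rank-deficient sides are rejected). r_CV1 is the correlation of
replication-half brain and behaviour scores under training weights,
oriented so the in-sample canonical correlation is positive.

Permutation nulls permute phenotype rows within the discovery set only
(brain matrix fixed; family structure ignored — no exchangeability
blocks were described for the reference analyses), retrain per
permutation, and take the 99.5th percentile of the null out-of-sample
statistic (upper edge of the two-sided 99% band; the 99th percentile is
available via the `quantile` argument for the one-sided reading).

A univariate feature-ranking variant (top-k training-set correlations
instead of PCA) is provided; it underperforms the PCA route
out-of-sample, as published.

## What the generator does and does not emulate

It reproduces: the univariate observed-effect spectrum and its anchors,
reliability attenuation, family-cluster split constraints, the 1/√n
decay of sampling variability, type-I calibration, the power/replication
calculus, and the in-sample vs out-of-sample optimism of multivariate
models. It does **not** emulate: spatial correlation among features
(features are conditionally independent given the factors, so PCA at a
fixed variance threshold retains far more noise components than on real
connectivity data, and out-of-sample multivariate associations plateau
near 0.2 rather than ~0.4); multi-site scanner structure; covariate
confounding; familial phenotype correlation; non-Gaussian phenotype
distributions. Passing tests therefore certify the statistical
machinery and the published directional phenomena, not point predictions
for real cohorts.

## Problem sizes

The package's own default scales keep everything on a single CPU: desk
preset B = 200 bootstrap iterations for univariate resampling (1,000 at
full scale), 20 bootstraps and 200 permutations for multivariate curves
(100 and 1,000 at full scale), and the 7,140-feature population (the
77,421-edge layout is a config change). Tests use further-reduced sizes
chosen so Monte Carlo tolerances (stated per test) comfortably cover the
run-to-run variation of the seeded generators.
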