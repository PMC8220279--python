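# Methods

This note documents the models implemented in `eggsig`, the choices made where
the underlying methodology leaves room, and what the synthetic-data generator
does and does not emulate.

## Phenotype metrics

**Cone catches.** For a reflectance spectrum `R(λ)`, receptor sensitivity
`S_i(λ)` and illuminant `I(λ)`, the photon catch is `q_i = ∫ R S_i I dλ`
(trapezoidal rule on the spectrum's grid; receptor curves are interpolated
onto it, zero outside their support). The four single-cone catches are divided
by their sum, removing absolute brightness; the double-cone catch is kept raw
as luminance. The shipped receptor set is an **idealized** violet-sensitive
passerine tetrachromat — Gaussian sensitivities peaking at 370/445/508/565 nm
with a broad double cone at 560 nm and a flat illuminant. It is a synthetic
fixture for exercising the machinery, not a measured sensitivity set for any
species; measured curves and illuminants can be supplied as `ReceptorSet`
fields. Sum-standardized catches are invariant to any positive scaling of the
spectrum.

**Granularity analysis.** The masked, mean-centred image is decomposed in the
frequency domain with differences of ideal isotropic low-pass filters: the
band at scale `s_i` (an octave series 2, 4, 8, … px, up to half the shorter
mask dimension) passes spatial periods in `[s_i, s_{i+1})`. Band energy is the
sum of squared filtered pixel values inside the mask. Ideal (hard-edged)
filters make band energies exactly disjoint on periodic images; masking leaks
a few percent of energy across band boundaries, which is why the
Parseval-style bound `Σ band energy ≤ total masked variance × pixels` is
asserted only within a 5% tolerance. The filter kernel is configurable; soft
(e.g. Gaussian ring) kernels trade exact band separation for less ringing.

**Pattern metrics.** Marking size = scale of the maximum-energy band;
dominance = its share of total band energy; contrast = total band energy per
masked pixel ("pattern energy"). Coverage requires a segmentation that the
source methodology does not pin down; the choice here is: background level =
intensity-histogram mode inside the mask, marked pixel = deviation from the
mode beyond `k·MAD` with `k = 3` (for a noise-free background, MAD = 0, any
deviation beyond half a grayscale bin counts). Dispersion is the normalized
absolute coverage difference between the two halves along the mask's principal
axis, in [0, 1], with a fallback to the image vertical axis (and a logged
warning) when the mask is rotation-symmetric. An immaculate egg (zero
coverage) forces all five pattern metrics to 0.

**Standardization.** Luminance and the five pattern metrics are divided by
their within-family maximum, so each attribute attains 1 at its family
maximum and all ten metrics share a comparable scale. Cone catches are already
sum-standardized and pass through untouched.

## Signature measures

**Consistency.** Clutches of one egg are removed (within-clutch distance is
undefined), every remaining clutch is reduced to two randomly selected eggs,
and the species index is 1 minus the mean within-pair Euclidean distance in
the 10-metric space. The index is ≤ 1 with equality iff all pairs are
identical; it is deliberately **not clamped below** — distances above 1 are
geometrically possible in 10 dimensions, and clamping would hide them.

**Entropy decomposition.** With one randomly selected egg per clutch (avoiding
pseudoreplication), the sample covariance Σ (ddof = 1) is split as

    entropy      H = ½ ln((2πe)^k det Σ)
    variance     A = Σᵢ ½ ln(2πe σᵢ²)        ("absolute distinctiveness")
    correlation  C = ½ ln det R              ("combinatorial distinctiveness")

with `H = A + C` exactly (since `det Σ = det R·Πσᵢ²`) and `C ≤ 0` by
Hadamard's inequality, `C = 0` iff R = I. All logarithms are natural, so every
entropy is in **nats**; the base only rescales values and affects no
comparison. Two degeneracies need decisions:

- *Sum-to-one cone catches* make the 10-metric covariance singular. The
  linearly redundant channel (`q_lw` by default) is dropped before computing
  `det R`; the variance component still sums over all metrics with non-zero
  variance. Alternatives (pseudo-determinant, ridge on R) are possible via the
  `drop_redundant` argument.
- *Zero-variance metrics* (species laying only immaculate eggs) make entropy
  undefined on a comparable scale. These return an `undefined_entropy` flag
  and missing values rather than raising, so whole-dataset runs simply skip
  such species; consistency and the MDPS measures remain defined for them.

A decomposition needs at least k + 2 one-egg-per-clutch rows; species sampled
more thinly are flagged undefined as well.

**MDPS distinctiveness** is the mean pairwise Euclidean distance among the
one-egg-per-clutch representatives — conceptually parallel to the variance
component, and empirically rank-correlated with it on synthetic species
varying in total between-clutch variance.

## Comparative models

Statuses are dummy-coded with **unparasitized as the reference level**, so an
interaction coefficient `predictor × status[parasitized]` equals the
parasitized-group slope minus the unparasitized-group slope; in a fully
interacted model (no shared covariates) this identity is exact against
separate group fits.

- OLS/WLS fits use classical standard errors and two-sided t-tests
  (statsmodels under the hood). Rank-deficient designs raise with the names of
  collinear columns.
- Cook's distance uses the hat-matrix formula `D_i = r_i² h_ii/(p s² (1−h_ii)²)`
  (computed on the whitened problem for weighted fits); observations with
  `D > 4/n` are flagged and the top 2 are dropped in the outlier-excluded
  variant. Both the threshold and the cap are configurable — influence
  screens have no canonical cutoff.
- Pagel's λ scales the off-diagonal of the Brownian covariance (shared
  root-to-tip branch length). λ is estimated by profile maximum likelihood on
  [0, 1]: a 21-point grid locates the basin, a bounded scalar search refines
  it to 1e-8, and both boundaries are re-checked. The significance test
  compares `2·ΔlogL` against χ²₁; at the λ̂ = 0 boundary this reference is
  conservative (the nominal 5% test rejects less often), which the type-I
  error check confirms. On a star tree the likelihood is flat in λ and the
  fit is flagged `unidentifiable` with p = 1.
- PGLS estimates λ by ML jointly with the coefficients (per model, not fixed
  from a univariate trait), then reports GLS coefficients with
  `σ̂² = rᵀV⁻¹r/(n−p)` standard errors. Phylogenetic runs exclude the family
  factor: the phylogeny already separates the two families, and the factor
  would be near-collinear with the tree structure.
- `lambda_over_trees` summarizes λ̂ and the LR p-value across a set of
  candidate trees as mean ± s.d. and a p range; per-tree failures are
  recorded, not fatal.
- `run_full_battery` executes the model grid — each defence ~ status + family
  + sample size; consistency ~ each distinctiveness component, additive and
  with a status interaction plus group-wise simple slopes — across variants:
  baseline, restrictive status, rank-transformed response (average ranks),
  sample-size weights (covariate dropped), species resampled to 5 clutches
  (only consistency is recomputed at the reduced size — five clutches cannot
  support a 10-metric covariance, so distinctiveness keeps full-sample
  values, and the sample-size covariate is dropped), Cook's-distance
  exclusions, and PGLS. Failures (e.g. a two-species group against four
  parameters under the restrictive status) are recorded in the `note` column
  and the run continues.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of a two-family egg collection: 11 + 14
species, ~15–60 clutches per species (≈800–1000 clutches in total), clutch
sizes 1–5 with mean ≈ 2.4 eggs and ≈13% singletons, 60% of species parasitized
with clutch-level Bernoulli parasitism at rates drawn from 2–43%, a few
unparasitized species carrying elsewhere-in-range parasitism records, and
three immaculate species in the second family. Egg phenotypes are hierarchical
Gaussians: clutch mean ~ N(species mean, Σ_b), egg ~ N(clutch mean, Σ_w), with
Σ_b standard deviations 0.08–0.20 and Σ_w 0.02–0.06 per metric (eggs of one
female resemble each other far more than clutches resemble each other) and
random full-rank correlation structures. Where the emulated study reports no
value (clutch-size distribution, covariance magnitudes), the defaults above
are fixed, field-plausible choices — configurable, not inferred.

By default metrics are **unconstrained Gaussians**, keeping (Σ_b, Σ_w) exact
as recovery ground truth; `clip_to_valid_ranges` optionally renormalizes cone
catches to the simplex and clips bounded metrics to [0, 1] for end-to-end
realism. Consequences: passing tests demonstrate that the estimators recover
known moments, flags and slopes under a correctly specified hierarchical
Gaussian model — they do not show robustness to the skewness, boundary
effects, measurement error or phylogenetic non-independence of real egg data.

Trees are pure-birth (Yule) simulations, exactly ultrametric. Trait vectors
with known λ are multivariate-normal draws from the λ-scaled Brownian
covariance. Egg images place non-overlapping circular spots on an elliptical
mask until a target coverage is reached, with a polar-bias parameter giving
the probability a spot falls in the blunt half (at bias 0 or 1 the whole disk
is constrained to the chosen half, so the extreme is exact). Spectra are
baselines plus Gaussian bumps, squashed through a logistic map only if they
would leave [0, 1].

The **strategy-blocking scenario** generator operates at the species level:
`consistency = intercept + slope(status)·combinatorial + ε`, with default
slopes −0.18 (parasitized) and −0.03 (unparasitized), predictor s.d. 0.5 nats
and residual s.d. 0.12, chosen so group-slope standard errors at the default
25-species sample are ≈ 0.07 — the precision regime the comparative analysis
is designed for. It is generated at the species level deliberately: the
egg-level generator has no closed-form mapping from (Σ_b, Σ_w) to the
species-level consistency–distinctiveness slope, and recovery experiments need
exact generative truth.

Every generator draws from a named substream spawned from one global seed
(CRC-32 of the component name into the seed sequence's spawn key), so adding a
generator never perturbs existing outputs, and each stage of a run is
independently reproducible from the manifest.

## Numerical notes

- PSD factors for simulation use the symmetric eigendecomposition with
  negative round-off eigenvalues clamped to zero, so singular covariances
  (e.g. Σ_w = 0) reproduce exactly rather than up to jitter.
- `gaussian_entropy` rejects non-positive-definite input, naming the offending
  eigenvalue; the log-determinant is computed from eigenvalues (entropy) or
  `slogdet` (correlation component).
- Cook's distance returns exact zeros for perfect fits (residual round-off
  over variance round-off is otherwise unstable).
- Problem sizes in the test suite and acceptance script (e.g. 200-tip trees
  with 50 replicates for λ recovery, 200 null replicates for the LR test,
  100 scenario replicates for slope recovery, 5000-draw plug-in checks) are
  chosen so Monte-Carlo standard errors sit well inside the asserted bands.

## Known limitations

- The Gaussian plug-in is the only entropy estimator (no k-NN estimators);
  small-sample bias of the log-determinant is visible below ~50 clutches.
- The receptor set is idealized; no discrimination (JND) modelling.
- The granularity variant (kernel, normalization) follows the common
  octave-bandpass convention but is one of several in use; it is configurable
  rather than asserted as canonical.
- PGLS assumes the candidate trees are correct and ultrametric;
  non-ultrametric trees are accepted with a warning.
- The consistency index can in principle go below 0 for extremely dissimilar
  within-clutch eggs; it is reported unclamped.
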