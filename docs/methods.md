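# Methods

## The model

A test measures K binary attributes (skills). The Q-matrix `Q` (I items ×
K attributes) records which attributes each item requires; a respondent's
profile `α ∈ {0,1}^K` records which attributes they have mastered. Given a
latent response `Ψ ∈ [0, 1]` summarising how far the respondent's mastery
satisfies the item's requirements, the correct-response probability is

    P(y = 1) = g + (1 − s − g) Ψ,

with guessing parameter `g` (success probability at Ψ = 0) and slip
parameter `s` (failure probability at Ψ = 1), under the monotonicity
restriction `g < 1 − s`.

Classical condensation rules define Ψ from the required attributes:

* **conjunctive** (DINA): Ψ = 1 iff *all* required attributes are mastered;
* **disjunctive** (DINO): Ψ = 1 iff *any* required attribute is mastered;
* **ratio** (DINR): Ψ = fraction of required attributes mastered.

The mixed-rule model (DINMix) replaces the forced choice of one rule by a
per-item convex combination

    Ψ_i = τ_i1 ω_conj + τ_i2 ω_disj + τ_i3 ω_ratio,

with mixing proportions `τ_i` on the 3-simplex. Setting τ at a vertex
recovers DINA, DINO or DINR exactly. For an item requiring a single
attribute all rules coincide, so τ is pinned at (1, 0, 0) at construction;
this also removes a spurious degree of freedom from estimation. Expressed
in the saturated (GDINA-style) parameterisation, a multidimensional
mixed-rule item generates all `2^{K*}` reduced-pattern probabilities from
just four free numbers (g, s, τ₁, τ₂); the package realises this map by
enumeration (`pattern_probabilities`) rather than by a closed-form
coefficient table, which keeps one code path for all six supported models.

Comparison models: the additive CDM (ACDM) with identity link (intercept
plus per-attribute main effects, nonnegative, all implied pattern
probabilities in [0, 1]) and the saturated GDINA (a free probability per
reduced pattern).

### Identification caveats baked into the code

* For an item requiring exactly **two** attributes, both single-mastery
  patterns share the same latent response under every rule, so the
  likelihood depends on τ only through `u = τ₂ + τ₃/2`: the posterior is
  exactly flat along a line segment of the simplex. The sampler includes
  an exact Gibbs draw along that segment (uniform under the flat Dirichlet
  prior); reported posterior means of τ for such items reflect the prior
  geometry along the ridge, which is why mixing-proportion recovery is
  intrinsically worse for two-attribute items.
* The unconstrained saturated model has an exact reflection symmetry per
  attribute (invert the mastery coding and swap the pattern probabilities
  of that attribute's unidimensional items). GDINA fits therefore
  order-constrain unidimensional items (mastery probability above
  non-mastery, via truncated conjugate draws), and chains start from a
  noisy monotone ramp so they do not seed spurious non-monotone modes.
  ACDM fits require nonnegative main effects, which breaks the same
  symmetry.

## Estimation

Bayesian estimation by an explicit Metropolis-within-Gibbs sampler
(`dinmix.mcmc`). State: per-person latent class (one of 2^K profiles),
class-proportion vector π over the 2^K profiles (a saturated,
"unstructured" latent structural model), and item parameters.

Priors are deliberately flat: uniform on (g, s) truncated to `g < 1 − s`;
Dirichlet(1, 1, 1) on τ; Dirichlet(1, …, 1) on π; Beta(1, 1) on saturated
pattern probabilities; uniform on the ACDM constraint polytope. Flat
priors keep posterior means comparable to likelihood-based fits and add no
information the designs do not state.

One sweep:

1. **Collapsed item/π moves** (guessing-slip family only). Item parameters
   and π are updated by Metropolis against the likelihood with the latent
   classes summed out. Purely conditional updates mix slowly because the
   conditional posterior given sampled classes is far narrower than the
   marginal; the collapsed moves remove that bottleneck. Proposals mix
   random walks with *fitted independence proposals*: during burn-in each
   chain fits per-item Gaussians on transformed scales (logit g, logit s,
   additive-log-ratio τ, and a joint 4-dimensional version capturing the
   within-item correlation between noise and mixing levels) plus a
   moment-matched Dirichlet for τ, in two stages (a provisional fit
   halfway through burn-in already speeds mixing, so the final fit comes
   from a better-mixed chain); the fits are frozen at the end of burn-in,
   so the post-burn-in kernel is a fixed, valid Metropolis–Hastings
   kernel. π gets Dirichlet-proposal Metropolis moves plus
   attribute-prevalence "tilt" moves (multiplicative reweighting of the
   classes mastering one attribute — a one-dimensional move along the
   slowly mixing direction that trades prevalence against guessing/slip
   levels; the simplex-tilt Jacobian is ∏w / S^C). The implementation
   aggregates per-person class weights over each item's reduced patterns,
   so a proposal costs two (N × R) products, R ≤ 2^{max K*}.
2. **Classes**: each person's profile is drawn from its exact conditional
   over all 2^K classes (Gumbel-max categorical sampling, vectorised).
3. **π**: conjugate Dirichlet draw given class counts.
4. **Conditional item updates**: random-walk Metropolis given the sampled
   classes (all items vectorised); exact conjugate Beta draws for GDINA;
   blocked random walk with polytope rejection for ACDM; the exact
   two-attribute τ ridge draw.

Random-walk scales adapt toward ~30% acceptance (within the accepted
20–45% band) during burn-in with a diminishing Robbins–Monro step and are
frozen afterwards. Defaults follow the study protocol: 2 chains × 10,000
iterations, 5,000 burn-in, no thinning.

Point estimates: EAP (posterior mean) for item parameters; attribute
estimates threshold the marginal posterior mastery probability at 0.5
(ties count as mastery — a documented, arbitrary but fixed rule); modal
profiles take each person's most frequent sampled class (smallest class
index on ties).

Convergence is diagnosed with the split-chain potential scale reduction
factor (PSRF): each chain is halved, and the usual between/within variance
ratio is computed over the half-chains, so within-chain drift also
inflates the statistic. The package targets max PSRF < 1.01 over item
parameters at the default run length.

## Model comparison

* **DIC** = D̄ + pD with pD = D̄ − D(θ̂). The deviance is evaluated
  *conditional on the sampled latent classes per draw* (the convention of
  general-purpose Gibbs software); the plug-in deviance uses
  posterior-mean item parameters with per-person modal profiles. The
  conditional and class-marginalised deviances differ; the conditional
  convention is used throughout and stated here because published numbers
  depend on it.
* **−2LCPO**: the conditional predictive ordinate of each response is the
  harmonic mean of its per-draw Bernoulli likelihoods, accumulated
  stably in log space (a running log-sum-exp of negative log-likelihoods);
  item-level −2LCPO sums over persons, test-level over items (additive by
  construction). Underflowing CPOs are counted and reported, not fatal.

Smaller DIC / −2LCPO indicates better fit.

## Rule identification

From the posterior mean τ̂ of a fitted mixed-rule item: τ̂₁ > 0.9 →
conjunctive; τ̂₂ > 0.9 → disjunctive; else if τ̂₃ is strictly largest →
ratio/compensatory; anything else → coexisting rules (a flag for item
revision). No reliable single cut-point exists for τ₃ — its posterior
mass rarely concentrates near 1 even under a true ratio rule, because τ₃
absorbs the estimation error of both other components — hence the
strict-majority rule. The 0.9 threshold is configurable; it must exceed
1/3, below which a "dominant" component need not even be the largest.
`classify_items` + `revision_report` compare verdicts against
expert-expected rules and count mismatches.

## Synthetic data

The generator reproduces two study designs.

**Recovery design** (factorial): N ∈ {500, 1000} persons, I ∈ {15, 30}
items, K = 5 attributes. Item quality: (logit g, logit s) bivariate normal
with means −2.197 (higher quality, mean probability ≈ 0.1) or −1.386
(lower, ≈ 0.2), unit variances, correlation −0.6; pairs violating
g < 1 − s are redrawn wholesale, which preserves the marginal shape.
Mixing proportions in fixed blocks: the first I/3 items are unidimensional
at (1, 0, 0); the rest are (1/3, 1/3, 1/3) under uniform mixing, or three
skew blocks (0.6, 0.2, 0.2) / (0.2, 0.6, 0.2) / (0.2, 0.2, 0.6) with
boundaries at 8I/15 and 11I/15. Attribute profiles are either uniform over
all 32 patterns ("unstructured") or thresholded at zero from a latent
multivariate normal with pairwise correlation 0.6 ("mvn"; marginal mastery
0.5, tetrachoric correlation ≈ 0.6). Responses are Bernoulli draws from
the mixed-rule probabilities.

**Model-comparison design**: N = 1000, I = 30, K = 5, unstructured
profiles, *fixed* item parameters with all correct-response probabilities
spanning exactly [0.1, 0.9]: g = s = 0.1 for the deterministic-input
models; ACDM intercept 0.1 with mains (0.5, 0.3) / (0.35, 0.25, 0.2) for
two-/three-dimensional items; GDINA intercept 0.1 with mains (0.35, 0.25)
and interaction 0.2, or mains (0.15, 0.10, 0.05), two-way interactions
(0.05, 0.10, 0.15) and three-way 0.20. Six situations: one per generating
model (conjunctive, disjunctive, ratio, compensatory, fuzzily/saturated)
plus a per-item allocation ("separately": items 1–10 unidimensional DINA,
then four-item blocks of DINA, DINO, DINR, ACDM, GDINA sharing the same
q-vectors, so only the generating model differs between blocks).

The shipped Q-matrices are canonical constructions satisfying every
stated design constraint: identity blocks (one for the recovery design,
two stacked for the comparison design), a unidimensional prefix (I/3 or
10 items), every attribute measured at least three times, and the
remainder cycling two- and three-dimensional q-vectors. The original
figures specifying exact Q-matrix cells are not machine-readable; any
Q-matrix meeting these constraints satisfies the same generic
identifiability conditions, and no published number depends on the exact
cells.

Seeding: one master seed deterministically spawns per-stage substreams
(items / profiles / responses), so any replication is reproducible in
isolation.

### What the generator does not emulate

Real assessments bring misspecified Q-matrices, attribute hierarchies,
within-item dependence between g and s, polytomous responses, and
respondent heterogeneity beyond the latent class structure. None of these
are generated, so passing recovery tests demonstrates internal
consistency of model + sampler under the model's own assumptions, not
robustness on real data.

## Numerical choices

* Bernoulli probabilities are clipped to [1e−12, 1 − 1e−12] before logs;
  additive-model parameters may legitimately sit on the 0/1 boundary
  during sampling.
* Simplex inputs are validated to |Στ − 1| ≤ 1e−10.
* Reduced patterns enumerate the required attributes in binary order with
  the *first required attribute as the least significant bit*; this
  convention is used by `pattern_probabilities`, the class/pattern maps in
  the sampler, and the full-profile enumeration `all_profiles`.
* PSRF of exactly constant identical chains is reported as 1.0; disjoint
  constant chains as +inf.

## Problem sizes used by the checked examples

The test suite reruns the studies at reduced scale, chosen to exercise
every claim while keeping a laptop-class run practical: the recovery
condition (N = 500, I = 15, higher quality, uniform mixing, unstructured)
with 5 replications and 2 chains × 4,000 iterations (2,000 burn-in); the
five pure comparison situations with 3 replications at N = 500 and
2 × 1,000 iterations; and the per-item allocation situation at N = 1000
with all six models fitted once (2 × 1,200–2,000 iterations) plus two
further mixture fits so the rule-identification check uses
replication-averaged mixing-proportion estimates, mirroring how the full
study reports them. Tolerances widen accordingly: recovery RMSE bounds of
0.08 (g, s) and 0.15 (τ₁, τ₂), and a profile-classification band of 0.05
around the known-truth reference classifier. The acceptance script runs
the full protocol (2 × 10,000 iterations) for its convergence figure.

## Known limitations

* Maximum-likelihood/EM estimation is not provided; estimation is MCMC
  only.
* The latent structural model is always the saturated class-proportion
  vector; structured alternatives (higher-order traits, hierarchies) are
  out of scope.
* Mixing-proportion estimates of two-attribute items are identified only
  up to the ridge described above.
* DIC uses the conditional-deviance convention; do not compare its values
  against implementations that marginalise the classes.
* Dichotomous items and binary attributes only.
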