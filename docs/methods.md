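# Methods

## Model

panelmix fits finite mixtures for categorical items. The cross-sectional
model (LCA) assigns each respondent to one of S latent classes with
prevalences γ and, conditional on class, draws the J items independently
with category probabilities ρ[s, j, ·]. The longitudinal model (LTA) places
a first-order Markov chain on statuses: first-occasion prevalences δ,
transition matrices τ_t between adjacent occasions, and the same
conditional-independence measurement model at every occasion. Latent
statuses are nominal; any ordering in the output is a reporting convention
(descending first-occasion prevalence), not a model assumption.

Estimation is maximum likelihood by EM. The LTA E-step runs scaled
forward–backward recursions over statuses, one pass per *distinct observed
response pattern* weighted by its frequency — with six binary items over
three occasions the complete table has 262,144 cells but a realistic sample
occupies only a few hundred to a few thousand distinct patterns, so pooling
by pattern dominates per-respondent passes. Brute-force enumeration of the
S^T status sequences exists only in the test suite, as an independent
oracle; the production path never enumerates.

### Missing data

A missing item contributes no emission factor; a fully missing occasion
contributes emission probability 1 at every status, which keeps the chain
intact across attrition gaps. This is the full-information MAR treatment:
respondents who drop out after wave 1 still inform δ, ρ at wave 1 and, via
the chain prior, the transition structure. Respondents with *no* observed
item anywhere are dropped from the pattern table (counted in
`n_dropped`); respondents with missing covariate values are excluded
listwise from covariate models only, with a logged count.

The saturated reference for G² is stratified by missingness pattern:
within each stratum the observed sub-patterns get their empirical
proportions. Because the model's marginal probabilities also normalize
within a stratum, G² stays nonnegative and is comparable across nested
fits on the same table. This choice can differ from other programs'
internals in the presence of missing data; the identities AIC − G² = 2P
and CAIC − BIC = P are unaffected.

### Effective sample size

The N used in BIC/CAIC/ABIC is the number of respondents contributing any
observed data to the fitted table, and is always reported alongside the
criteria (`N_effective`). Published analyses rarely state their analyzed N
per wave, so BIC-family values are only meaningful relative to one
another within a run; AIC and the exact identities are N-free.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_starts` | 100 (LCA), 50 (LTA) | random EM initializations; the best log-likelihood wins |
| `tol` | 1e-8 | relative log-likelihood convergence tolerance |
| `max_iter` | 5000 | EM iteration cap per start |
| `clamp` | 1e-6 | probabilities kept in [clamp, 1 − clamp] to avoid log(0) while preserving near-boundary estimates (published profiles contain values like 0.0035) |
| `sparseness_threshold` | 1.0 | minimum expected transition count per cell before transition-covariate logits are attempted |
| `alpha` (pipeline) | 0.05 | LRDT level for invariance and covariate decisions |
| `highlight_threshold` (pipeline) | 0.5 | profile-table emphasis cutoff |

Initialization draws ρ slices from uniform perturbations around the flat
profile, γ/δ from a flat Dirichlet, and τ rows from a Dirichlet with a mild
diagonal boost (latent chains in panel data are usually persistent;
the boost only shapes the search, not the estimate). The `random_state`
seeds the entire start sequence, so a fit is reproducible bit-for-bit.
Convergence diagnostics report how many starts reached the best
log-likelihood (within 1e-4); a best solution found only once raises an
identification warning, as does a data-to-parameter ratio below 5 — a
positive residual df does not guarantee an identified mixture.

## Constraints and covariates

Measurement invariance pools the expected item-category counts across
occasions before normalizing; transition invariance pools the expected
transition counts across occasion pairs. Additional ρ restrictions are
supported as fixed values and equality groups, enforced exactly at every
M-step (equality groups share the pooled count ratio; the free categories
of a slice renormalize around the constrained mass). At most one
constrained cell per probability slice is supported — enough for the usual
anchoring and equating restrictions on binary items.

Covariates enter the model one-step: the E-step uses respondent-specific
prevalences `δ_i = softmax(β₀ + β₁ z_i)` and the M-step refits a weighted
multinomial logit to the expected first-occasion memberships by
Newton–Raphson with step halving (ascent is guaranteed, so EM monotonicity
is preserved). The reference status of the reported coefficients is the
highest-prevalence status; odds ratios are entrywise exp(β) per unit of the
covariate on the scale supplied (raw by default — center before fitting if
a centered interpretation is wanted). Covariates on transition rows use
per-origin multinomial logits, are off by default, and are guarded by an
expected-count sparseness check that raises a `SparsenessError` naming the
thin cells rather than returning unstable estimates; transition effects
are routinely inestimable at moderate N, and the guard turns that into a
reportable finding. No standard errors are computed for ρ/δ/τ/β; inference
runs through likelihood-ratio difference tests and criteria.

Grouped models share ρ across groups and let δ and/or τ vary by group, for
homogeneity tests across known subpopulations under a common measurement
model. Groups and covariates cannot be combined in one fit.

## Model-building pipeline

The framework automates the usual decision sequence with explicit,
logged rules:

* **Step 0** fits the per-occasion LCA grid and pools every class count
  that minimizes at least one of {AIC, BIC, CAIC, ABIC} at at least one
  occasion. Entropy is reported but never drives pool membership — it
  measures classification crispness, not fit. Manual include/exclude
  overrides are honored and logged, since substantive grounds can
  legitimately overrule criteria.
* **Step 1** tests longitudinal measurement invariance per candidate by
  LRDT (invariant vs occasion-varying ρ). If no candidate passes, the
  report recommends repeated-measures LCA instead of crashing.
* **Step 2** selects among survivors by a configured criterion (default
  AIC) with a mandatory conflict warning when BIC disagrees, and emits the
  ρ-profile table with entries at or above the highlight threshold marked;
  a status elevated on every item is flagged as globally elevated.
* **Step 3** tests transition invariance (only for T ≥ 3; at T = 2 the
  test is skipped with a note) and, for grouped panels, δ/τ homogeneity.
  When LRDT and criteria conflict, the configured arbiter (default: the
  LRDT) decides and the conflict is recorded.
* **Step 4** adds each configured covariate to the selected model,
  reports β, odds ratios, and the LRDT effect test; sparseness failures
  become report findings.
* **Step 5** (distal outcomes) is a placeholder marked unimplemented.

Nested comparisons warm-start the freer model from the restricted
solution (appended as one extra EM start), so the nesting inequality
LL_free ≥ LL_restricted holds deterministically rather than up to
multi-start luck. All sub-seeds derive from the single configured seed via
a stable hash; identical (data, config, seed) produce byte-identical
reports.

## Synthetic data

The generator draws status chains (δ, τ), emits items from ρ, optionally
tilts first-occasion prevalences by a covariate through the same softmax
link the estimator uses, and applies monotone attrition: per-wave overall
missing-everything rates, with dropouts never returning. Sporadic
item-level missingness is available as a separate rate. It emulates the
structure of a school-survey panel — six binary items, three waves,
1,180 respondents, attrition 5.59 % and 15.34 % at the later waves — and
`make_paper_like_truth(4)` uses the published 4-status item profiles,
prevalences, and both transition matrices as the generating truth (rows
renormalized to absorb printing rounding; the printed prevalences sum to
0.9999). The 3-status variant is a package construction: the two
middle-prevalence statuses are merged with prevalence weights, mirroring
which classes collapse in the 3-status solution; it is not a published
estimate.

What the simulator does *not* emulate: local dependence between items
within status, non-MAR dropout, clustering of respondents within schools,
and measurement drift. Recovery tests passing on simulated panels
therefore certify the estimation machinery (likelihood, EM, constraints,
selection logic), not robustness to those real-data violations.

## Numerical choices

Emission products use log-space accumulation; the forward pass rescales
per occasion, so likelihoods of rare patterns cannot underflow at these
model sizes. Probabilities are clamped to [1e-6, 1 − 1e-6] during EM.
Posterior ties in modal assignment break toward the lowest class index and
are flagged. Status alignment between two solutions solves the assignment
problem exactly (Hungarian algorithm) on total absolute ρ difference.
Degenerate inputs are defined rather than accidental: S = 1 yields a unit
transition matrix and the independence log-likelihood; entropy at S = 1 is
flagged undefined (NaN), not 0 or 1; a constant covariate reproduces the
covariate-free maximum with slopes pinned near zero by the ridge-guarded
Newton solve.

## Problem sizes in the shipped checks

The test suite and acceptance script use simulation sizes chosen to make
the statistical assertions sharp at desk scale: N = 5000 for parameter
recovery from the survey-shaped truth (MAE tolerance 0.05), N = 50,000 for
pure Monte-Carlo calibration of the generator (tolerance 0.01), 200
replicates at N = 300 for the covariate-null type-I rate (band
0.02–0.09 at α = 0.05), and N = 700 for the end-to-end framework run on a
well-separated 3-status truth. Structural quantities (parameter counts,
degrees of freedom, criterion identities, chi-square tails, odds ratios)
are exact and data-free.

## Known limitations

Continuous indicators, growth-mixture hybrids, distal outcomes, and
three-step/BCH classify-analyze corrections are out of scope. Standard
errors are not provided. The ρ-constraint engine supports one constrained
cell per probability slice. The chi-square reference for the LRDT is only
used for nested fits with equal S (never for class enumeration, where its
regularity conditions fail); enumeration relies on information criteria.
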