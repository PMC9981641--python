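# Methods

`emabayes` fits a hierarchical Bayesian model to Ecological Momentary
Assessment (EMA) data: repeated in-situ questionnaires in which each
report names the current *situation* (one nominal category per declared
dimension) and optionally rates one or more perceptual *attributes* on
ordinal scales.  This note documents the model, its assumptions, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The model

### Data and parameter vector

A study has `T >= 1` phases, `K` joint situation categories (the
Cartesian product of the declared dimensions), and `I` attributes with
`L_i >= 2` ordinal levels each.  All records of participant `n` are
modeled through one parameter vector `xi_n` of dimension

    D = T*K  +  I*P  +  sum_i L_i

concatenating (1) situation logits, (2) ordinal-regression effects
(`P` per attribute), and (3) unconstrained threshold parameters.  For a
two-phase study with one 7-category situation dimension, a saturated
phase-by-situation regression, and attributes with 7/5/7 levels this is
`14 + 42 + 19 = 75` parameters per participant.

### Situation block

Records are exchangeable within (participant, phase); the per-phase
category counts are multinomial with probabilities
`u_t = softmax(logits_t)`.  All `K` logits per phase are kept (not
`K - 1`): the one redundant direction per row is harmless under the
population prior, keeps the block layout aligned with the dimension
accounting above, and avoids a privileged reference category.

### Attribute block: graded-response model

Each rating arises from a latent logistic variable with unit scale
located at `theta_{nik}` — the interval-scale attribute value of
participant `n`, attribute `i`, in phase-situation cell `k`.  The
observed level is `l` when the latent draw falls between consecutive
thresholds `tau_{i,l-1} < Y <= tau_{i,l}`.  Thresholds are specific to
participant and attribute but shared across situations, so individual
response styles (conservative versus extreme scale use, non-uniform
category widths) are part of the model rather than noise.

Locations vary over the `T*K` cells through a cell-indicator design,
`theta = X beta`.  Effect terms are subsets of
`{phase} ∪ {situation dimensions}`; each term contributes one column per
category combination with no reference level dropped.  Main-effect
designs are deliberately rank-deficient in this coding; the population
prior regularizes the null space and reported effects are contrasts,
which are identified.  The default term is the saturated
phase-by-all-dimensions interaction (the design is then a permutation of
the identity on cells).

Thresholds are parameterized by `L_i` unconstrained reals: a location
plus `L_i - 1` softplus-mapped widths, cumulated into a strictly
increasing interior sequence (minimum gap `1e-8` so numerically fused
thresholds cannot produce zero-probability categories).  Response
log-probabilities use the identity
`F(b) - F(a) = F(b) F(-a) (1 - e^{a-b})` in log space, so likelihoods
and gradients stay finite for locations far beyond the data range.

Adding one constant to all locations and thresholds of an attribute
changes no response probability.  The restriction is chosen per
attribute: `median-zero` (default) forces the median interior threshold
to zero inside the likelihood; `zero-mean-attribute` instead centers the
cell locations.  Under `median-zero` the threshold-location coordinate
is redundant and simply regularized by the prior.

Missing ratings contribute nothing to the likelihood — no imputation at
any stage; a situation-only record is fully valid.

### Population model

Within each participant group, the `xi_n` are modeled as draws from a
Gaussian mixture with diagonal-covariance components, with conjugate
Bayesian posteriors over its parameters: Dirichlet over the weights and
per-coordinate normal-gamma over (mean, precision).  The mixture can
express non-linear dependencies between coordinates even though each
component is diagonal, and the Bayesian treatment exhibits the usual
Occam behaviour — components not needed by the data keep only their
small symmetric prior share of the weight.

Hyperparameters (all user-overridable via `GmmHyper`):

| parameter | default | meaning |
|---|---|---|
| `weight_conc` | 1.0 | total Dirichlet concentration, split evenly over `M_max` components |
| `mean_scale` | 1e-2 | precision scaling `kappa_0` of each component-mean prior |
| `prec_shape` | 0.5 | gamma shape of each coordinate precision |
| `prior_scale` | 10 | typical prior coordinate scale in logit units; gamma rate is `prec_shape * prior_scale^2` |
| `M_max` | 5 | maximum mixture components |

These are broad relative to the unit-scale logistic latent variable and
deliberately weak; with a handful of participants the population
posterior is prior-dominated and individual estimates lean on their own
data.

**Component pruning.** After learning, components whose accumulated
responsibility mass (`alpha - alpha0`) is below 0.5 participants are
dropped before any population-level prediction.  An empty component's
mean posterior is essentially the very broad prior, and its expected
weight `alpha0 / (weight_conc + N)` does not vanish for small `N`; a
weight-based threshold would therefore let prior-scale dispersion leak
into population-mean and random-individual draws exactly when studies
are small.  Evidence-based pruning is equivalent at large `N` and robust
at small `N`.

### Learning

Variational learning alternates two steps until the objective proxy
stabilizes:

1. **Individual posteriors.** Each participant's posterior over `xi` is
   `exp(log-likelihood + E[log population density])`, the expectation
   taken under the current population posterior (computed as
   `logsumexp_m(E[log w_m] + E[log N_m])`, which is smooth and has an
   analytic gradient).  It is sampled with Hamiltonian Monte Carlo:
   leapfrog integration (10 steps), identity mass, dual-averaging
   step-size adaptation targeting 0.8 acceptance, per-walker step sizes.
   All (participant, chain) walkers run in one vectorized pass — the
   likelihood and gradient of every walker are evaluated simultaneously
   on stacked count tables, which is what makes the alternating loop
   fast on one CPU.  Default 4 chains x 100 kept samples per iteration;
   warm-up is full on the first iteration and shortened (1/5) afterwards
   since positions and step sizes are warm-started.  Acceptance rates and
   divergence counts are recorded; a run in which every chain diverges
   raises with diagnostics.
2. **Population update.** One conjugate variational update of the
   per-group mixture posterior from the participant sample sets.  Every
   sample of participant `n` carries weight `1/S_n`, so each participant
   contributes total responsibility weight 1 regardless of sample count
   or number of EMA records — a participant with ten times the records
   gets a sharper individual posterior but no extra influence on the
   population estimate.

The convergence proxy is the per-participant mean sampled log joint
density.  Exact evidence-bound bookkeeping is not attempted; the proxy
is monotone up to sampler noise, and the stopping rule (relative change
below `tol = 1e-5` on `patience = 3` consecutive iterations) therefore
acts together with `max_iter` and the cooperative time limit
(`max_minutes`, checked between iterations, never mid-iteration; a
time-limited fit is flagged `partial`).  In the simulation studies below
the proxy plateaus within about 8 iterations.

A single seed drives all randomness — initialization jitter, component
jitter, HMC momenta and accept decisions — so a fit is exactly
reproducible from its settings snapshot.

### Predictive inference and credibility

Three inference levels reuse the same push-forward maps (softmax,
design matrix, threshold transform):

* `random_individual` — hierarchical draws: mixture parameters from
  their posterior, then a component, then `xi`;
* `population_mean` — posterior draws of the mixture mean
  `sum_m w_m mu_m`;
* `participant:<id>` — that participant's stored sample set.

Tables report the 2.5/25/50/75/97.5 percentiles.  The credibility of a
set of inequalities (e.g. "the phase-B location exceeds the phase-A
location, averaged over situations") is the fraction of draws satisfying
all of them jointly, with a Monte-Carlo standard error; joint evaluation
already accounts for multiplicity, so no correction is applied.
Posterior-predictive checking simulates rating counts conditional on
each observed record's cell for each posterior draw and overlays the
observed counts on the 95% count intervals.

## The synthetic-data generator

`TruePopulation` specifies a mixture over `xi`-space, per-phase Poisson
record-count means, and per-attribute missing-completely-at-random
probabilities; `simulate_dataset` pushes ground-truth parameters through
the same maps as the model and writes the standard file dialect with the
truth serialized alongside.  Two scenarios ship with the package:

* `ihab_like_scenario()` — the structure of a two-phase
  hearing-rehabilitation study: 7 listening-situation categories,
  attributes with 7/5/7 levels (75 parameters per participant),
  13 participants, ~51 records per participant and phase (~1330 total in
  expectation), uneven situation occupancy with rare categories,
  low-dispersion loudness ratings, a scarce involvement attribute
  (~89% missing), strongly skewed disability ratings improving by
  2.9 logit units after intervention, non-uniform threshold spacing.
* `recovery_scenario(effect)` — a minimal non-trivial design for
  simulation studies (two phases, two situation categories, one 5-level
  attribute, `D = 13`, single-Gaussian truth, ~30 records per
  participant and phase) with a configurable phase effect; small enough
  that replicated fit studies run in minutes on one CPU.

What the generator does **not** emulate: prompt timing and
within-day autocorrelation (records are exchangeable within phase),
informative missingness (dropout is MCAR per attribute), response
drift over time, and continuous context covariates.  Passing recovery
and calibration tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness
to these real-data departures.

## Simulation-study sizes and tolerances

The replicated studies in the test suite use the recovery scenario at
N=20 participants and reduced sampler settings (2 chains x 40 kept
samples, 10 variational iterations) so a 20-replicate suite completes in
a few minutes on one CPU; single-fit spot checks in the acceptance
script use the same sizes.  Quantitative expectations:

* elementary probability blocks match closed-form oracles to 1e-12;
* sampled single-participant situation inference matches the conjugate
  Dirichlet posterior mean within 0.05 per coordinate (Monte-Carlo error
  plus the O(1/R) difference between a broad Gaussian prior on logits
  and a flat Dirichlet on the simplex);
* a 2-logit population phase effect is recovered by the population-mean
  posterior median within ±0.5 with ~95% interval coverage across
  replicate seeds;
* under a null effect, credibility of an improvement stays in
  (0.05, 0.95); under a 3-logit effect it exceeds 0.95;
* ≥90% of observed response-category counts fall inside their 95%
  posterior-predictive intervals on well-specified data.

## Degenerate inputs and edge behaviour

* A participant declared but without records has likelihood 0 and a
  posterior equal to the population predictive.
* A single-participant study runs (with a warning); the population
  posterior stays prior-dominated.
* An attribute never rated by anyone yields an empty
  posterior-predictive table, not a failure.
* Counts on a zero-probability situation return `-inf` likelihood
  rather than raising; the softmax parameterization keeps fitted
  probabilities strictly positive.
* Duplicate or partial reports from one assessment prompt are treated
  as independent records.

## Limitations

* No continuous covariates in the regression (categorical effects
  only).
* Full-covariance mixture components are not supported; dependence
  between coordinates is expressed only through multiple components.
* No cross-group hierarchical sharing: each group's population model is
  learned independently.
* The HMC sampler uses an identity mass matrix; strongly anisotropic
  individual posteriors rely on step-size adaptation alone, which can
  be slow for extreme record counts per cell.
* Thresholds are shared across situations by design; situation-specific
  response styles are outside the model.
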