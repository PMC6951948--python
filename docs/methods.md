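# Methods

## Model

`cthmm` fits a continuous-time hidden Markov model (CTHMM) of disease
progression. A patient's latent disease state `S(τ)` moves through
`M` ordered states according to a time-homogeneous continuous-time Markov
chain with generator `Q` (rates per year; rows sum to zero). At each clinic
visit — at irregular, patient-specific times `τ_1 < … < τ_T` — a vector of
`K` continuous features is observed; conditional on the current state the
features are independent Gaussians, `Z_k | S = m ~ N(μ_{m,k}, σ²_{m,k})`.
The parameter set is `Θ = {Q, π, μ, σ²}`, where `π` is the distribution of
the state at the **first observed visit**. That convention is forced by the
data this model targets: observational cohorts are left-truncated, so
patients enter the record partway through their disease course and `π`
cannot be read as a disease-onset distribution.

Structural knowledge enters as a mask on the off-diagonal entries of `Q`:

* **full** — any state can transition to any other (progression and
  recovery);
* **forward** — only to strictly later states (irreversible disease);
* **forward chain of order L** — only to the next `L` states (irreversible
  and gradual, with limited "skipping").

Any state may additionally be declared absorbing (zero exit rates),
modelling a terminal stage. Transition probabilities over an inter-visit
gap `δ` are `A(δ) = expm(δQ)`; entries structurally unreachable under the
mask are pinned to exact zero after the exponential, so e.g. a forward
model's `A(δ)` has an exactly zero lower triangle at any horizon.

## Estimation

Parameters are estimated by soft (posterior-weighted) EM:

* **E step.** Per patient, a scaled forward–backward pass over the visit
  sequence (with interval-specific `A(τ_t − τ_{t−1})`) yields per-visit
  posteriors `γ` and per-interval pairwise posteriors `ξ`, plus the exact
  observed-data log-likelihood. Because the states between visits are
  unobserved, the expected transition counts `E[N_kl(δ)]` and sojourn times
  `E[R_k(δ)]` over each interval are computed conditional on the interval's
  endpoint states and averaged under `ξ`. The endpoint-conditioned
  integrals are evaluated with the auxiliary `2M×2M` block-matrix
  exponential `expm(δ [[Q, B], [0, Q]])` (one exponential per needed unit
  matrix `B`). This route was chosen over eigendecomposition because
  forward-chain generators with tied rates are defective (non-diagonalizable),
  where eigenvector methods lose accuracy; the block method is uniformly
  robust.
* **M step.** Closed forms: `Q_ij = E[N_ij]/E[R_i]` on mask-allowed
  entries, `π` the average first-visit posterior, `μ` and `σ²` the
  posterior-weighted feature moments.

Soft EM is used throughout, and Viterbi decoding is applied only to produce
the reported state sequences. Using posteriors inside EM (rather than a
single decoded path) is what gives the monotone-likelihood guarantee that
the test suite asserts on every cohort.

### Numerical choices

* Forward-pass scaling by per-visit normalizers, log-accumulated; emission
  log-densities are shifted by their per-visit maximum before
  exponentiation. Series of 25 visits and a dozen states stay far from
  underflow.
* Off-diagonal rates are clipped to `[1e-6, 1e3]`/year during estimation.
  Disease sojourns of interest span days to decades; the clip keeps
  `expm` well-conditioned for degenerate intermediate iterates and keeps
  every allowed transition minimally supported.
* Emission variances are floored at `1e-6` to prevent collapse onto single
  observations.
* Elapsed times are canonicalized to a `1e-6`-year grid for caching matrix
  exponentials (the exponential is still evaluated at the exact requested
  gap; the grid only decides cache identity). Registry data carry visit
  dates, so genuinely distinct gaps never collide at that resolution.
* Convergence: relative log-likelihood change below `1e-6` (default), with
  a 500-iteration cap and best-of-3 k-means restarts. EM is a local
  optimizer and the initialization is therefore deterministic given a seed:
  k-means clusters (computed on a canonically sorted copy of the pooled
  features, so patient order cannot change the fit) are relabelled in
  ascending order of a severity score — the projection of the pooled
  features on their first principal direction, signed so that the score
  increases over within-patient time.
* Viterbi ties break toward the lower state index, for determinism across
  runs and platforms.
* Visits with any missing feature are dropped at load time, then patients
  with fewer remaining visits than the configured minimum (2 for fitting;
  the selection command defaults to 4, mirroring the common practice of
  selecting model size on the richer series).

## Choosing the number of states

`select_num_states` splits the cohort **by patient** (deterministically,
given a seed), fits one model per candidate `M` on the training side and
scores each by total log-likelihood on the held-out side; the argmax wins,
with ties broken toward smaller `M`. A single split is the default;
per-visit normalization of the score is available for strongly unbalanced
cohorts. Information criteria (AIC/BIC) are deliberately out of scope: the
held-out score is the selection rule this package implements.

One property of this procedure is worth knowing: with one fixed cohort,
scores across different split seeds are strongly correlated, because every
split shares the cohort's finite-sample quirks; models with surplus states
can exploit those quirks on both sides of the split at once. Replicated
selection experiments should therefore simulate an independent cohort per
replicate, which is what the test suite does.

## The synthetic cohort generator

`simulate_cohort` mirrors how pooled observational registries actually
observe patients:

* the hidden course starts in the initial state (or a configured onset
  distribution) and evolves by Gillespie simulation of the generator;
* observation begins at a random **entry time**, uniform over a
  configurable window (default 30 years), emulating left truncation — the
  cohort mixes early, transitional and late presentations;
* visit counts are `1 + Poisson(mean − 1)` truncated at 25, calibrated by
  default to a mean of about 2.9 visits per participant, the typical yield
  of pooled registry data (a balanced fixed-count panel is available for
  designed-study scenarios);
* gaps are Gamma around 1 year, rounded to a 0.1-year grid — scheduled
  roughly-annual visits with month-scale jitter;
* observations are Gaussian around the state means.

Ground-truth state sequences are returned alongside the cohort.

`hd_preset` is a nine-state, second-order forward-chain scenario with an
absorbing ninth state whose exit rates are constructed so the expected
state durations equal the published staging values (9.7, 9.2, 3.8, 2.9,
5.8, 3.5, 3.0, 3.2 years). The exit mass splits 80/20 between the +1 and
+2 jumps, except out of states 3 and 4 where the skip share is enlarged to
40%, reflecting the non-negligible state-skipping reported for the
transition phase. Its nine features (three factors in each of the motor,
functional and cognitive domains) carry invented, illustrative means —
monotone trends (motor worsening upward, functional/cognitive downward)
with unit variances and two-sigma separation between adjacent states; no
published per-state feature values exist to calibrate against.

### What the generator does not emulate

Real registry data have missingness that is informative, assessment
batteries that change between studies, rater effects, measurement floors
and ceilings, and feature distributions that are only approximately
Gaussian. Passing the simulation-based tests therefore demonstrates the
correctness of the estimation machinery under the model's own assumptions,
not robustness to their violation.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale, chosen to make each check
statistically meaningful: likelihoods are verified against brute-force
enumeration on instances up to 4 states and 6 visits; endpoint-conditioned
expectations against ≥100,000 simulated paths per start state; parameter
recovery on 500-patient balanced panels of five annual visits from a
3-state chain with 4σ-separated states and sojourns of several years (the
regime where annual panels identify the +1/+2 jump split); and state-count
recovery on ten independent 300-patient cohorts with a 50/50 patient
split. Sampling-noise analysis behind these sizes: the maximum-likelihood
estimate of a skip rate under annual observation carries a relative
sampling spread of roughly 10–20% at this cohort size, so recovery bands
tighter than that are not testable at smaller scales.

## Prediction

`predict_future` propagates the last-visit posterior through `A(h)` for a
horizon `h` and reports the resulting state distribution together with the
posterior-mixture expected feature vector. This is a standard construction
chosen by this package; it conditions on the full observed series and
reduces to the last-visit posterior at `h = 0`.

## Known limitations

* Time-homogeneous dynamics only; no covariate-dependent rates, no
  semi-Markov sojourns, no time-inhomogeneous generators.
* Emissions are independent Gaussians; other exponential-family emission
  models are a natural extension point but are not implemented.
* No standard errors or posterior uncertainty for `Θ`.
* Model-size selection by held-out likelihood has limited power to reject
  surplus states on small cohorts (see above); curves should be read with
  that in mind.
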