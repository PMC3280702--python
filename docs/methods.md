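# Methods

This note records the model, the choices made where the design was open, and
what the synthetic experiments do and do not establish.

## Detection statistic

The connectivity matrix of one window is the band-integrated cross-power
between all channel pairs, diagonal (auto-power) included. Choices:

- **Spectral estimator.** Welch cross-spectra with 1-s Hann sub-windows and
  50% overlap inside each 5-s window. At sampling rates of 250–500 Hz this
  gives 1-Hz resolution with ~9 averaged segments per window, a standard
  variance/resolution compromise for short EEG windows.
- **Complex cross-spectra.** The band-integrated cross-spectrum is complex
  off-diagonal; the matrix entry is its magnitude (default), which guarantees
  a symmetric nonnegative real matrix so that singular values coincide with
  eigenvalue magnitudes. Taking the real part instead is available via the
  `mode` argument.
- **Band integration** is a trapezoidal sum over the FFT bins whose centers
  lie in `[lb, ub]` inclusive, falling back to a rectangle rule if the band
  holds a single bin.
- **Causality.** The matrix indexed by second `k` uses samples `(k−5, k]`
  only, so a detector reading `σ1(k)` at stage `k` sees no future data. A
  record of `floor(duration)` whole seconds yields `floor(duration) − 4`
  matrices.
- **Band presets.** theta 4–7, alpha 8–13, beta 13–30 Hz. Clinical
  descriptions of the beta band vary between 13 and 14 Hz at the lower edge;
  the 13-Hz convention is used here.
- **Sign convention.** The first singular vector's sign is fixed by making
  its largest-magnitude component positive; SVD sign is otherwise arbitrary.

## Observation model

The per-second statistic is quantized by a monotone uniform-width quantizer
built on the training range (default 50 bins; out-of-range values clip to the
end bins). Nothing in the method constrains the quantizer dialect; uniform
bins keep the code-to-statistic map affine, so the fitted GLM contrast is
easy to read.

Each state's emission law is Poisson with log-rate
`α_x + Σ_{j=1..L} β_{x,j} n_{k−j}`. Fitting is plain maximum likelihood via
iteratively reweighted least squares (statsmodels GLM), with the asymptotic
covariance retained for 95% bounds; a small ridge (1e−6) is the fallback on
degenerate designs. The lag order is selected by AIC = 2(L+1) − 2·loglik with
all candidates fitted on a common effective sample (stages ≥ max candidate
lag) so their likelihoods are comparable; ties break toward smaller L. AIC
keeps its usual fixed overselection probability, so "β = 0 selects L = 0"
holds modally, not surely.

Training protocol: Θ0 is fitted on nonictal stages, Θ1 on annotated ictal
stages. Lagged covariates always come from the full continuous series, so an
ictal epoch shorter than L borrows its history from the immediately preceding
signal rather than being padded. ρ is the closed-form chain MLE —
(# 0→1 transitions) / (# state-0 stages with a successor) — pooled over
training sequences.

History initialization: stages `k < L` (and the history-free evaluation of
the initial posterior) use a constant pad equal to the integer nearest the
nonictal stationary mean `exp(α0)`, which avoids a start-up transient biased
toward either state.

Band selection picks the candidate band maximizing the distance between the
two states' parameter vectors, measured as the Euclidean norm of
`(Θ0 − Θ1)` with each coordinate scaled by the pooled standard error
`sqrt(se0² + se1²)`; with no definition of "distance" inherent in the
method, this standardized form was chosen so well-resolved contrasts
dominate poorly estimated ones. It defaults to a short lag (L = 3) so the
ictal fit stays well conditioned on few annotated epochs.

## Information-state filter

All likelihood work is in the log domain. The recursion is evaluated as
`π' = Lr / [(1−π)(1−ρ) + Lr]` with `r = π + (1−π)ρ`: every term is
nonnegative, so there is no catastrophic cancellation as π → 1. The
likelihood ratio is clipped to `exp(±50)` (with a logged warning) and π is
clipped to `[1e−12, 1 − 1e−12]` between updates so the filter stays
responsive after long quiescent stretches; both safeguards are inactive in
ordinary operation and all exactness tests pass through the unclipped
region.

After a detection the filter terminates and restarts: π re-initializes via
the one-observation posterior while the GLM history buffer is retained by
default (the underlying signal is physically continuous). With carryover
disabled, each restart segment is refiltered as a fresh series — then the
post-restart trajectory is bit-identical to filtering the suffix alone,
which is the property the tests assert.

## Stopping policy

Per-stage costs under the geometric change prior `P(T=k) = (1−ρ)^{k−1} ρ`:

- continue (u=0): `γ · D(k) · π` with `D(k) = E[k−T | T ≤ k]`, the expected
  age of an already-occurred change. D(k) grows like `k − 1/ρ` for large k,
  which is what drives the threshold downward over the horizon.
- stop (u=1): `(1−γ) · (1/ρ) · (1−π)`, the memoryless expected residual
  time to the change weighting the false-positive probability.
- The delay exponent is 1 by default; `delay_exponent=2` squares D(k) for a
  harsher late-detection penalty. The linear form is the operational
  per-stage cost actually minimized by the recursion; the quadratic variant
  is provided because the aggregate objective can be stated with a squared
  distance.
- Final stage: `G_M(π) = (1−γ)(1/ρ)(1−π)` — the horizon forces a decision,
  costed as a forced stop. A delay-styled alternative is configurable.

Backward induction runs over the information state. Two backends share the
cost model:

- **grid** (default): J tabulated on a uniform π grid (1001 points default)
  with linear interpolation inside the one-step expectation. O(M·grid·A)
  time, constant memory; used at production horizons (M in the thousands).
- **exact**: for this two-state problem J_k(π) is piecewise linear and
  concave, so it is carried exactly as a lower envelope of lines; stop
  minus continue is convex, so the stopping region is an interval [F_k, 1]
  and the threshold is the exact crossing point. Line counts can grow
  geometrically with the horizon, so this backend is intended for small
  alphabets/horizons, where it agrees with extensive-form enumeration to
  ~1e−14.

Because exact DP over history-dependent emissions is exponential in L, the
policy is synthesized from *history-marginalized* per-state pmfs — the
average one-step predictive pmf over training histories, truncated to the
quantizer alphabet with the tail folded into the last bin — while the online
filter keeps full history dependence. The approximation is exact for
history-free models, which is where the enumeration checks run.

Online detection uses the strict rule `π_k > F_k` (ties continue), restarts
the filter and the stage clock after each alarm, and suppresses re-alarms
for a refractory period (default 60 s). Beyond the horizon the last
threshold F_{M−1} is held: the geometric prior is memoryless, so an expired
stage clock carries no extra information.

## Baselines and scoring

BE thresholds π at 0.5 with the same restart/refractory machinery; HT
thresholds the raw statistic at mean + 3 SD of nonictal training data, with
the sample (n−1) standard deviation. Scoring matches detections to onsets
greedily in detection-time order, one-to-one, within a symmetric inclusive
±20-s window; delays are signed (negative = anticipation) and the combined
delay summary is the mean of absolute values. FP-per-hour denominators
exclude annotated ictal spans and, approximately, post-detection refractory
spans.

## Synthetic data

Two generators define the study conditions:

- **Surrogate recordings**: independent AR(1) noise per channel (coefficient
  0.9) plus one shared sinusoid whose amplitude switches from
  `nonictal_coupling` (0.2) to `ictal_coupling` (1.5) inside annotated
  epochs, at 20 Hz by default so the contrast lands in the beta band. The
  cross-power matrix responds directly to shared band-limited power, so the
  generator's effect on σ1 is analytically predictable; a common drive of
  amplitude a adds a rank-one component of order a²/2 per channel pair.
- **HMM-GLM sequences**: counts drawn from the observation model itself.
  The benchmark corpus uses nonictal baseline rate 5 and ictal rate 15 with
  weak positive self-excitation over 3 lags (total β ≈ 0.06 / 0.015) —
  strong but overlapping separation, so detection takes a few seconds and
  the γ trade-off is visible. Runs are 7200 s with one scripted 60-s epoch,
  onset geometric (ρ = 1/3600) conditioned into [600 s, 5400 s]; 2 training
  and 10 validation runs. A log-rate cap of +20 aborts (rather than clips)
  runaway self-excitation. The log-link self-exciting process has a heavy
  tail — on the order of 1% of 2-h sample paths escalate past the cap — so
  the corpus builder deterministically redraws such a path; the corpus is
  thereby conditioned on the model's stable operating range.

One integer seed governs everything; per-component sub-streams derive from
it deterministically.

What the surrogates do **not** emulate: seizure morphology (spikes,
electrodecrement, rhythmic evolution), postictal σ1 depression and drift,
sleep/wake nonstationarity, volume conduction, artifacts. Passing tests
therefore establish the correctness of the machinery and the direction of
the delay/false-alarm trade-off under model-matched conditions — not
clinical performance, which in real recordings is limited by model mismatch
rather than by the policy computation.

## Problem sizes

The test suite and the acceptance script run the corpus at 10 × 2-h
validation runs, enumeration checks at horizon ≤ 6 and alphabet ≤ 3 (all
observation sequences), filter exactness on all 3-symbol sequences up to
length 8, and recovery at 1,000 chains (ρ) and 100 replicates of n = 20,000
(GLM). These sizes give Monte-Carlo error well inside the asserted
tolerances while keeping a full run in minutes.

## Known limitations

- The DP threshold's dependence on the current observation and history is
  mediated entirely through π and the marginalized emission pmfs; a policy
  synthesized against the full history-dependent law would require an
  exponential state space.
- The fitted ρ under-estimates the onset hazard when long post-ictal
  nonictal stretches are pooled with pre-ictal ones; with one event per
  training run this biases ρ̂ low by roughly the post/pre duration ratio.
- Quantile or adaptive quantizers, m > 2 hidden states, multi-band fusion,
  and exponential delay penalties are out of scope.
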