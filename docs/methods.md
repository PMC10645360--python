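# Methods

This note documents the model implemented by `lakeq`, the assumptions it
makes, what the synthetic generators do and do not emulate, and the
numerical and design choices behind every default. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## The decision problem

A multivariate environmental series (s indicator channels, uniform hourly
grid) is forecast one step at a time by a pool of base models
M = {m₁, …, m_K}. The agent's state space and action space both index this
pool: the state at step t+1 is defined as the model chosen at step t, so
the Q tables are K×K. This state carries no information about the data
regime — it is the construction the method prescribes — and consequently
the best achievable stationary policy is essentially "always pick the best
single arm, possibly in a cycle". The learning problem is therefore close
to a (nonstationary) multi-armed bandit dressed as an MDP, and the
discount γ mainly couples cells through the bootstrap term.

### Exploitation schedule

ε(u) = (2/π)·arctan(scale·(u − offset)), clipped to [0, 1), with defaults
scale = 0.2 and offset = 0.1. ε is the probability of *exploiting*
(argmax of Q\*); with probability 1 − ε a uniformly random action is taken.
The curve rises steeply early (ε(1) ≈ 0.13, ε(10) ≈ 0.70) and saturates
towards 1, so exploration is front-loaded. A fixed-ε baseline
(`ConstantSchedule`) is provided for comparisons. The printed source for
the schedule's constants is ambiguous; both constants are configuration
knobs.

### Reward

R = (1/s) Σᵢ −|yᵢ − ŷᵢ|, computed by default on z-scored channels using the
training split's statistics, so channels with different units contribute
comparably (a raw-scale variant sits behind `reward_zscore=False`).
Degenerate (constant) channels get a unit divisor instead of zero. R ≤ 0
always, with equality only for a perfect forecast, and R is invariant to a
common shift of truth and prediction.

### Triple-Q update

Three tables receive synchronous updates from the shared combined table:
all three targets are computed from the pre-update Q\* and each table's own
next-state maximum, then the touched cell of Q\* is rebuilt once as
Q\* = λ·Q_ave + (1−λ)·Q_min with λ = |Q_ave−Q_min|/(c+|Q_ave−Q_min|).
Q_min ≤ Q_ave always, so Q\* is a convex combination lying between them,
and λ ∈ [0, 1) for any c > 0; both facts are asserted after every update in
the tests.

A structural consequence of this exact update rule: with the default
all-zeros initialization the three tables receive *identical* updates and
remain equal forever, so λ = 0 and Q\* degenerates to a single Q table
during pipeline training. The mean/min weighting only engages when the
tables differ (they are exercised separately in the tests). We implement
the rule as stated rather than desynchronizing the tables, and note that
the pessimism machinery is inert under this initialization.

Defaults α = 0.1, γ = 0.9, c = 1.0 — conventional tabular values; the
method names these parameters without fixing them, so all are configurable
and logged with every run.

### Known behavioural limits of the tabular agent

Two effects matter in practice and shaped several design choices below:

* **Recency.** With constant α the Q value of a cell is an exponentially
  weighted average of its last ~1/α visits. Late in training, when ε ≈ 1,
  the greedy arm is visited every step and its Q value tracks only the most
  recent stretch of the walk, while rival arms' values are stale snapshots.
  Arms separated by less than roughly the reward noise over a ~10-visit
  memory cannot be distinguished reliably, and the greedy policy can churn
  indefinitely on near ties.
* **Lock-in.** Because exploration decays towards zero, whatever the tables
  say when exploration effectively stops tends to persist. Tasks used for
  convergence checks therefore need either well-separated optima or enough
  early exploration for the values to converge first.

## Two-stage pipeline

**Stage 1.** Base models are fitted once on the first half of the training
split (`eval_fraction = 0.5`) and the learning walk covers the second half,
so every reward reflects out-of-sample skill. This matters: a fitted
autoregression scored in-sample looks optimistically good and the learned
selection does not transfer. Because the models are fixed and the walk
follows the true series, each model's forecast at a given step is the same
in every episode; forecasts and per-(action, step) rewards are precomputed
once and the episode loop reduces to table updates. An expanding-window
refit mode (`refit_every`) exists for users who prefer more data per fit at
the cost of an error series drawn from a mixture of fit sizes.

**Hand-off.** After stage-1 training a deterministic greedy pass over the
walked region produces the preliminary predictions and the error series
(truth − preliminary, channel order preserved; compensation is therefore
addition). The deployed stage-1 models are exactly the models whose errors
stage 2 sees — deployment consistency is why stage 1 is *not* refitted on
the full split.

**Stage 2.** The same learning machinery runs on the error series with
re-initialized tables. The default error-model registry is
`["zero", "ridge_ar"]` with a 6-step window, not a copy of the stage-1
pool:

* a **null arm** anchors compensation at the identity — when the residuals
  carry no structure the correct correction is zero, and the agent can say
  so;
* a **ridge autoregression** with cross-validated shrinkage (per channel,
  penalties from 10⁻³ to 10⁵) collapses towards the null on white
  residuals and captures structure (e.g. the decaying transients an
  averaging model leaves after a level shift) when it exists;
* persistence and window-mean are *excluded* by default: applied to
  near-white residuals, persistence multiplies the noise variance by two
  and a trailing mean injects the window's noise average, and both were
  measurably harmful as corrections.

The error window (6 h) is deliberately much shorter than the base-model
window (24 h): residual structure decays within hours, and short lag
vectors keep the ridge fit from chasing noise. Stage-2 models are refitted
on the whole error series after training (nothing downstream consumes their
errors, so the extra data is pure gain). Stage-2 rewards are z-scored on
the error series' own statistics, symmetric with stage 1.

**Prediction.** One-step evaluation walks the test rows with true history:
the stage-2 buffer holds the *realized* errors of already-observed steps,
so the correction for step t uses only information available before t.
Multi-step `predict` rolls forward on its own final forecasts and its own
predicted errors. Compensation never changes channel count or timestamps.

**Early stopping.** Training stops when the greedy policy has been stable
for `patience` (50) consecutive episodes, within a budget of
`n_episodes` (500). On tasks with clearly separated arms this triggers
within the first ~50–100 episodes; on near ties it does not trigger and
the final tables decide.

## Base forecasters

Deliberately lightweight so the selection mechanism — the contribution —
can be exercised quickly: persistence (window 1), a multi-output linear
autoregression (one least-squares AR(24) per channel on its own lags), and
a trailing 24-hour mean. The per-channel AR design is intentional: a single
regression on the flattened window·s lag matrix has hundreds of collinear
features and interpolates training noise. Heavier sequence models
(recurrent, attention, deep-forest) plug in through the same two-method
contract (`fit`, `predict_next`) when their dependencies are installed;
requesting them without the dependency raises a named error. The default
window of 24 steps is one day at hourly sampling.

## Preprocessing

**Recursive average filtering.** Each channel is convolved with a uniform
kernel of length l (default 5); output entry j is the trailing-window mean
for j ≥ l and the ramp-in partial sum (N₁+…+N_j)/l before that, so output
length equals input length. `ramp_in_mask` flags the attenuated leading
entries so downstream code can drop them. Larger l smooths harder.

**Correlation PCA.** Eigendecomposition (`numpy.linalg.eigh`) of the s×s
correlation matrix of the z-scored channels — the eigenvalues then sum
to s. Loadings follow the SPSS component-matrix convention
(eigenvector × √λ, each component sign-flipped so its largest-magnitude
loading is positive); communalities are row sums of squared retained
loadings. Retention keeps the smallest p with cumulative contribution
≥ 85 % (configurable); an "eigenvalue near one" heuristic is reported via
the spectrum but not enforced, since it is not operational at the margin.
A faithful unit-norm column scaling (`column_normalize`, no centering) is
provided separately. KMO uses the anti-image partial-correlation matrix;
Bartlett's sphericity statistic is −((v−1) − (2s+5)/6)·ln det R on
s(s−1)/2 degrees of freedom. For a singular correlation matrix (fewer
samples than channels) the suitability statistics are reported as NaN
while the spectrum is still computed, with a rank-deficiency warning.

Missing values at ingestion are rejected by default; linear interpolation
along time is available behind a flag. PCA is a diagnostic stage: the
forecasting pipeline consumes all channels, not the reduced scores.

## Synthetic data

No public record of the hourly indicator data the method targets exists,
so two generators stand in.

**`generate` (structured indicator series).** Twelve channels (the named
indicators, at realistic base levels and amplitudes) driven by three shared
latent factors — a diurnal sinusoid, a multi-week sinusoid, and a
stationary AR(1) drift — through a loading matrix in which about two
thirds of the channels load heavily on the diurnal factor (so the leading
correlation eigenvalue exceeds 2 and the retention rule is exercised), plus
independent Gaussian channel noise (sd = 0.3 × amplitude by default) and
scheduled abrupt level shifts (by default at 40 % and 70 % of the series on
three channels). 1008 hourly steps ≈ six weeks; the first 900 rows are the
training split and the next 90 the test split throughout. Values are
clipped at zero with a warning, since concentrations are nonnegative —
clipping slightly distorts the noise law near zero, which is why the
defaults keep levels well away from it. A ground-truth sidecar (latent
factors, noiseless values, noise sds, shift schedule) supports the tests.
What this generator does *not* emulate: cross-channel lead–lag structure,
heavy-tailed sensor error, missingness patterns, or any real site's
distributions — conclusions from passing tests are about the method's
mechanics, not about any particular lake.

**`generate_regime_benchmark` (model-selection benchmark).** Blocks of 96
steps alternate through a trend–plateau–trend pattern. Trend blocks are
near-linear ramps (slope redrawn per block, mean-reverting toward a long-run
center so levels stay inside the fitted range) buried in heavy Gaussian
noise (sd 0.8 in latent units): the territory of the linear autoregression,
which both averages the noise and extrapolates the slope, while persistence
pays √2 × the noise and a window mean lags the ramp by half a window.
Plateau blocks are quiet levels (sd 0.05) with occasional per-channel
shifts (magnitude 2.0, on average every 8 steps per channel): persistence
territory, since an averaging model smears every shift across its window.
Shifts are per-channel rather than synchronized so the multi-indicator mean
reward is not dominated by rare synchronized spikes — under synchronized
shifts the reward noise exceeds the between-arm gaps and the tabular agent
cannot resolve them (the recency effect above). The 2:1 trend weighting
separates the overall best arm enough to be learnable while each regime
still has a different winner; both properties are asserted in the tests.
The chosen arm's plateau errors carry decaying post-shift transients — the
structure stage 2 can exploit.

On this benchmark the expected ordering of median test MAE is
DD-3Q ≤ 3Q ≤ 1.05 × best single model. The second inequality holds with a
clear margin; the first is structurally thin: the one-step errors of a
well-chosen linear model are near-white, so the exploitable structure is
limited to the post-shift transients, and the honest compensation gain is a
few percent — an unlucky seed family can erase it. This is a property of
the method under these semantics, not an implementation artifact: a
correction stage cannot predict the innovations of an already-adequate
model.

## Numerical choices and degenerate inputs

* Ties in every argmax go to the lowest action index; all randomness flows
  from a single seeded `numpy` generator per run, and seeds are stored with
  every artifact (plus a config hash) for exact regeneration.
* Identical seed and config ⇒ bit-identical traces, tables and forecasts;
  asserted in the tests, including through a save/load round trip (tables
  as CSV, model states and config as JSON/YAML).
* Zero-variance channels: rejected by PCA (explicit error naming the
  channel), tolerated by the reward scaler (unit divisor), and a constant
  series trains end to end with a warning that the error series is null.
* MAPE guards truths below 10⁻⁸ (error by default, maskable); pooled
  metrics average per-channel values with equal weights.
* The ramp-in entries of the smoother are kept (output length equals input
  length) but masked, trading a small known attenuation at the start for
  exact agreement with the stated expansion.

## Limitations

* The state construction cannot condition on the data regime, so the agent
  cannot beat the best single model through switching alone; its realistic
  target is to *find* that model and to compensate its systematic errors.
* Tabular learning with fixed α resolves reward gaps down to roughly the
  per-visit noise over a ~1/α-visit memory; arms closer than that churn.
* The compensation stage helps only where the stage-1 errors are
  predictable; on near-white errors its best move is the null correction.
* Base models are fitted once per run; there is no online refitting, and
  no uncertainty quantification (point forecasts only).
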