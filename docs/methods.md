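# Methods

This note documents the models implemented in `metabandit`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Task environment

The environment is a discrete-trial two-port bandit with concurrent
variable-interval ("baited") reward schedules. At the start of every trial
each port that is not already loaded is loaded with a reward with its current
assignment probability; a loaded reward stays on the port until that port is
next chosen. Assignment probabilities come in (left, right) pairs cycling
(0.60, 0.10) → (0.10, 0.60) → (0.525, 0.175) → (0.175, 0.525) → …, with block
lengths drawn uniformly from {60, …, 80} trials. A due transition is
postponed while the fraction of recent choices (window: the last 60 included
choice trials) on the currently rich side is below 50%, and re-checked every
trial thereafter.

Because rewards accumulate on a neglected port, the probability that a
reward is available on side *s* at trial *t* is

    P_avail(t) = 1 − Π_{x=t−n(t)}^{t} (1 − A_s(x)),

where n(t) counts the trials since side *s* was last chosen. We define n(t)
over *all* trials (baits accrue on lapse trials too), which coincides with
the successive-opposite-choice count whenever no lapse trials intervene.
The **optimality score** is the session mean of P_avail on the chosen side;
**P(choose high)** is the fraction of included choices on the richer side.

Degenerate inputs: sessions without included choice trials raise an error
rather than returning a silent NaN.

## Recurrent actor–critic agent

Two parallel recurrent subnetworks (50 tanh units each for actor and critic;
no cross-connections) receive three input neurons — previous reward,
previous-left, previous-right — active only at the single time step after the
previous choice; the first trial of a session receives all-zero input. Each
trial lasts 4 or 5 time steps (uniform per trial). The action is sampled from
the softmax over the two actor logits at the trial's final step; the critic
reads out a scalar value at every step.

Training is single-worker advantage actor–critic with truncated
backpropagation through time, implemented directly in numpy with
hand-derived gradients (validated against central finite differences of the
teacher-forced objective to ~1e-10 relative error; the test suite asserts
1e-5):

* policy loss −ln π(a|s)·δ − β_e H(π) at choice steps;
* value loss β_v·0.5·(R − V)² at every time step;
* advantage δ = R − V with the n-step bootstrapped return R computed per
  50-step unroll segment, discount γ = 0.5 per *time step*, bootstrap value
  taken at the first step of the next segment (0 at session end);
* returns and advantages are stop-gradients (standard A2C semi-gradient).

Hyperparameters: learning rate 5e-4, β_e = 0.5, β_v = 0.01, unroll 50 steps,
500 trials/session, 300 training sessions plus one frozen evaluation
session. Weights are strictly frozen within a session; per-segment gradients
are stored and applied sequentially with RMSProp (decay 0.99, ε = 1e-5) at
the session boundary (an averaged single-step mode is available via
`TrainConfig.update_mode`). Initialization is Glorot-uniform with zero
biases. Where the value loss applies was an open choice: we keep it at every
time step (the critic learns a step-granular value), while the policy loss
exists only at choice steps, the only steps with an action.

At this scale (300 sessions, ~45 s per network on one CPU) the networks
reproduce the qualitative meta-learning signature: the high-side choice
probability rises from ~0.50 to ~0.60, the summed reward-history regression
weight becomes clearly positive (~+1.9) and the summed choice-history weight
clearly negative (~−1.0, reward-independent alternation).

**Unit inactivation.** A random ⌊f·100⌋-unit subset of the concatenated
actor+critic population is silenced (activations clamped to zero) at the
time step immediately before the action-selection step, on ~13% of trials
scheduled with a ≥4-control-trial refractory rule, 50 repeats with fresh
subsets. We read "immediately before action selection" as the penultimate
recurrent step, by parallel with the decoding epoch ("the three time steps
immediately before choice"); silencing at the selection step itself is
available as an option and behaves almost identically in our hands.
Silencing 30% of units reliably lowers the summed reward-history weight on
inactivated versus control trials. The companion claim that the
history-independent |bias| increases does *not* replicate at this scale: our
trained networks are nearly left/right symmetric, so a random 30% subset
displaces the constant part of the choice logit by only ~N(0, 0.09²) —
below the |bias| estimation noise floor of a ~65-trial penalized fit. The
corresponding acceptance test states the property as-is and is expected to
be marginal; we prefer that over weakening the assertion.

## Behavioral models

**History-kernel regression.** Left-choice log-odds are regressed on signed
reward-history differences (r_L − r_R ∈ {−1, 0, 1}) and choice-history
differences (c_L − c_R ∈ {−1, 1}) over lags 1–5 plus a constant bias
(unpenalized L-BFGS logistic fit; the first five trials are dropped as
response rows rather than zero-padded). The two 5-vectors of lag weights are
the session's **policy axes**; cosine similarity / angle between sessions
measures policy stability. Perfect separation and non-convergence are
flagged, not silently accepted.

The control/inactivation split variant fits separate kernels for the two
trial classes in one L2-penalized model (inverse penalty from a 100-point
log grid in [1e−4, 1e4], fivefold CV), with control trials randomly
subsampled to the inactivation count, repeated with the minimum number of
iterations covering every control trial, weights averaged over iterations
and |bias| taken per iteration before averaging.

**Forgetting RL model.** Chosen-side value moves toward the outcome with
separate learning rates for rewarded (α_rew) and unrewarded (α_unr) trials;
the unchosen value decays by a forgetting rate ω per trial; the choice rule
is a softmax on β_ΔQ·(β_0 [+ β_c·C(t−1)] + Q_L − Q_R), with the
previous-choice term β_c only in the deep-RL variant. Values start at
Q_L = Q_R = 0.5 (midpoint of the admissible range; configurable) and are
frozen through lapse trials. Fitting minimizes the L2-penalized negative
log-likelihood with bounded multi-start L-BFGS-B (10 restarts; bounds
α, ω ∈ [0,1], β_ΔQ ∈ [0, 50]); λ is chosen from a 20-point log grid in
[1e−4, 1e2] by tenfold CV on contiguous unshuffled folds, where the value
recursion runs over all trials and only the fold's trials are scored (no
restart artifacts at fold boundaries). The likelihood recursion is
JIT-compiled (numba), making the full CV protocol a few seconds per
session. On teacher-generated data (α_rew = 0.6, α_unr = 0.2, ω = 0.1,
β_ΔQ = 3), median absolute recovery errors for the rates are ≈ 0.04–0.05
over ten 500-trial sessions.

## Trial-difference decoding

Value signals (ΔQ = Q_L − Q_R, ΣQ = Q_L + Q_R, Q_ch = value of the
previously chosen side) and neural activity both carry slow autocorrelation,
so a per-trial regression inflates apparent coding. The decoder therefore
regresses *adjacent-trial differences* of the value signal on
adjacent-trial differences of each neuron's activity (ordinary least
squares; "adjacent" means adjacent within the retained included-trial
sequence). Accuracy is the Pearson correlation of pooled held-out
predictions under tenfold CV on contiguous unshuffled folds. Rank-deficient
designs fall back to the least-norm solution with a flag.

Chance floors: within-session (value differences permuted across rows, 100
shuffles) and cross-session (foreign sessions' value series, circularly
rotated at a random offset — offset 0 allowed — and length-aligned).
Populations larger than 55 cells are decoded by the covering rule: draws of
55 without replacement until every cell is used, the last draw topped up
with re-sampled cells, accuracies averaged.

On drift-only null populations (zero coding weights, smoothed random-walk
drift at 2× the nominal coding scale plus white noise) the trial-difference
decoder stays inside the shuffle-null 95% band while the per-trial decoder
exceeds it — the motivating failure mode, reproduced by construction.

**Coding axes.** A session's decoder weight vector restricted to the
registered shared neurons of a session pair is its coding axis; stability is
the cosine/angle between paired axes. At the generator's default
signal-to-noise (noise SD = coding SD, drift SD = 2× coding SD; CV r ≈
0.75), the cosine between the fitted axis and the generative weights sits
near 0.90: the residual gap is weight-estimation noise (55 weights from
~430 difference rows) plus, when all three correlated value signals are
coded, a genuine estimand mixture. The axis-recovery acceptance test
therefore codes the target signal alone at halved noise (CV r ≈ 0.92),
where the recovery cosine is ≈ 0.92.

The coding-axis/policy-axis relation uses angles (arccos), pairs them per
session pair, and reports a Spearman rank correlation with a permutation
p-value — a deliberately simple substitute for hierarchical mixed-effects
inference that ignores subject-level nesting.

## Synthetic data

The generators provide ground truth for every stage; they emulate

* behavior from the forgetting-RL teacher (or a logistic history-kernel
  teacher) playing the real environment, with configurable lapse rate
  (lapse trials marked excluded, values frozen through them);
* activity as a linear readout of standardized value signals through
  per-neuron Gaussian coding weights, plus smoothed-random-walk drift
  (exponential smoothing timescale 20 trials) and white noise. Defaults
  (noise SD = coding SD, drift SD = 2× coding SD) keep the
  spurious-correlation hazard visible without burying the code;
* longitudinal studies: two interleaved "planes" per subject with disjoint
  persistent neuron IDs, per-session 10% neuron dropout, session pairs two
  apart within a plane, and a rotate-then-freeze schedule under which the
  behavioral reward kernel and every plane's coding weights rotate toward
  random orthogonal directions by the same session-indexed magnitude
  (default 45°·exp(−(k−1)/4)), so policy and coding axes co-rotate early
  and stabilize late;
* inactivation schedules as a renewal process flagging eligible trials with
  probability q = rate/(1 − rate·min_gap), which yields the target long-run
  rate while enforcing the refractory run; rates above 1/(1+min_gap) are
  rejected as infeasible.

What the synthetic data do **not** emulate: calcium-indicator dynamics and
deconvolution artifacts, spiking statistics, imaging registration errors
(neuron identity is exact by construction), within-trial temporal structure
of real activity (epochs are separate tables with gain factors), and
motivational or satiety trends in behavior. Passing tests therefore
establish the correctness and calibration of the *analysis machinery* under
the assumed generative structure, not conclusions about biological tissue.

## Problem sizes

Defaults used by the test suite: 3 networks × 300 training sessions × 500
trials; 50 inactivation repeats per network; 10 teacher sessions for RL
recovery; 5 × 5,000 trials for kernel recovery; 8 null sessions × 40
shuffles for the spurious-correlation check; 2 subjects × 12 sessions for
the longitudinal geometry. These sizes were chosen so the full pipeline
runs on a single CPU in minutes while every statistical assertion retains a
comfortable margin; all are parameters, not constants.
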