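# Methods

This note documents the modelling and analysis choices the package makes,
what its synthetic data do and do not emulate, and the numerical details a
user should know before trusting or extending the results.

## Task and behavioral measure

The modelled task is magnitude reproduction: on each trial a length between
6 and 14 cm is presented and the participant reproduces it. Across trials the
reproductions regress toward the mean of the experienced stimuli (central
tendency). The strength of that pull is the **regression index**
RI = 1 − slope of the ordinary-least-squares fit of reproduced on presented
lengths: 0 is veridical reproduction, 1 is pure reproduction of the prior
mean. RI is deliberately *not* clipped to [0, 1]; anti-regression or
over-compensation (RI < 0) is preserved because clipping would bias
subject-wise condition differences. The prior is defined as the average of all
stimuli scheduled within one condition, not a trial-by-trial running mean; a
running-mean observer variant exists behind a flag (`running_mean_prior`) for
sensitivity analyses, because session-internal prior drift cannot be ruled
out from the task description alone.

Three situational conditions are modelled: individual, mechanical robot and
social robot. Their only difference in the model is behavioral — the strength
of prior reliance encoded in the data — plus the stimulus jitter and trial
dropout that the robot's physical screen touches introduced.

## Synthetic cohort generator

The generator is first-class, tested code, since the original human dataset
is unavailable. It emulates:

- 11 stimulus lengths on the arithmetic grid 6.0, 6.8, …, 14.0 cm (the task
  reports only the range and count; equal spacing is an assumption), each
  presented 6 times per condition in randomized order;
- robot-condition stimulus jitter: additive Gaussian noise with
  sd = 0.62/√(2/π) ≈ 0.777 cm, chosen so the **mean absolute** deviation
  matches the reported 0.62 cm (the task reports a mean absolute variation,
  not a distribution);
- robot-condition trial dropout: i.i.d. Bernoulli with survival probability
  62.66/66, matching the reported mean surviving count. The reported SD of
  3.83 trials is *not* separately matched — a binomial's SD at this rate is
  smaller — and no attempt is made to tune it;
- a mixture observer: reproduced = (1 − ρ)·presented + ρ·prior + ε with
  motor noise ε ~ N(0, 0.3² cm²) by default. ρ is the cell's true regression
  index; OLS on noise-free output recovers it exactly;
- condition-level mean reliances 0.50 / 0.35 / 0.25 for individual /
  mechanical / social with between-subject sd 0.1 (truncated-normal draws in
  [0, 1]). The human study reports only the *ordering* of conditions, not
  numeric values; these defaults preserve the ordering and give subject-wise
  differences of realistic magnitude. The 0.3 cm motor noise is of the order
  of human trial-to-trial scatter relative to the 6–14 cm range.

What the generator does **not** emulate: sequential effects (local drift,
serial dependence), heteroskedastic motor noise, response clipping at the
screen edge, or any perceptual difference between conditions beyond jitter
and dropout. Passing tests therefore show that the pipeline recovers the
structure it generates — linear-Gaussian mixture behavior — not that it would
fit every idiosyncrasy of real participants.

## Trajectory encoding

Scalar lengths are unrolled into straight 22-step paths (20 interior points
between 0 and the length) and mapped affinely onto [−1, 1] using the fixed
range [0, 14] cm shared by all participants and conditions, so every encoded
trajectory starts at exactly −1 and the design maximum ends at +1. Whether
the original analysis normalized per dataset or per fixed range is unstated;
the fixed map keeps train- and test-time encodings consistent. Jittered robot
stimuli can exceed 14 cm by a fraction of a cm; they are clipped to the
maximum with a logged warning. Decoding takes the unsigned difference of the
denormalized start and end points, which makes it applicable to generated
trajectories that are not straight lines; in particular the reproduced length
of a generated trial is decoded from the network's 21 predicted means.

## Internal model (S-CTRNN)

Per time step, with leak 1/τ and no bias terms anywhere:

    u_t = (1 − 1/τ) u_{t−1} + (1/τ)(W_cc c_{t−1} + w_in x_t)
    c_t = tanh(u_t),   μ_t = tanh(w_μ·c_t),   σ²_t = exp(w_σ·c_t) + floor

The exact update rule and output nonlinearities are a declared design choice
(the standard leaky-integration formulation of variance-predicting CTRNNs):
τ = 2 by default and configurable; the tanh mean readout keeps predictions in
the trajectory range; the exponential variance readout keeps σ² positive with
`variance_floor` = 1e-6 guarding the likelihood against degenerate variance.
The prediction read out from c_t targets step t + 1; a 22-step trajectory
yields 21 scored predictions. Initial states u₀ are learnable per
participant × condition cell; weights initialize i.i.d. N(0, 0.1²) and
initial states at 0.

### Likelihood

The output term sums, over scored steps,
−ln(2π σ²_t) − (x_{t+1} − μ_t)²/(2σ²_t); the initial-state term sums, over
all S states and N neurons, −ln(2π σ²_init) − (u₀ − û)²/(2 v_dist) with
v_dist = σ²_init = 1e7 and û a learnable mean. Note the working form carries
no ½ on the log term; the standard Gaussian log-density is available via
`TrainingConfig.standard_log_form`. The maximizing μ is identical under both
forms and the σ² estimate differs only by a constant reparameterization
(the working form's optimum is σ² = residual²/2). With the default huge
σ²_init the quadratic initial-state penalty is effectively flat: states
separate freely, anchored only cosmetically to û.

### Training

Full-batch backpropagation through time with hand-derived gradients
(verified against central finite differences to ≤ 1e-4 relative error for
every weight map, every initial-state component and û) and adaptive-moment
(Adam) gradient ascent. Defaults: 15000 epochs, learning rate 1e-3, no
gradient clipping, 10 independently seeded networks. Two choices deserve
comment:

- **Initial-state learning-rate scale** (default 10×): initial states are
  per-cell parameters that receive gradient mass from only their own
  sequences and must travel far from the common origin to separate
  3 × n_participants dynamics; a larger step for them is the standard remedy
  for embedding-like parameters and substantially accelerates cell
  separation.
- **Scaled-run learning rate**: for few-thousand-epoch runs (tests,
  demonstrations) the package uses 0.01; the 1e-3 default is conservative
  and appropriate for the full 15000-epoch budget.

Training is teacher-forced on the raw encoded stimuli with H_prior =
H_sensor = 1; the Bayesian module is not in the training loop by default,
since H = 1 integration with the default sensory variance is input-dominated
and the training-time role of the module is ambiguous in the source
formulation. A flag (`integrate_in_training`) feeds posterior means instead;
in that variant the integrated signal is treated as given (no gradient is
propagated through the integration itself), which is documented rather than
hidden. Training aborts with the epoch index if the loss becomes non-finite;
seeded runs are bitwise reproducible.

## Bayesian integration and generation

The posterior of a Gaussian prediction (μ_prior, H_prior σ²_prior) and a
sensory sample (x, H_sensor σ²_sensor) is the precision-weighted fusion given
in the README. σ²_sensor is nowhere specified by the source analysis; the
package fixes it globally at 1e-3 in normalized units — small enough that
H = 1 generation tracks the input, large enough that H_prior ≈ 0.05 visibly
drags generation toward the internal model — and reports sweeps as functions
of the precision *ratio*, in which this constant cancels. Only means are
propagated during generation (no posterior sampling; a sampling flag exists
for variance-sensitive extensions), so generation is deterministic.

Two generation modes exist and are used deliberately:

- `inference="off"` (open loop): the raw encoded stimulus drives the
  network. This is the mode for replication checks (does the trained model
  reproduce each cell's RI?), because it measures the internal model itself.
- `inference="on"` (closed loop through the Bayesian module): the posterior
  mean of prediction and input drives the next step. This is the mode for
  the H-sweeps, whose whole point is to rescale the fused precisions. At
  H = (1, 1) the two modes agree within the model's own training error; the
  residual gap depends on the ratio of the learned σ²_prior to σ²_sensor.

## Experiments

**Replication / parameter recovery.** After training on a synthetic cohort,
the per-cell RI of open-loop regeneration is compared with the generating ρ.
The test suite runs this at a scaled-down size chosen to keep the suite
fast while leaving the phenomenon intact: 6 participants, condition means
(0.50, 0.35, 0.25), 0.3 cm noise, 2 networks × 2000 epochs at the scaled-run
learning rate. The acceptance bound is ±0.07 per cell on the ensemble-mean
RI (averaging the networks' RIs per cell, as in pooling networks when
comparing model and human data); note ±0.03 of that budget is the sampling
error by which the *data's own* empirical RI differs from ρ at 66 trials.
The subject-wise ordering individual−social > mechanical−social > 0 must
also be reproduced by the model's own behavior.

**H sweeps (prior vs sensory reliance).** Using only the baseline (social)
condition's initial states, stimuli are regenerated at each H on the grid
0.5 … 0.05 (denser below 0.1, where behavior changes fastest), and the
median across participants of the per-participant RI difference vs the H = 1
regeneration is recorded per network. The median is exactly 0 at H = 1 and
non-decreasing as H_prior falls — the hyperbolic posterior weight
w = 1/(1 + H_prior σ²_prior/(H_sensor σ²_sensor)) decays monotonically and
nonlinearly in H_prior. The ratio-matched H_sensor sweep (grid 1/H) yields
identical generated means to ≤ 1e-9 — the posterior mean depends only on the
precision ratio — while posterior variances differ by the factor H. Matches
between a sweep median and a reference difference are declared at the grid
value minimizing the absolute gap; no interpolation between grid points.
Sweeping from the *individual* (strong-prior) states never pushes the
difference below its H = 1 value: the network was trained on behavioral, not
veridical, targets, so no amount of extra sensory reliance recovers accuracy
the training data never contained.

**Statistics.** Condition contrasts use sign-flip permutation tests on the
paired per-participant differences (exhaustive enumeration when 2ⁿ fits the
permutation budget, Monte-Carlo with add-one correction otherwise) instead of
linear mixed-effect models; the per-subject deltas are exported so any model
can be fitted externally. Interval summaries are 80% percentile intervals
(whether the original intervals were percentile or normal-theory is
unstated).

## Neural dynamics

Activation traces c_t (22 × 25 per trial) are recorded during closed-loop
generation. Trials are binned into length categories — the distinct rounded
(0.1 cm) presented lengths whose count exceeds a threshold. The absolute
threshold appropriate to the full human-scale dataset (> 100 presentations)
does not transfer to arbitrary cohort sizes, so the default scales as
0.8 × repetitions × n_participants, which preserves the 11-category
structure at any scale; trials farther from every category than half the
minimum category gap are dropped with a logged count. On unjittered,
undropped data the categories are exactly the 11 design lengths.

The between-participant distance at each time step is the mean squared
difference (1/N)Σᵢ(xᵢ−yᵢ)² — implemented exactly as printed, without a
square root; an RMS variant sits behind a flag in case the root was intended
— averaged over all unordered participant pairs within one length category
and condition, then over categories, so length differences do not inflate
the measure. When a participant has several trials in a category, their
trace is the per-time-step average of those trials: distances are defined
*between participants*, so within-participant replicates are collapsed. Each
network's activations are normalized to [0, 1] jointly across its whole
tensor first; profiles are averaged across networks with standard errors.
Categories with fewer than two participants are excluded with a warning.

PCA embeddings are fitted on the pooled activation vectors of *all* time
steps of one network, so t = 0 (initial states) and t = 21 (length-
differentiated end states) share one space; per-time-step fitting is
available by flag. Rank-deficient inputs yield fewer components rather than
failing. Per-condition means and 2 × 2 covariances of the embedded points
are exported. The qualitative endpoint contrast — the strong-prior condition
showing relatively higher t = 0 and lower t = 21 variability — is reported
in the outputs but not asserted by tests, since it depends on training
idiosyncrasies.

## Pipeline

A run is a pure function of (config, seed): each stage's seed derives
deterministically from the global seed, unknown config keys are rejected,
every figure-style quantity has a CSV/JSON twin, and a manifest records the
config hash plus per-stage file checksums; identical runs are verifiable by
checksum equality, and `--resume` skips stages whose outputs are unchanged.
The CLI (`tendnet simulate|train|sweep|dynamics|report|all|validate`) is a
thin wrapper over the library.

## Known limitations

- The exact τ, nonlinearities and optimizer of the original analysis are
  unrecoverable from its description; the declared defaults are conventional,
  not inferred.
- σ²_sensor is a single global constant; condition-dependent sensory
  precision is not modelled (and is one obvious extension).
- The closed-loop H = 1 generation is only approximately equal to open-loop
  generation; the gap grows where the learned predictive variance is small
  relative to σ²_sensor.
- Initial-state likelihood uses v_dist = σ²_init in both the log and the
  quadratic term, as specified by its source formulation, even though the
  double role is redundant at the default value.
- Figure-only quantities of the original human-data analysis (exact
  best-matching H values, the explained-variance percentage, mixed-model
  p-values) are properties of networks trained on the unavailable human
  dataset and are out of scope; the package reproduces the corresponding
  *structural and qualitative* results on synthetic cohorts.
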