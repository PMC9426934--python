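# tendnet

A predictive-coding model of the **central-tendency effect** — the tendency to
reproduce a stimulus magnitude shifted toward the mean of previously
experienced stimuli — and of how **social context** modulates it.

The package is written for computational cognitive scientists who want to
replicate, at the level of a trainable neural system, behavioral findings from
a length-reproduction task performed in three situational conditions: alone
(*individual*), with a robot acting mechanically (*mechanical*), and with the
same robot acting socially (*social*). Humans show the strongest pull toward
the prior when alone and the weakest with the social robot. The model asks
whether that difference is explainable as a continuous change in the
*precision* assigned to prior versus sensory information.

## The model

Each stimulus length is unrolled into a 22-step one-dimensional trajectory,
normalized to [−1, 1]. A **stochastic continuous-time recurrent neural
network (S-CTRNN)** with N = 25 recurrent units serves as the internal model.
Fed the trajectory step by step, it predicts the mean and variance of the next
step of the participant's *reproduction*:

```
u_t  = (1 − 1/τ) u_{t−1} + (1/τ) (W_cc c_{t−1} + w_in x_t)
c_t  = tanh(u_t)
μ_prior,t    = tanh(w_μ · c_t)
σ²_prior,t   = exp(w_σ · c_t) + floor
```

One learnable initial state u₀ per participant × condition (S = 3 · 25 = 75
for the full design) lets a single network replicate every cell of the
experiment. Training maximizes ln L = ln L_out + ln L_init by full-batch
backpropagation through time, where L_out is the Gaussian likelihood of the
reproduction trajectory under the predicted (μ, σ²) and L_init anchors the
initial states to a learnable mean with a very large target variance
(σ²_init = 1e7), so they separate freely.

A **Bayesian inference module** fuses each prediction with the raw input by
precision weighting, with reliance factors H on each variance:

```
σ²_post = (H_sensor σ²_sensor)(H_prior σ²_prior) / (H_sensor σ²_sensor + H_prior σ²_prior)
μ_post  = σ²_post · ( μ_prior / (H_prior σ²_prior) + x / (H_sensor σ²_sensor) )
```

Sweeping H_prior below 1 (or, ratio-matched, H_sensor = 1/H_prior above 1)
makes generation increasingly prior-driven, raising the regression index
RI = 1 − slope of reproduced-vs-presented lengths. The package's experiments
quantify how far such sweeps move the model from the social condition's
behavior toward the mechanical and individual conditions, and analyze the
recurrent layer's state-space dynamics (PCA embeddings and length-stratified
between-participant activation distances over time).

Because the original human dataset is not public, a first-class synthetic
cohort generator reproduces the task's structure (11 lengths from 6–14 cm × 6
repetitions, stimulus jitter and trial dropout in the robot conditions,
condition-ordered prior reliance) so every stage is testable end to end.

## Worked example

```python
import numpy as np
from tendnet import (generate_cohort, regression_indices_by_cell,
                     subject_wise_differences, summarize_differences,
                     paired_permutation_test)

table = generate_cohort(n_participants=25, seed=1)
ri = regression_indices_by_cell(table)
print(ri.groupby("condition")["regression_index"].mean().round(3))

diffs = subject_wise_differences(ri)
print(summarize_differences(diffs).round(3).to_string(index=False))

d = diffs.query("pair == 'mechanical-social'")["delta_ri"].to_numpy()
p, info = paired_permutation_test(d, np.zeros_like(d), n_perm=10000, seed=0)
print(f"mechanical-social: mean delta = {info['mean_diff']:.3f}, p = {p:.4f}")
```

prints

```
condition
individual    0.509
mechanical    0.357
social        0.250
Name: regression_index, dtype: float64
                 pair  mean    sd     lo    hi  n
individual-mechanical 0.151 0.151 -0.046 0.341 25
    individual-social 0.258 0.154  0.087 0.408 25
    mechanical-social 0.107 0.140 -0.100 0.286 25
mechanical-social: mean delta = 0.107, p = 0.0014
```

The per-condition mean regression indices recover the generating reliances
(0.50 / 0.35 / 0.25); the subject-wise differences are ordered
individual−social > mechanical−social > 0, and the sign-flip permutation test
confirms the mechanical−social difference is reliably positive. The `lo`/`hi`
columns are 80% percentile intervals across participants.

The full pipeline — simulate, train an ensemble of networks, run the
H-parameter sweeps and the dynamics analyses — is driven by the CLI:

```
tendnet all --seed 1 --out runs/demo            # default (full-scale) config
tendnet sweep --config my_config.yaml --out runs/demo
tendnet validate runs/demo/behavior.csv
```

Every figure-style result has a machine-readable CSV/JSON twin in the output
directory, together with a checksum manifest for reproducibility.

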