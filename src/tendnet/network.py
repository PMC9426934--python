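"""Stochastic continuous-time recurrent network (S-CTRNN) internal model.

The internal model is a 25-unit leaky recurrent network that, fed a
normalized stimulus trajectory step by step, predicts the mean and variance of
the *next* step of the participant's reproduction.  Per time step:

    u_t = (1 - 1/tau) * u_{t-1} + (1/tau) * (W_cc c_{t-1} + w_in x_t)
    c_t = tanh(u_t)
    mu_t = tanh(w_mu . c_t)          # predicted mean of step t+1
    sigma2_t = exp(w_var . c_t) + variance_floor

All mappings are linear with no bias terms.  One learnable initial state
u_0 per participant x condition lets a single network replicate every cell of
the experiment: 25 participants x 3 conditions = 75 initial states.

Training maximizes ln L = ln L_out + ln L_init by full-batch backpropagation
through time with adaptive-moment (Adam) updates:

    ln L_out  = sum_t sum_i ( -ln(2 pi sigma2_{t,i})
                              - (x_{t+1,i} - mu_{t,i})^2 / (2 sigma2_{t,i}) )
    ln L_init = sum_s sum_n ( -ln(2 pi sigma2_init)
                              - (u(s)_{0,n} - uhat_n)^2 / (2 v_dist) )

with v_dist = sigma2_init = 1e7 by default, so initial states separate almost
freely while remaining anchored to a learnable common mean uhat.  The log-term
coefficient follows the working form above (no 1/2 on the log term); the
standard Gaussian log-density (1/2 on the log term) is available via
``TrainingConfig.standard_log_form`` — the maximizing mean is identical and
the variance estimate differs only by a constant reparameterization.

Gradients for every weight map and every initial-state component are derived
by hand and checked against central finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codec import N_TIME_STEPS, NormalizationSpec, encode_lengths, trajectory_to_length
from .inference import HParams, SensoryModel, posterior_mean

logger = logging.getLogger(__name__)

N_CONTEXT = 25  # recurrent-layer size sufficient for the 1-d task
DEFAULT_SIGMA2_INIT = 1e7


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class NumericOverflowError(RuntimeError):
    """Raised when a forward pass produces a non-finite state."""


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------


@dataclass
class SCTRNNParams:
    """Weight maps and dynamics constants of the internal model (no biases)."""

    w_in: np.ndarray  # (N,)  input -> context
    w_cc: np.ndarray  # (N, N) context -> context
    w_mu: np.ndarray  # (N,)  context -> mean readout
    w_var: np.ndarray  # (N,)  context -> variance readout
    tau: float = 2.0
    variance_floor: float = 1e-6

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_cc = np.asarray(self.w_cc, dtype=float)
        self.w_mu = np.asarray(self.w_mu, dtype=float)
        self.w_var = np.asarray(self.w_var, dtype=float)
        n = self.w_in.shape[0]
        if self.w_cc.shape != (n, n) or self.w_mu.shape != (n,) or self.w_var.shape != (n,):
            raise ValueError("inconsistent weight shapes")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")

    @property
    def n_context(self) -> int:
        return self.w_in.shape[0]

    @classmethod
    def initialize(cls, n_context: int = N_CONTEXT, tau: float = 2.0, variance_floor: float = 1e-6, seed: int = 0) -> "SCTRNNParams":
        """Fresh network with i.i.d. Normal(0, 0.1^2) weights."""
        rng = np.random.default_rng(seed)
        return cls(
            w_in=rng.normal(0.0, 0.1, n_context),
            w_cc=rng.normal(0.0, 0.1, (n_context, n_context)),
            w_mu=rng.normal(0.0, 0.1, n_context),
            w_var=rng.normal(0.0, 0.1, n_context),
            tau=tau,
            variance_floor=variance_floor,
        )


@dataclass
class InitialStateBank:
    """Learnable initial internal states, one per participant x condition."""

    states: np.ndarray  # (S, N) pre-activation vectors u_0
    u_hat: np.ndarray  # (N,) learnable mean of all initial states
    sigma2_init: float = DEFAULT_SIGMA2_INIT
    index: dict = field(default_factory=dict)  # (participant_id, condition) -> row

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.u_hat = np.asarray(self.u_hat, dtype=float)
        if self.sigma2_init <= 0:
            raise ValueError("sigma2_init must be positive")
        if self.index:
            rows = sorted(self.index.values())
            if rows != list(range(self.states.shape[0])):
                raise ValueError("index must be a bijection onto state rows")

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def row(self, participant_id: str, condition: str) -> int:
        key = (str(participant_id), str(condition))
        if key not in self.index:
            raise KeyError(f"no initial state for participant/condition {key}")
        return self.index[key]

    def state(self, participant_id: str, condition: str) -> np.ndarray:
        return self.states[self.row(participant_id, condition)]

    @classmethod
    def for_cells(cls, cells, n_context: int = N_CONTEXT, sigma2_init: float = DEFAULT_SIGMA2_INIT) -> "InitialStateBank":
        """Zero-initialized bank for the given (participant, condition) cells."""
        cells = sorted({(str(p), str(c)) for p, c in cells})
        return cls(
            states=np.zeros((len(cells), n_context)),
            u_hat=np.zeros(n_context),
            sigma2_init=sigma2_init,
            index={cell: i for i, cell in enumerate(cells)},
        )


@dataclass(frozen=True)
class GaussianPrediction:
    """One-step-ahead predicted mean and variance of the next input."""

    mu: float
    sigma2: float


@dataclass
class ForwardTrace:
    """Full record of one generated trajectory.

    ``u``/``c`` hold the 22 internal states and activations; ``mu``/``sigma2``
    the 21 next-step predictions (the prediction at index t, read out from
    c_t, targets step t+1); ``inputs_fed`` the signal actually fed to the
    network (raw input, or the Bayesian posterior mean during closed-loop
    generation).
    """

    u: np.ndarray  # (22, N)
    c: np.ndarray  # (22, N)
    mu: np.ndarray  # (21,)
    sigma2: np.ndarray  # (21,)
    inputs_fed: np.ndarray  # (22,)


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run."""

    epochs: int = 15000
    learning_rate: float = 1e-3
    initial_state_lr_scale: float = 10.0
    optimizer_name: str = "adam"
    n_networks: int = 10
    seeds: tuple[int, ...] | None = None
    gradient_clip: float | None = None
    tau: float = 2.0
    variance_floor: float = 1e-6
    sigma2_init: float = DEFAULT_SIGMA2_INIT
    n_context: int = N_CONTEXT
    standard_log_form: bool = False  # 1/2 coefficient on the Gaussian log term
    integrate_in_training: bool = False  # feed Bayesian posterior means during training
    log_every: int = 0  # epochs between progress log lines (0 = silent)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.n_networks:
            raise ValueError("seeds length must equal n_networks")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")

    @property
    def log_coeff(self) -> float:
        return 0.5 if self.standard_log_form else 1.0


@dataclass
class ModelBundle:
    """A trained internal model together with its codec and provenance."""

    params: SCTRNNParams
    bank: InitialStateBank
    spec: NormalizationSpec
    config: TrainingConfig | None = None
    seed: int | None = None

    def save(self, path) -> None:
        """Persist as a single .npz archive plus a JSON provenance sidecar."""
        path = str(path)
        index_keys = sorted(self.bank.index, key=lambda k: self.bank.index[k])
        np.savez(
            path,
            w_in=self.params.w_in,
            w_cc=self.params.w_cc,
            w_mu=self.params.w_mu,
            w_var=self.params.w_var,
            tau=self.params.tau,
            variance_floor=self.params.variance_floor,
            states=self.bank.states,
            u_hat=self.bank.u_hat,
            sigma2_init=self.bank.sigma2_init,
            index_keys=np.array([f"{p}\t{c}" for p, c in index_keys]),
            source_min_cm=self.spec.source_min_cm,
            source_max_cm=self.spec.source_max_cm,
        )
        sidecar = {"seed": self.seed, "config": None if self.config is None else vars(self.config).copy()}
        if sidecar["config"] is not None and sidecar["config"].get("seeds") is not None:
            sidecar["config"]["seeds"] = list(sidecar["config"]["seeds"])
        with open(path + ".json" if not path.endswith(".npz") else path[:-4] + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(str(path), allow_pickle=False) as z:
            params = SCTRNNParams(
                w_in=z["w_in"], w_cc=z["w_cc"], w_mu=z["w_mu"], w_var=z["w_var"],
                tau=float(z["tau"]), variance_floor=float(z["variance_floor"]),
            )
            keys = [tuple(s.split("\t")) for s in z["index_keys"]]
            bank = InitialStateBank(
                states=z["states"], u_hat=z["u_hat"], sigma2_init=float(z["sigma2_init"]),
                index={k: i for i, k in enumerate(keys)},
            )
            spec = NormalizationSpec(float(z["source_min_cm"]), float(z["source_max_cm"]))
        return cls(params=params, bank=bank, spec=spec)


# ---------------------------------------------------------------------------
# forward dynamics
# ---------------------------------------------------------------------------


def _readout(params: SCTRNNParams, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance readout from activations (vectorized over leading axes)."""
    mu = np.tanh(c @ params.w_mu)
    sigma2 = np.exp(c @ params.w_var) + params.variance_floor
    return mu, sigma2


def forward_step(
    params: SCTRNNParams, u_prev: np.ndarray, c_prev: np.ndarray, x_t: float
) -> tuple[np.ndarray, np.ndarray, GaussianPrediction]:
    """One leaky-integration step; the returned prediction targets step t+1."""
    u_prev = np.asarray(u_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    leak = 1.0 / params.tau
    u_t = (1.0 - leak) * u_prev + leak * (params.w_cc @ c_prev + params.w_in * float(x_t))
    if not np.all(np.isfinite(u_t)):
        raise NumericOverflowError("non-finite internal state in forward_step")
    c_t = np.tanh(u_t)
    mu, sigma2 = _readout(params, c_t)
    return u_t, c_t, GaussianPrediction(float(mu), float(sigma2))


def predict_sequence(params: SCTRNNParams, initial_state: np.ndarray, inputs: np.ndarray) -> ForwardTrace:
    """Open-loop (teacher-forced) forward pass over a full 22-step trajectory.

    Emits 22 internal states and 21 next-step predictions; the prediction at
    index t is read out from c_t and targets inputs[t + 1].
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != (N_TIME_STEPS,):
        raise ValueError(f"inputs must have shape ({N_TIME_STEPS},), got {inputs.shape}")
    n = params.n_context
    u = np.empty((N_TIME_STEPS, n))
    c = np.empty((N_TIME_STEPS, n))
    u[0] = np.asarray(initial_state, dtype=float)
    c[0] = np.tanh(u[0])
    for t in range(1, N_TIME_STEPS):
        u[t], c[t], _ = forward_step(params, u[t - 1], c[t - 1], inputs[t])
    mu, sigma2 = _readout(params, c[:-1])
    return ForwardTrace(u=u, c=c, mu=mu, sigma2=sigma2, inputs_fed=inputs.copy())


def _generate_batch(
    params: SCTRNNParams,
    u0: np.ndarray,  # (B, N)
    x: np.ndarray,  # (B, 22) raw encoded stimuli
    h: HParams,
    sm: SensoryModel,
    inference: str,
):
    """Vectorized behavior generation for a batch of trials.

    With ``inference='on'`` the input actually fed at step t+1 is the
    precision-weighted posterior mean of the network's prediction for t+1 and
    the raw input x_{t+1}; with ``'off'`` the raw input is fed unchanged.
    Only the posterior/predicted mean is propagated (no sampling), so
    generation is deterministic.
    """
    if inference not in ("on", "off"):
        raise ValueError(f"inference must be 'on' or 'off', got {inference!r}")
    leak = 1.0 / params.tau
    B, n = u0.shape
    u = np.empty((B, N_TIME_STEPS, n))
    c = np.empty((B, N_TIME_STEPS, n))
    mu = np.empty((B, N_TIME_STEPS - 1))
    sigma2 = np.empty((B, N_TIME_STEPS - 1))
    fed = np.empty((B, N_TIME_STEPS))
    fed[:, 0] = x[:, 0]
    u[:, 0] = u0
    c[:, 0] = np.tanh(u0)
    for t in range(N_TIME_STEPS - 1):
        mu[:, t], sigma2[:, t] = _readout(params, c[:, t])
        if inference == "on":
            fed[:, t + 1] = posterior_mean(mu[:, t], sigma2[:, t], x[:, t + 1], sm, h)
        else:
            fed[:, t + 1] = x[:, t + 1]
        a = c[:, t] @ params.w_cc.T + np.outer(fed[:, t + 1], params.w_in)
        u[:, t + 1] = (1.0 - leak) * u[:, t] + leak * a
        c[:, t + 1] = np.tanh(u[:, t + 1])
    if not np.all(np.isfinite(u)):
        raise NumericOverflowError("non-finite internal state during generation")
    return u, c, mu, sigma2, fed


def generate_behavior(
    params: SCTRNNParams,
    bank: InitialStateBank,
    participant_id: str,
    condition: str,
    presented_cm: float,
    h: HParams = HParams(),
    sm: SensoryModel = SensoryModel(),
    inference: str = "on",
    spec: NormalizationSpec = NormalizationSpec(),
) -> tuple[float, ForwardTrace]:
    """Generate one reproduced length from the bound initial state.

    The stimulus is encoded as a trajectory, the network is initialized with
    the (participant, condition) initial state, and only mean signals are
    propagated, so output is deterministic.  The reproduced length is the
    unsigned difference between the denormalized start and end points of the
    generated mean trajectory (the 21 predicted means).
    """
    x = encode_lengths([presented_cm], spec, clip=True)
    u0 = bank.state(participant_id, condition)[None, :]
    u, c, mu, sigma2, fed = _generate_batch(params, u0, x, h, sm, inference)
    # the reproduced trajectory is the sequence of predicted means; its start
    # and end points define the reproduced length
    length = trajectory_to_length(mu[0], spec)
    trace = ForwardTrace(u=u[0], c=c[0], mu=mu[0], sigma2=sigma2[0], inputs_fed=fed[0])
    return length, trace


def generate_table_behavior(
    params: SCTRNNParams,
    bank: InitialStateBank,
    table: pd.DataFrame,
    h: HParams = HParams(),
    sm: SensoryModel = SensoryModel(),
    inference: str = "on",
    spec: NormalizationSpec = NormalizationSpec(),
    *,
    state_condition: str | None = None,
    return_traces: bool = False,
):
    """Regenerate every trial of a behavior table with the model.

    Returns a copy of the table with ``reproduced_cm`` replaced by the model's
    output (and optionally the stacked activation traces).  With
    ``state_condition`` set, the initial states of that condition are used for
    every trial regardless of the trial's own condition — the mechanism of the
    H-sweep experiments, which replay one condition's stimuli through another
    condition's internal dynamics.
    """
    rows = [
        bank.row(p, state_condition if state_condition is not None else c)
        for p, c in zip(table["participant_id"], table["condition"])
    ]
    x = encode_lengths(table["presented_cm"].to_numpy(), spec, clip=True)
    u, c, mu, sigma2, fed = _generate_batch(params, bank.states[rows], x, h, sm, inference)
    lengths = np.abs(spec.denormalize(mu[:, -1]) - spec.denormalize(mu[:, 0]))
    out = table.copy()
    out["reproduced_cm"] = lengths
    if return_traces:
        return out, {"u": u, "c": c, "mu": mu, "sigma2": sigma2, "inputs_fed": fed}
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def log_likelihood_out(trace: ForwardTrace, target: np.ndarray, log_coeff: float = 1.0) -> float:
    """Output log-likelihood of one trajectory under the trace's predictions.

    The prediction at index t is scored against target step t+1.  With the
    working form (log_coeff = 1) perfect predictions at sigma2 = 1/(2 pi)
    yield exactly 0.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (N_TIME_STEPS,):
        raise ValueError(f"target must have shape ({N_TIME_STEPS},)")
    mu, s2 = trace.mu, trace.sigma2
    if np.any(s2 <= 0):
        raise ValueError("non-positive predicted variance")
    e = target[1:] - mu
    return float(np.sum(-log_coeff * np.log(2.0 * np.pi * s2) - e**2 / (2.0 * s2)))


def log_likelihood_init(bank: InitialStateBank, log_coeff: float = 1.0) -> float:
    """Initial-state log-likelihood over all S states and N neurons.

    The quadratic term uses v_dist = sigma2_init (default 1e7), so with the
    default it is almost flat: states separate freely while the log term
    contributes the constant -S * N * log_coeff * ln(2 pi sigma2_init).
    """
    d = bank.states - bank.u_hat
    s, n = bank.states.shape
    return float(
        -s * n * log_coeff * np.log(2.0 * np.pi * bank.sigma2_init)
        - np.sum(d**2) / (2.0 * bank.sigma2_init)
    )


# ---------------------------------------------------------------------------
# training (full-batch BPTT, Adam ascent)
# ---------------------------------------------------------------------------


def _build_dataset(tables: pd.DataFrame, spec: NormalizationSpec, bank: InitialStateBank):
    x = encode_lengths(tables["presented_cm"].to_numpy(), spec, clip=True)
    y = encode_lengths(tables["reproduced_cm"].to_numpy(), spec, clip=True)
    idx = np.array([bank.row(p, c) for p, c in zip(tables["participant_id"], tables["condition"])])
    return x, y, idx


def _forward_batch(params: SCTRNNParams, u0: np.ndarray, x: np.ndarray):
    """Teacher-forced batch forward pass; returns state/readout histories."""
    leak = 1.0 / params.tau
    B, n = u0.shape
    c = np.empty((B, N_TIME_STEPS, n))
    u = np.empty((B, N_TIME_STEPS, n))
    u[:, 0] = u0
    c[:, 0] = np.tanh(u0)
    for t in range(1, N_TIME_STEPS):
        a = c[:, t - 1] @ params.w_cc.T + np.outer(x[:, t], params.w_in)
        u[:, t] = (1.0 - leak) * u[:, t - 1] + leak * a
        c[:, t] = np.tanh(u[:, t])
    mu = np.tanh(c[:, :-1] @ params.w_mu)  # (B, 21)
    v = c[:, :-1] @ params.w_var
    sigma2 = np.exp(v) + params.variance_floor
    return u, c, mu, sigma2


def _loss_and_grads(
    params: SCTRNNParams,
    bank: InitialStateBank,
    x: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    log_coeff: float,
    fed: np.ndarray | None = None,
):
    """ln L and its gradients w.r.t. all weights, initial states and uhat.

    ``fed`` optionally overrides the signal driving the recurrent dynamics
    (used by the in-loop-integration training variant; gradients through the
    integration itself are not propagated — the fed signal is treated as
    given, which the open-question discussion in the methods note covers).
    """
    drive = x if fed is None else fed
    u0 = bank.states[idx]
    u, c, mu, sigma2 = _forward_batch(params, u0, drive)
    B, n = u0.shape
    leak = 1.0 / params.tau

    e = y[:, 1:] - mu  # (B, 21)
    ll_out = float(np.sum(-log_coeff * np.log(2.0 * np.pi * sigma2) - e**2 / (2.0 * sigma2)))
    ll_init = log_likelihood_init(bank, log_coeff)

    # per-step readout gradients
    dmu = e / sigma2
    dm = dmu * (1.0 - mu**2)  # pre-tanh mean readout
    ds2 = -log_coeff / sigma2 + e**2 / (2.0 * sigma2**2)
    dv = ds2 * (sigma2 - params.variance_floor)  # d sigma2 / d v = exp(v)

    g = {
        "w_in": np.zeros(n),
        "w_cc": np.zeros((n, n)),
        "w_mu": np.einsum("bt,btn->n", dm, c[:, :-1]),
        "w_var": np.einsum("bt,btn->n", dv, c[:, :-1]),
    }
    gu_next = np.zeros((B, n))
    for t in range(N_TIME_STEPS - 1, -1, -1):
        if t < N_TIME_STEPS - 1:
            gc = dm[:, t, None] * params.w_mu + dv[:, t, None] * params.w_var
            gc += leak * (gu_next @ params.w_cc)
            g["w_cc"] += leak * gu_next.T @ c[:, t]
            g["w_in"] += leak * gu_next.T @ drive[:, t + 1]
        else:
            gc = np.zeros((B, n))  # the last activation feeds no scored readout
        gu = gc * (1.0 - c[:, t] ** 2) + (1.0 - leak) * gu_next
        gu_next = gu

    g_states = np.zeros_like(bank.states)
    np.add.at(g_states, idx, gu_next)
    g_states += -(bank.states - bank.u_hat) / bank.sigma2_init
    g_uhat = np.sum(bank.states - bank.u_hat, axis=0) / bank.sigma2_init
    g["states"] = g_states
    g["u_hat"] = g_uhat
    return ll_out, ll_init, g, (u, c, mu, sigma2)


class _Adam:
    """Adaptive-moment gradient *ascent* on a dict of arrays."""

    def __init__(self, shapes: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def train(
    tables: pd.DataFrame,
    spec: NormalizationSpec = NormalizationSpec(),
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    sm: SensoryModel = SensoryModel(),
) -> tuple[SCTRNNParams, InitialStateBank, pd.DataFrame]:
    """Train one network on a behavior table.

    Inputs are the encoded presented stimuli; targets the encoded
    reproductions; every training trajectory is bound to the initial state of
    its (participant, condition) cell.  Returns the trained parameters, the
    initial-state bank, and a loss history (epoch, neg_L, neg_L_out,
    neg_L_init).  Fully deterministic given ``seed``.
    """
    cells = set(zip(tables["participant_id"].astype(str), tables["condition"].astype(str)))
    counts = tables.groupby(["participant_id", "condition"]).size()
    if counts.min() < 1 or len(cells) == 0:
        raise ValueError("every (participant, condition) cell needs at least one trial")

    params = SCTRNNParams.initialize(config.n_context, config.tau, config.variance_floor, seed=seed)
    bank = InitialStateBank.for_cells(cells, config.n_context, config.sigma2_init)
    x, y, idx = _build_dataset(tables, spec, bank)
    log_coeff = config.log_coeff

    shapes = {
        "w_in": params.w_in.shape,
        "w_cc": params.w_cc.shape,
        "w_mu": params.w_mu.shape,
        "w_var": params.w_var.shape,
        "states": bank.states.shape,
        "u_hat": bank.u_hat.shape,
    }
    opt = _Adam(shapes, config.learning_rate)
    history = np.empty((config.epochs, 4))
    for epoch in range(config.epochs):
        fed = None
        if config.integrate_in_training:
            _, _, mu, sigma2 = _forward_batch(params, bank.states[idx], x)
            fed = x.copy()
            fed[:, 1:] = posterior_mean(mu, sigma2, x[:, 1:], sm, HParams(1.0, 1.0))
        ll_out, ll_init, g, _ = _loss_and_grads(params, bank, x, y, idx, log_coeff, fed=fed)
        loss = -(ll_out + ll_init)
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch)
        history[epoch] = (epoch, loss, -ll_out, -ll_init)
        if config.gradient_clip is not None:
            norm = np.sqrt(sum(np.sum(gr**2) for gr in g.values()))
            if norm > config.gradient_clip:
                g = {k: gr * (config.gradient_clip / norm) for k, gr in g.items()}
        upd = opt.step(g)
        params.w_in += upd["w_in"]
        params.w_cc += upd["w_cc"]
        params.w_mu += upd["w_mu"]
        params.w_var += upd["w_var"]
        # initial states are per-cell parameters that must travel far to
        # separate the 3 x n_participants dynamics; they take larger steps
        bank.states += config.initial_state_lr_scale * upd["states"]
        bank.u_hat += config.initial_state_lr_scale * upd["u_hat"]
        if config.log_every and epoch % config.log_every == 0:
            logger.info("epoch %d: -L = %.4f (-L_out = %.4f)", epoch, loss, -ll_out)
    hist = pd.DataFrame(history, columns=["epoch", "neg_L", "neg_L_out", "neg_L_init"])
    hist["epoch"] = hist["epoch"].astype(int)
    return params, bank, hist


def train_ensemble(
    tables: pd.DataFrame,
    spec: NormalizationSpec = NormalizationSpec(),
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> list[ModelBundle]:
    """Train ``config.n_networks`` independent networks (distinct seeds)."""
    if config.seeds is not None:
        seeds = list(config.seeds)
    else:
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(config.n_networks)]
    bundles = []
    for i, net_seed in enumerate(seeds):
        logger.info("training network %d/%d (seed %d)", i + 1, len(seeds), net_seed)
        params, bank, hist = train(tables, spec, config, seed=net_seed)
        bundle = ModelBundle(params=params, bank=bank, spec=spec, config=replace(config, seeds=tuple(seeds)), seed=net_seed)
        bundle.loss_history = hist
        bundles.append(bundle)
    return bundles
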