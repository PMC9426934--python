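"""Synthetic length-reproduction behavior with the structure of the tablet task.

The human study this package models had 25 participants reproduce visual
lengths on a touch screen in three situational conditions — alone
(``individual``), with a robot acting mechanically (``mechanical``), and with
the same robot acting socially (``social``).  Eleven lengths spanning 6-14 cm
were each shown 6 times per condition in randomized order.  In the robot
conditions the robot's finger touch introduced small stimulus jitter
(mean absolute deviation 0.62 cm) and occasional trial loss (on average 62.66
of 66 trials survived).

The generator emulates that structure with a mixture observer: each
participant x condition cell has a true prior reliance rho (the regression
index), and every reproduction is

    reproduced = (1 - rho) * presented + rho * prior_mean + motor noise,

where the prior mean is the average of all stimuli scheduled in that
condition.  Condition-level mean reliances default to 0.50 / 0.35 / 0.25 for
individual / mechanical / social, preserving the ordering observed in humans
(strongest central tendency alone, weakest with the social robot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

INDIVIDUAL = "individual"
MECHANICAL = "mechanical"
SOCIAL = "social"
CONDITIONS = (INDIVIDUAL, MECHANICAL, SOCIAL)
ROBOT_CONDITIONS = (MECHANICAL, SOCIAL)

BEHAVIOR_COLUMNS = ["participant_id", "condition", "trial_index", "presented_cm", "reproduced_cm"]

#: Default condition-level mean prior reliance (regression index).  The study
#: reports only the ordering individual > mechanical > social, not numeric
#: values; these defaults preserve that ordering with realistic spacing.
DEFAULT_CONDITION_MEAN_RI = {INDIVIDUAL: 0.50, MECHANICAL: 0.35, SOCIAL: 0.25}

#: Gaussian jitter sd whose mean absolute deviation equals the reported
#: 0.62 cm stimulus variation: sd = 0.62 / sqrt(2/pi).
DEFAULT_JITTER_SD_CM = 0.62 / np.sqrt(2.0 / np.pi)


def default_lengths_cm() -> list[float]:
    """The 11-length arithmetic grid 6.0, 6.8, ..., 14.0 cm."""
    return [round(x, 1) for x in np.linspace(6.0, 14.0, 11)]


@dataclass(frozen=True)
class StimulusDesign:
    """Stimulus schedule parameters for one condition of the task."""

    lengths_cm: tuple[float, ...] = field(default_factory=lambda: tuple(default_lengths_cm()))
    repetitions: int = 6
    jitter_sd_cm: float = DEFAULT_JITTER_SD_CM
    dropout_mean_trials: float = 62.66
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lengths = tuple(float(l) for l in self.lengths_cm)
        object.__setattr__(self, "lengths_cm", lengths)
        if len(lengths) == 0 or any(l <= 0 for l in lengths):
            raise ValueError("lengths_cm must be non-empty and all positive")
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("lengths_cm must be strictly increasing")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.jitter_sd_cm < 0:
            raise ValueError("jitter_sd_cm must be >= 0")
        if self.dropout_mean_trials > self.n_trials_nominal:
            raise ValueError(
                f"dropout_mean_trials ({self.dropout_mean_trials}) cannot exceed the "
                f"nominal trial count ({self.n_trials_nominal})"
            )

    @property
    def n_trials_nominal(self) -> int:
        return len(self.lengths_cm) * self.repetitions

    @property
    def dropout_keep_prob(self) -> float:
        """Per-trial i.i.d. survival probability matching the mean trial count."""
        return float(self.dropout_mean_trials) / self.n_trials_nominal


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one simulated participant in one condition."""

    participant_id: str
    condition: str
    regression_index_true: float
    motor_noise_sd_cm: float = 0.3

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not 0.0 <= self.regression_index_true <= 1.0:
            raise ValueError(f"regression_index_true must lie in [0, 1], got {self.regression_index_true}")
        if self.motor_noise_sd_cm < 0:
            raise ValueError("motor_noise_sd_cm must be >= 0")


def generate_stimulus_schedule(
    design: StimulusDesign, condition: str, seed: int | None = None
) -> np.ndarray:
    """Randomized presented-length schedule for one participant x condition.

    In the ``individual`` condition the schedule is an exact random permutation
    of ``repetitions`` copies of each design length.  In the robot conditions
    each length first receives additive Gaussian jitter (sd ``jitter_sd_cm``)
    and trials are dropped i.i.d. so the expected surviving count equals
    ``dropout_mean_trials``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(design.rng_seed if seed is None else seed)
    base = np.repeat(np.asarray(design.lengths_cm, dtype=float), design.repetitions)
    schedule = rng.permutation(base)
    if condition in ROBOT_CONDITIONS:
        if design.jitter_sd_cm > 0:
            jittered = schedule + rng.normal(0.0, design.jitter_sd_cm, size=schedule.size)
            # the touch screen cannot record a non-positive length
            schedule = np.clip(jittered, 0.05, None)
        keep_p = design.dropout_keep_prob
        if keep_p < 1.0:
            schedule = schedule[rng.random(schedule.size) < keep_p]
    return schedule


def simulate_observer(
    schedule: np.ndarray,
    params: ObserverParams,
    prior_mean_cm: float | None = None,
    seed: int = 0,
    *,
    running_mean_prior: bool = False,
) -> pd.DataFrame:
    """Simulate one participant x condition cell of the behavior table.

    ``prior_mean_cm`` defaults to the mean of the schedule, matching the
    regression-index convention that the prior is the average of all stimuli
    perceived during one condition.  With ``running_mean_prior`` the prior at
    trial i is instead the mean of stimuli presented up to and including trial
    i (a session-drift sensitivity variant, not the default analysis).
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    rho = params.regression_index_true
    if prior_mean_cm is None:
        prior_mean_cm = float(schedule.mean())
    if prior_mean_cm <= 0:
        raise ValueError("prior_mean_cm must be positive")
    if running_mean_prior:
        prior = np.cumsum(schedule) / np.arange(1, schedule.size + 1)
    else:
        prior = np.full(schedule.size, prior_mean_cm)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.motor_noise_sd_cm, size=schedule.size) if params.motor_noise_sd_cm > 0 else 0.0
    reproduced = np.clip((1.0 - rho) * schedule + rho * prior + noise, 0.0, None)
    return pd.DataFrame(
        {
            "participant_id": params.participant_id,
            "condition": params.condition,
            "trial_index": np.arange(schedule.size),
            "presented_cm": schedule,
            "reproduced_cm": reproduced,
        }
    )


def generate_cohort(
    n_participants: int = 25,
    design: StimulusDesign = StimulusDesign(),
    condition_mean_ri: dict[str, float] | None = None,
    ri_between_subject_sd: float = 0.1,
    motor_noise_sd_cm: float = 0.3,
    seed: int = 0,
    *,
    running_mean_prior: bool = False,
) -> pd.DataFrame:
    """Full behavior table for a cohort: n_participants x 3 conditions.

    Each participant draws one true prior reliance per condition from
    Normal(condition mean, ri_between_subject_sd^2) truncated to [0, 1].
    Every stochastic choice (reliance draws, schedules, motor noise) derives
    deterministically from ``seed``.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    if condition_mean_ri is None:
        condition_mean_ri = dict(DEFAULT_CONDITION_MEAN_RI)
    if not condition_mean_ri:
        raise ValueError("condition_mean_ri must not be empty")
    for cond, m in condition_mean_ri.items():
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"condition mean RI for {cond!r} must lie in [0, 1], got {m}")
    ss = np.random.SeedSequence(seed)
    tables = []
    width = len(str(n_participants))
    for p, p_seed in enumerate(ss.spawn(n_participants)):
        pid = f"P{p + 1:0{width}d}"
        child = p_seed.spawn(2 * len(condition_mean_ri))
        for c, cond in enumerate(sorted(condition_mean_ri)):
            mean_ri = condition_mean_ri[cond]
            rng = np.random.default_rng(child[2 * c])
            if ri_between_subject_sd > 0:
                a = (0.0 - mean_ri) / ri_between_subject_sd
                b = (1.0 - mean_ri) / ri_between_subject_sd
                rho = float(
                    stats.truncnorm.rvs(a, b, loc=mean_ri, scale=ri_between_subject_sd, random_state=rng)
                )
            else:
                rho = mean_ri
            sched_seed, obs_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child[2 * c + 1].spawn(2))
            schedule = generate_stimulus_schedule(design, cond, seed=sched_seed)
            params = ObserverParams(pid, cond, rho, motor_noise_sd_cm)
            tables.append(
                simulate_observer(
                    schedule, params, seed=obs_seed, running_mean_prior=running_mean_prior
                ).assign(regression_index_true=rho)
            )
    return pd.concat(tables, ignore_index=True)


def write_behavior_table(table: pd.DataFrame, path) -> None:
    """Serialize a behavior table to CSV (UTF-8, '.' decimal separator)."""
    table[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table at {path} is missing columns {missing}")
    return df
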