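"""Behavioral statistics and H-parameter sweep experiments.

The central-tendency strength of one participant x condition cell is the
regression index RI = 1 - slope of the ordinary-least-squares fit of
reproduced against presented lengths: 0 means veridical reproduction, 1 means
pure reproduction of the prior mean.  Condition effects are quantified by
subject-wise differences of RIs between condition pairs, with sign-flip
permutation tests on the paired differences.

The sweep experiments replay the stimuli of a baseline condition (the social
robot condition, where prior reliance is weakest) through the trained model
while scaling the prior variance (H_prior < 1, sweep 1A) or the sensory
variance (H_sensor > 1, sweep 1B).  The reported quantity per grid value is
the median, across participants, of the subject-wise RI difference relative to
the unmodified H = 1 regeneration.  Because the posterior mean depends only on
the precision ratio, the ratio-matched H_sensor sweep reproduces the H_prior
sweep exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .inference import HParams, SensoryModel, equivalent_h_sensor
from .network import ModelBundle, generate_table_behavior
from .synthetic import CONDITIONS, INDIVIDUAL, MECHANICAL, SOCIAL

logger = logging.getLogger(__name__)

#: Condition pairs reported by default, ordered (stronger, weaker) prior reliance.
DEFAULT_PAIRS = ((INDIVIDUAL, MECHANICAL), (INDIVIDUAL, SOCIAL), (MECHANICAL, SOCIAL))

#: The H_prior sweep grid, densified below 0.1 where behavior changes fastest.
DEFAULT_H_GRID = (0.5, 0.45, 0.4, 0.35, 0.3, 0.25, 0.2, 0.15, 0.1, 0.09, 0.08, 0.07, 0.06, 0.05)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    regression_index: float
    n_trials: int


def regression_index(trials: pd.DataFrame) -> RegressionResult:
    """OLS regression index of one behavior-table slice.

    RI = 1 - slope of reproduced on presented; not clipped, so values outside
    [0, 1] (over-compensation, anti-regression) are preserved.
    """
    x = trials["presented_cm"].to_numpy(dtype=float)
    y = trials["reproduced_cm"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("regression index requires >= 2 distinct presented lengths")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        regression_index=1.0 - float(fit.slope),
        n_trials=len(trials),
    )


def regression_indices_by_cell(table: pd.DataFrame) -> pd.DataFrame:
    """Regression index for every (participant, condition) cell of a table."""
    rows = []
    for (pid, cond), grp in table.groupby(["participant_id", "condition"], sort=True):
        r = regression_index(grp)
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "slope": r.slope,
                "intercept": r.intercept,
                "regression_index": r.regression_index,
                "n_trials": r.n_trials,
            }
        )
    return pd.DataFrame(rows)


def subject_wise_differences(ri_table: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Per-participant signed RI differences for each condition pair.

    ``ri_table`` is the output of :func:`regression_indices_by_cell`.  A
    participant missing one member of a pair is skipped with a warning.
    Returns columns participant_id, pair, delta_ri with pair labels like
    ``individual-social`` (delta = first member minus second member).
    """
    pivot = ri_table.pivot(index="participant_id", columns="condition", values="regression_index")
    rows = []
    for a, b in pairs:
        label = f"{a}-{b}"
        for pid, r in pivot.iterrows():
            if a not in r or b not in r or pd.isna(r.get(a)) or pd.isna(r.get(b)):
                logger.warning("participant %s missing condition %s or %s; skipped for pair %s", pid, a, b, label)
                continue
            rows.append({"participant_id": pid, "pair": label, "delta_ri": float(r[a] - r[b])})
    return pd.DataFrame(rows)


def summarize_differences(diffs: pd.DataFrame, interval: float = 0.80) -> pd.DataFrame:
    """Mean, SD and percentile interval (default 80%) of deltas per pair."""
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    out = []
    for pair, grp in diffs.groupby("pair", sort=False):
        d = grp["delta_ri"].to_numpy()
        out.append(
            {
                "pair": pair,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "lo": float(np.quantile(d, lo_q)),
                "hi": float(np.quantile(d, hi_q)),
                "n": int(d.size),
            }
        )
    return pd.DataFrame(out)


def paired_permutation_test(
    deltas_a,
    deltas_b,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[float, dict]:
    """Sign-flip permutation test for the mean paired difference a - b.

    Enumerates all 2^n sign patterns exhaustively when that is no more than
    ``n_perm``; otherwise uses ``n_perm`` random sign flips with the add-one
    correction.  Deterministic given ``seed``.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("paired samples must be equal-length 1-d arrays with n >= 5")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = a - b
    obs = d.mean()
    n = d.size
    if 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        perm = signs @ d / n
        exact = True
        total = perm.size
        extra = 0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        perm = signs @ d / n
        exact = False
        total = n_perm + 1  # add-one: the observed labelling counts as one permutation
        extra = 1
    if alternative == "greater":
        count = np.sum(perm >= obs)
    elif alternative == "less":
        count = np.sum(perm <= obs)
    else:
        count = np.sum(np.abs(perm) >= abs(obs))
    p = float((count + extra) / total)
    return p, {"mean_diff": float(obs), "n": int(n), "exact": exact, "alternative": alternative}


# ---------------------------------------------------------------------------
# H-parameter sweeps (Experiments 1A / 1B)
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Outcome of one H sweep over an ensemble of trained networks."""

    parameter: str  # "H_prior" or "H_sensor"
    grid: tuple[float, ...]
    baseline_condition: str
    medians: pd.DataFrame  # columns: network, H, median_delta
    details: pd.DataFrame  # columns: network, H, participant_id, delta_ri
    references: dict = field(default_factory=dict)  # label -> human/synthetic reference delta

    def best_matching_h(self, reference: float) -> float:
        """Grid value whose across-network mean median delta is closest to
        ``reference`` (declared match; no interpolation between grid points)."""
        mean_by_h = self.medians.groupby("H")["median_delta"].mean()
        return float((mean_by_h - reference).abs().idxmin())


def _h_params(parameter: str, value: float) -> HParams:
    if parameter == "H_prior":
        return HParams(h_prior=value, h_sensor=1.0)
    if parameter == "H_sensor":
        return HParams(h_prior=1.0, h_sensor=value)
    raise ValueError(f"parameter must be 'H_prior' or 'H_sensor', got {parameter!r}")


def h_sweep(
    bundles: list[ModelBundle],
    tables: pd.DataFrame,
    parameter: str = "H_prior",
    grid=DEFAULT_H_GRID,
    baseline_condition: str = SOCIAL,
    sm: SensoryModel = SensoryModel(),
    references: dict | None = None,
) -> SweepResult:
    """Sweep one reliance parameter on the baseline condition's initial states.

    For every network and grid value H, the baseline condition's stimuli are
    regenerated with the altered HParams, the per-participant RI is compared
    with the H = 1 regeneration of the same stimuli, and the median
    subject-wise difference across participants is recorded.  For the
    H_sensor sweep pass the ratio-matched grid (see
    :func:`tendnet.inference.equivalent_h_sensor`).
    """
    if baseline_condition not in CONDITIONS:
        raise ValueError(f"unknown baseline condition {baseline_condition!r}")
    grid = tuple(float(v) for v in grid)
    if any(v <= 0 for v in grid):
        raise ValueError("grid values must be positive")
    base_table = tables[tables["condition"] == baseline_condition]
    if base_table.empty:
        raise ValueError(f"tables contain no {baseline_condition!r} trials")

    med_rows, det_rows = [], []
    for net_id, bundle in enumerate(bundles):
        baseline = generate_table_behavior(
            bundle.params, bundle.bank, base_table, HParams(1.0, 1.0), sm, "on", bundle.spec
        )
        ri0 = regression_indices_by_cell(baseline).set_index("participant_id")["regression_index"]
        for hval in grid:
            regen = generate_table_behavior(
                bundle.params, bundle.bank, base_table, _h_params(parameter, hval), sm, "on", bundle.spec
            )
            ri = regression_indices_by_cell(regen).set_index("participant_id")["regression_index"]
            delta = (ri - ri0).dropna()
            med_rows.append({"network": net_id, "H": hval, "median_delta": float(delta.median())})
            det_rows.extend(
                {"network": net_id, "H": hval, "participant_id": pid, "delta_ri": float(v)}
                for pid, v in delta.items()
            )
    return SweepResult(
        parameter=parameter,
        grid=grid,
        baseline_condition=baseline_condition,
        medians=pd.DataFrame(med_rows),
        details=pd.DataFrame(det_rows),
        references=dict(references or {}),
    )


def ratio_matched_grid(h_prior_grid=DEFAULT_H_GRID) -> tuple[float, ...]:
    """H_sensor grid with the same prior:sensory precision ratios as the
    H_prior grid (elementwise reciprocal)."""
    return tuple(equivalent_h_sensor(h) for h in h_prior_grid)


def reference_differences(table: pd.DataFrame, baseline_condition: str = SOCIAL) -> dict:
    """Mean subject-wise RI differences of the other conditions vs baseline.

    These are the horizontal reference lines the sweep medians are compared
    against (e.g. mean individual-social and mechanical-social differences).
    """
    ri = regression_indices_by_cell(table)
    pairs = [(c, baseline_condition) for c in CONDITIONS if c != baseline_condition]
    diffs = subject_wise_differences(ri, pairs=pairs)
    return {pair: float(grp["delta_ri"].mean()) for pair, grp in diffs.groupby("pair")}
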