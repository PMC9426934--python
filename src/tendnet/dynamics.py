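"""Analysis of recurrent-layer dynamics during behavior generation.

While the trained network regenerates every trial, the 25-dimensional
activation vector of the recurrent layer is recorded at each of the 22 time
steps.  Two analyses quantify how the three situational conditions are encoded
in these traces:

* a 2-d principal-component embedding of the pooled activation vectors, with
  per-condition means and covariance ellipses at selected time steps (the
  initial states at t = 0 versus the length-differentiated states at t = 21);

* a length-stratified between-participant distance profile: trials are binned
  into length categories (the most commonly presented lengths), and at each
  time step the mean squared difference d(x, y) = 1/N * sum_i (x_i - y_i)^2 is
  averaged over all unordered participant pairs within one category and
  condition, then over categories — so differences in reproduced length do not
  inflate the between-participant measure.  Profiles are averaged across
  independently trained networks (mean and standard error), after each
  network's activations are normalized to [0, 1].

A relatively high early-time distance in a condition means participants are
told apart mainly by their initial states (prior-driven encoding); a high
late-time distance means they are told apart by the input-driven dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codec import N_TIME_STEPS
from .inference import HParams, SensoryModel
from .network import N_CONTEXT, ModelBundle, generate_table_behavior

logger = logging.getLogger(__name__)


@dataclass
class ActivationTensor:
    """Recurrent-layer activation traces of one network's regeneration run.

    ``values`` has shape (n_trials, 22, n_neurons); ``meta`` aligns row-wise
    with participant_id, condition, trial_index and presented_cm.
    """

    values: np.ndarray
    meta: pd.DataFrame
    normalization: str = "raw"  # "raw" | "unit-interval"

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1] != N_TIME_STEPS:
            raise ValueError(f"values must be (n_trials, {N_TIME_STEPS}, n_neurons)")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta must align row-wise with values")

    def normalized(self) -> "ActivationTensor":
        """Rescale all activations of this network to [0, 1] jointly."""
        lo, hi = self.values.min(), self.values.max()
        if hi == lo:
            vals = np.zeros_like(self.values)
        else:
            vals = (self.values - lo) / (hi - lo)
        return replace(self, values=vals, normalization="unit-interval")


@dataclass
class LengthCategoryMap:
    """Binning of trials into the most common presented-length categories."""

    categories: np.ndarray  # sorted representative lengths (cm)
    threshold: float  # minimum presentation count (exclusive)
    assignment: np.ndarray  # per-trial category index, -1 = dropped
    n_dropped: int


def record_activation_tensor(
    bundle: ModelBundle,
    tables: pd.DataFrame,
    h: HParams = HParams(),
    sm: SensoryModel = SensoryModel(),
    inference: str = "on",
) -> ActivationTensor:
    """Regenerate every trial of ``tables`` and record activation traces.

    Generation is deterministic (mean signals only), so identical trials from
    the same initial state yield identical traces, and the t = 0 slice equals
    the squashed initial states regardless of stimulus length.
    """
    _, traces = generate_table_behavior(
        bundle.params, bundle.bank, tables, h, sm, inference, bundle.spec, return_traces=True
    )
    meta = tables[["participant_id", "condition", "trial_index", "presented_cm"]].reset_index(drop=True)
    return ActivationTensor(values=traces["c"], meta=meta)


def build_length_categories(
    tables: pd.DataFrame, threshold: float, decimals: int = 1
) -> LengthCategoryMap:
    """Select length categories and assign every trial to its nearest one.

    Categories are the distinct presented lengths (rounded to ``decimals``)
    whose presentation count across the whole table exceeds ``threshold``; on
    undropped, unjittered data this recovers exactly the design lengths.
    Trials farther from every category than half the minimum category gap are
    dropped (logged).  A sensible threshold for a synthetic cohort is
    0.8 * repetitions * n_participants (see :func:`default_category_threshold`).
    """
    if tables.empty:
        raise ValueError("tables must be non-empty")
    presented = tables["presented_cm"].to_numpy(dtype=float)
    counts = pd.Series(np.round(presented, decimals)).value_counts()
    cats = np.sort(counts[counts > threshold].index.to_numpy(dtype=float))
    if cats.size == 0:
        raise ValueError(
            f"no length presented more than {threshold} times; lower the threshold "
            f"(max observed count: {counts.max()})"
        )
    nearest = np.argmin(np.abs(presented[:, None] - cats[None, :]), axis=1)
    if cats.size > 1:
        max_dist = np.min(np.diff(cats)) / 2.0
    else:
        max_dist = np.inf
    dist = np.abs(presented - cats[nearest])
    assignment = np.where(dist <= max_dist, nearest, -1)
    n_dropped = int(np.sum(assignment < 0))
    if n_dropped:
        logger.info("dropped %d trials farther than %.3f cm from every length category", n_dropped, max_dist)
    return LengthCategoryMap(categories=cats, threshold=threshold, assignment=assignment, n_dropped=n_dropped)


def default_category_threshold(n_participants: int, repetitions: int) -> float:
    """Count threshold scaled to the cohort so the design lengths survive."""
    return 0.8 * repetitions * n_participants


def _participant_traces(tensor: ActivationTensor, cats: LengthCategoryMap):
    """Collapse replicate trials: mean trace per (condition, category, participant)."""
    meta = tensor.meta
    out: dict[tuple, dict[str, np.ndarray]] = {}
    for cond in meta["condition"].unique():
        for k in range(cats.categories.size):
            mask = (meta["condition"] == cond).to_numpy() & (cats.assignment == k)
            if not mask.any():
                continue
            traces = {}
            for pid in meta.loc[mask, "participant_id"].unique():
                pmask = mask & (meta["participant_id"] == pid).to_numpy()
                traces[pid] = tensor.values[pmask].mean(axis=0)  # (22, N)
            out[(cond, k)] = traces
    return out


def within_condition_distances_single(
    tensor: ActivationTensor, cats: LengthCategoryMap, *, rms: bool = False
) -> pd.DataFrame:
    """Length-stratified between-participant distance profile of one network.

    At each time step the distance 1/N * sum_i (x_i - y_i)^2 (optionally its
    square root with ``rms``) is averaged over all unordered participant pairs
    within one length category and condition, then over categories.
    Categories with fewer than two participants' traces are excluded (logged).
    Expects a unit-interval-normalized tensor.
    """
    if tensor.normalization != "unit-interval":
        raise ValueError("normalize the tensor to the unit interval first (ActivationTensor.normalized)")
    grouped = _participant_traces(tensor, cats)
    rows = []
    for cond in tensor.meta["condition"].unique():
        per_cat = []
        for k in range(cats.categories.size):
            traces = grouped.get((cond, k))
            if traces is None or len(traces) < 2:
                logger.warning(
                    "condition %s, length category %.1f cm: fewer than 2 participants; excluded",
                    cond,
                    cats.categories[k] if k < cats.categories.size else float("nan"),
                )
                continue
            stack = np.stack(list(traces.values()))  # (P, 22, N)
            pair_d = [np.mean((stack[i] - stack[j]) ** 2, axis=1) for i, j in combinations(range(len(stack)), 2)]
            d = np.mean(pair_d, axis=0)  # (22,)
            per_cat.append(np.sqrt(d) if rms else d)
        if not per_cat:
            raise ValueError(f"no length category has >= 2 participants in condition {cond!r}")
        profile = np.mean(per_cat, axis=0)
        rows.extend(
            {"condition": cond, "time_step": t, "distance": float(profile[t])} for t in range(N_TIME_STEPS)
        )
    return pd.DataFrame(rows)


def within_condition_distances(
    tensors: list[ActivationTensor], cats_list, *, rms: bool = False
) -> pd.DataFrame:
    """Distance profile across an ensemble of networks: mean and standard error.

    Each network's tensor is normalized to [0, 1] independently before its
    profile is computed.  ``cats_list`` is one LengthCategoryMap per network
    (or a single map shared by all, when every network regenerated the same
    trials).
    """
    if not isinstance(cats_list, (list, tuple)):
        cats_list = [cats_list] * len(tensors)
    profiles = [
        within_condition_distances_single(t.normalized(), c, rms=rms) for t, c in zip(tensors, cats_list)
    ]
    for i, prof in enumerate(profiles):
        prof["network"] = i
    allp = pd.concat(profiles, ignore_index=True)
    out = (
        allp.groupby(["condition", "time_step"])["distance"]
        .agg(mean_distance="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out


@dataclass
class Embedding:
    """2-d principal-component embedding of activation vectors."""

    components: np.ndarray  # (k, n_neurons), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    points: pd.DataFrame  # participant_id, condition, trial_index, time_step, pc1, pc2
    condition_stats: pd.DataFrame  # condition, time_step, mean/cov entries


def pca_embedding(
    tensor: ActivationTensor,
    time_steps=(0, N_TIME_STEPS - 1),
    *,
    fit_on_all_steps: bool = True,
) -> Embedding:
    """Embed activation vectors of one network in their first two PCs.

    The components are fitted on the pooled activation vectors of all time
    steps (default) so the displayed time steps share one space; with
    ``fit_on_all_steps=False`` only the requested steps are pooled for the
    fit.  Rank-deficient inputs yield fewer components instead of failing.
    Per-condition means and 2x2 covariances of the embedded points are
    reported per requested time step.
    """
    time_steps = tuple(int(t) for t in time_steps)
    if any(t < 0 or t >= N_TIME_STEPS for t in time_steps):
        raise ValueError(f"time steps must lie in [0, {N_TIME_STEPS - 1}]")
    fit_steps = range(N_TIME_STEPS) if fit_on_all_steps else time_steps
    fit_mat = tensor.values[:, list(fit_steps), :].reshape(-1, tensor.values.shape[2])
    if fit_mat.shape[0] < 3:
        raise ValueError("PCA embedding needs at least 3 activation vectors")
    rank = np.linalg.matrix_rank(fit_mat - fit_mat.mean(axis=0))
    k = int(min(2, max(1, rank), fit_mat.shape[0] - 1, fit_mat.shape[1]))
    pca = PCA(n_components=k)
    pca.fit(fit_mat)

    rows = []
    for t in time_steps:
        coords = pca.transform(tensor.values[:, t, :])
        for i in range(coords.shape[0]):
            rows.append(
                {
                    "participant_id": tensor.meta["participant_id"].iat[i],
                    "condition": tensor.meta["condition"].iat[i],
                    "trial_index": int(tensor.meta["trial_index"].iat[i]),
                    "time_step": t,
                    "pc1": float(coords[i, 0]),
                    "pc2": float(coords[i, 1]) if k > 1 else 0.0,
                }
            )
    points = pd.DataFrame(rows)
    stats_rows = []
    for (cond, t), grp in points.groupby(["condition", "time_step"]):
        xy = grp[["pc1", "pc2"]].to_numpy()
        cov = np.cov(xy.T) if len(xy) > 1 else np.zeros((2, 2))
        stats_rows.append(
            {
                "condition": cond,
                "time_step": t,
                "mean_pc1": float(xy[:, 0].mean()),
                "mean_pc2": float(xy[:, 1].mean()),
                "cov_11": float(cov[0, 0]),
                "cov_12": float(cov[0, 1]),
                "cov_22": float(cov[1, 1]),
            }
        )
    return Embedding(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        points=points,
        condition_stats=pd.DataFrame(stats_rows),
    )
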