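"""End-to-end orchestration: generate -> train -> sweeps -> dynamics -> report.

A run is a pure function of its configuration and seed: every stochastic
stage derives its seed deterministically from the global seed, all outputs
are CSV/JSON twins of the figure-style results, and a manifest records the
config hash and per-stage file checksums so identical runs are verifiable by
checksum equality.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    DEFAULT_H_GRID,
    DEFAULT_PAIRS,
    h_sweep,
    paired_permutation_test,
    ratio_matched_grid,
    reference_differences,
    regression_indices_by_cell,
    subject_wise_differences,
    summarize_differences,
)
from .codec import NormalizationSpec
from .dynamics import (
    build_length_categories,
    default_category_threshold,
    pca_embedding,
    record_activation_tensor,
    within_condition_distances,
)
from .inference import SensoryModel
from .network import ModelBundle, TrainingConfig, train_ensemble
from .synthetic import (
    DEFAULT_CONDITION_MEAN_RI,
    DEFAULT_JITTER_SD_CM,
    CONDITIONS,
    StimulusDesign,
    default_lengths_cm,
    generate_cohort,
    read_behavior_table,
    write_behavior_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "sweep", "dynamics", "report")


def default_config() -> dict:
    """The full run configuration with its documented defaults."""
    return {
        "seed": 0,
        "synthetic": {
            "n_participants": 25,
            "lengths_cm": default_lengths_cm(),
            "repetitions": 6,
            "jitter_sd_cm": float(DEFAULT_JITTER_SD_CM),
            "dropout_mean_trials": 62.66,
            "condition_mean_ri": dict(DEFAULT_CONDITION_MEAN_RI),
            "ri_between_subject_sd": 0.1,
            "motor_noise_sd_cm": 0.3,
        },
        "codec": {"source_min_cm": 0.0, "source_max_cm": 14.0},
        "training": {
            "epochs": 15000,
            "learning_rate": 1e-3,
            "initial_state_lr_scale": 10.0,
            "n_networks": 10,
            "tau": 2.0,
            "variance_floor": 1e-6,
            "sigma2_init": 1e7,
            "gradient_clip": None,
            "standard_log_form": False,
            "integrate_in_training": False,
        },
        "inference": {"sigma2_sensor": 1e-3, "h_prior_grid": list(DEFAULT_H_GRID)},
        "analysis": {
            "baseline_condition": "social",
            "n_perm": 2000,
            "category_threshold": None,
            "rms_distance": False,
            "embedding_time_steps": [0, 21],
        },
    }


def _check_keys(cfg: dict, template: dict, path: str = "") -> None:
    for key, value in cfg.items():
        if key not in template:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if isinstance(template[key], dict) and key != "condition_mean_ri" and isinstance(value, dict):
            _check_keys(value, template[key], path=f"{path}{key}.")


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults.

    Unknown keys are rejected rather than silently ignored.
    """
    cfg = default_config()

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict) and k != "condition_mean_ri":
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, cfg)
        merge(cfg, user)
    if overrides:
        _check_keys(overrides, cfg)
        merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _derived_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(STAGES, children)}


def validate_behavior_table(source) -> dict:
    """Schema, invariant and coverage checks on a behavior table.

    ``source`` is a CSV path or a DataFrame.  Returns a machine-readable
    report: row-level violations carry the offending (0-based) row numbers;
    coverage warnings name the missing (participant, condition) cell.
    """
    df = read_behavior_table(source) if not isinstance(source, pd.DataFrame) else source
    violations, warnings = [], []
    for i, row in df.iterrows():
        if not row["presented_cm"] > 0:
            violations.append({"row": int(i), "error": f"presented_cm not positive: {row['presented_cm']}"})
        if not row["reproduced_cm"] >= 0:
            violations.append({"row": int(i), "error": f"reproduced_cm negative: {row['reproduced_cm']}"})
        if row["condition"] not in CONDITIONS:
            violations.append({"row": int(i), "error": f"unknown condition: {row['condition']!r}"})
    dup = df.duplicated(subset=["participant_id", "condition", "trial_index"])
    for i in df.index[dup]:
        violations.append({"row": int(i), "error": "duplicate (participant_id, condition, trial_index)"})
    for (pid, cond), grp in df.groupby(["participant_id", "condition"]):
        idx = np.sort(grp["trial_index"].to_numpy())
        if not np.array_equal(idx, np.arange(len(idx))):
            violations.append({"row": int(grp.index[0]), "error": f"trial_index not contiguous from 0 in cell ({pid}, {cond})"})
    for pid in df["participant_id"].unique():
        have = set(df.loc[df["participant_id"] == pid, "condition"])
        for cond in CONDITIONS:
            if cond not in have:
                warnings.append(f"participant {pid} missing condition {cond}")
    return {"n_rows": int(len(df)), "violations": violations, "coverage_warnings": warnings, "ok": not violations}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, out: Path, seed: int) -> list[Path]:
    s = cfg["synthetic"]
    design = StimulusDesign(
        lengths_cm=tuple(s["lengths_cm"]),
        repetitions=s["repetitions"],
        jitter_sd_cm=s["jitter_sd_cm"],
        dropout_mean_trials=s["dropout_mean_trials"],
    )
    table = generate_cohort(
        n_participants=s["n_participants"],
        design=design,
        condition_mean_ri=dict(s["condition_mean_ri"]),
        ri_between_subject_sd=s["ri_between_subject_sd"],
        motor_noise_sd_cm=s["motor_noise_sd_cm"],
        seed=seed,
    )
    path = out / "behavior.csv"
    write_behavior_table(table, path)
    table[["participant_id", "condition", "regression_index_true"]].drop_duplicates().to_csv(
        out / "true_regression_indices.csv", index=False
    )
    return [path, out / "true_regression_indices.csv"]


def _spec(cfg) -> NormalizationSpec:
    return NormalizationSpec(cfg["codec"]["source_min_cm"], cfg["codec"]["source_max_cm"])


def _training_config(cfg) -> TrainingConfig:
    t = cfg["training"]
    return TrainingConfig(
        epochs=t["epochs"],
        learning_rate=t["learning_rate"],
        initial_state_lr_scale=t["initial_state_lr_scale"],
        n_networks=t["n_networks"],
        tau=t["tau"],
        variance_floor=t["variance_floor"],
        sigma2_init=t["sigma2_init"],
        gradient_clip=t["gradient_clip"],
        standard_log_form=t["standard_log_form"],
        integrate_in_training=t["integrate_in_training"],
    )


def _stage_train(cfg, out: Path, seed: int) -> list[Path]:
    table = read_behavior_table(out / "behavior.csv")
    bundles = train_ensemble(table, _spec(cfg), _training_config(cfg), seed=seed)
    files = []
    for i, bundle in enumerate(bundles):
        path = out / f"model_{i}.npz"
        bundle.save(path)
        bundle.loss_history.to_csv(out / f"loss_history_{i}.csv", index=False)
        files += [path, out / f"loss_history_{i}.csv"]
    return files


def _load_bundles(out: Path) -> list[ModelBundle]:
    paths = sorted(out.glob("model_*.npz"), key=lambda p: int(p.stem.split("_")[1]))
    if not paths:
        raise FileNotFoundError(f"no trained models in {out}; run the train stage first")
    return [ModelBundle.load(p) for p in paths]


def _stage_sweep(cfg, out: Path, seed: int) -> list[Path]:
    table = read_behavior_table(out / "behavior.csv")
    bundles = _load_bundles(out)
    sm = SensoryModel(cfg["inference"]["sigma2_sensor"])
    base = cfg["analysis"]["baseline_condition"]
    grid = tuple(cfg["inference"]["h_prior_grid"])

    ri = regression_indices_by_cell(table)
    ri.to_csv(out / "regression_indices.csv", index=False)
    diffs = subject_wise_differences(ri, pairs=DEFAULT_PAIRS)
    diffs.to_csv(out / "subject_differences.csv", index=False)
    refs = reference_differences(table, baseline_condition=base)

    results = {}
    for parameter, pgrid in (("H_prior", grid), ("H_sensor", ratio_matched_grid(grid))):
        sweep = h_sweep(bundles, table, parameter, pgrid, base, sm, references=refs)
        sweep.medians.to_csv(out / f"sweep_{parameter}.csv", index=False)
        sweep.details.to_csv(out / f"sweep_{parameter}_details.csv", index=False)
        results[parameter] = sweep

    n_perm = cfg["analysis"]["n_perm"]
    tests = {}
    pivot = diffs.pivot(index="participant_id", columns="pair", values="delta_ri")
    for pair in pivot.columns:
        d = pivot[pair].dropna().to_numpy()
        if d.size >= 5:
            p, info = paired_permutation_test(d, np.zeros_like(d), n_perm=max(n_perm, 100), seed=seed)
            tests[pair] = {"p_value": p, **info}
    summary = {
        "references": refs,
        "permutation_tests": tests,
        "difference_summary": summarize_differences(diffs).to_dict(orient="records"),
        "best_matching_h": {
            param: {label: sweep.best_matching_h(refs[label]) for label in refs}
            for param, sweep in results.items()
        },
    }
    with open(out / "sweep_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return [
        out / "regression_indices.csv",
        out / "subject_differences.csv",
        out / "sweep_H_prior.csv",
        out / "sweep_H_prior_details.csv",
        out / "sweep_H_sensor.csv",
        out / "sweep_H_sensor_details.csv",
        out / "sweep_summary.json",
    ]


def _stage_dynamics(cfg, out: Path, seed: int) -> list[Path]:
    table = read_behavior_table(out / "behavior.csv")
    bundles = _load_bundles(out)
    sm = SensoryModel(cfg["inference"]["sigma2_sensor"])
    threshold = cfg["analysis"]["category_threshold"]
    if threshold is None:
        threshold = default_category_threshold(
            table["participant_id"].nunique(), cfg["synthetic"]["repetitions"]
        )
    cats = build_length_categories(table, threshold)
    tensors = [record_activation_tensor(b, table, sm=sm) for b in bundles]
    profile = within_condition_distances(tensors, cats, rms=cfg["analysis"]["rms_distance"])
    profile.to_csv(out / "distance_profile.csv", index=False)

    emb = pca_embedding(tensors[0], tuple(cfg["analysis"]["embedding_time_steps"]))
    emb.points.to_csv(out / "embedding.csv", index=False)
    emb.condition_stats.to_csv(out / "embedding_condition_stats.csv", index=False)
    with open(out / "explained_variance.json", "w") as fh:
        json.dump(
            {
                "explained_variance_ratio": [float(v) for v in emb.explained_variance_ratio],
                "length_categories_cm": [float(c) for c in cats.categories],
                "n_dropped_trials": cats.n_dropped,
            },
            fh,
            indent=2,
        )
    return [
        out / "distance_profile.csv",
        out / "embedding.csv",
        out / "embedding_condition_stats.csv",
        out / "explained_variance.json",
    ]


def _stage_report(cfg, out: Path, seed: int) -> list[Path]:
    report = {"validation": validate_behavior_table(out / "behavior.csv")}
    for name in ("sweep_summary.json", "explained_variance.json"):
        path = out / name
        if path.exists():
            with open(path) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "sweep": _stage_sweep,
    "dynamics": _stage_dynamics,
    "report": _stage_report,
}


def run_pipeline(
    config: dict | None = None,
    out_dir="runs/default",
    seed: int | None = None,
    stages=None,
    resume: bool = False,
) -> dict:
    """Execute pipeline stages in order and write the run manifest.

    With ``resume``, a stage is skipped when a previous manifest in the output
    directory has the same config hash and all the stage's output files still
    match their recorded checksums.  Any stage failure is re-raised annotated
    with the stage name and a replayable single-stage command.
    """
    cfg = copy.deepcopy(config) if config is not None else default_config()
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    chash = config_hash(cfg)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == chash:
            previous = old.get("stages", {})

    seeds = _derived_seeds(cfg["seed"])
    manifest = {"config_hash": chash, "package_version": __version__, "seed": cfg["seed"], "stages": {}}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            stale = json.load(fh)
        if stale.get("config_hash") == chash:
            manifest["stages"] = stale.get("stages", {})

    logger.info("run %s: seed=%d stages=%s", chash, cfg["seed"], stages)
    for name in STAGES:
        if name not in stages:
            continue
        prev = previous.get(name)
        if prev and all(Path(out / f).exists() and _sha256(out / f) == h for f, h in prev["files"].items()):
            logger.info("stage %s: outputs unchanged, skipped", name)
            manifest["stages"][name] = prev
            continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[name](cfg, out, seeds[name])
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed ({exc}); replay with: tendnet {name} --out {out} --seed {cfg['seed']}"
            ) from exc
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = {
            "files": {p.name: _sha256(p) for p in files},
            "seconds": round(elapsed, 3),
        }
        logger.info("stage %s: %d files in %.1fs", name, len(files), elapsed)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
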