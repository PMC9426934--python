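import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tendnet.codec import NormalizationSpec
from tendnet.network import ModelBundle, TrainingConfig, train
from tendnet.synthetic import generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    return NormalizationSpec()


@pytest.fixture(scope="session")
def recovery_cohort():
    """Scaled-down cohort for model-replication checks.

    Six participants, condition mean reliances 0.50 / 0.35 / 0.25 and 0.3 cm
    motor noise, with the robot conditions' stimulus jitter and trial dropout
    at their task defaults.
    """
    table = generate_cohort(
        n_participants=6,
        condition_mean_ri={"individual": 0.50, "mechanical": 0.35, "social": 0.25},
        ri_between_subject_sd=0.1,
        motor_noise_sd_cm=0.3,
        seed=42,
    )
    true_ri = (
        table[["participant_id", "condition", "regression_index_true"]]
        .drop_duplicates()
        .set_index(["participant_id", "condition"])["regression_index_true"]
    )
    return table, true_ri


@pytest.fixture(scope="session")
def trained_bundles(recovery_cohort, spec):
    """Two networks trained for 2000 epochs on the scaled-down cohort.

    Shared across the replication, sweep and dynamics tests; the 0.01 base
    learning rate is the package's scaled-run default for few-thousand-epoch
    training (see docs/methods.md).
    """
    table, _ = recovery_cohort
    cfg = TrainingConfig(epochs=2000, learning_rate=0.01, n_networks=2, seeds=(7, 8))
    bundles = []
    for seed in cfg.seeds:
        params, bank, hist = train(table, spec, cfg, seed=seed)
        bundle = ModelBundle(params=params, bank=bank, spec=spec, config=cfg, seed=seed)
        bundle.loss_history = hist
        bundles.append(bundle)
    return bundles


@pytest.fixture()
def tiny_table():
    """Hand-sized two-participant table with all three conditions."""
    rows = []
    for pid in ("A", "B"):
        for cond in ("individual", "mechanical", "social"):
            for i, (pres, rep) in enumerate([(6.0, 6.5), (10.0, 9.8), (14.0, 13.1)]):
                rows.append((pid, cond, i, pres, rep))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "trial_index", "presented_cm", "reproduced_cm"])
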