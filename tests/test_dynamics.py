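import numpy as np
import pandas as pd
import pytest

from tendnet.dynamics import (
    ActivationTensor,
    build_length_categories,
    default_category_threshold,
    pca_embedding,
    record_activation_tensor,
    within_condition_distances,
    within_condition_distances_single,
)
from tendnet.synthetic import generate_cohort


def _meta(rows):
    return pd.DataFrame(rows, columns=["participant_id", "condition", "trial_index", "presented_cm"])


def _hand_tensor():
    """2 participants x 2 length categories x 3 neurons, one condition.

    Constant-in-time traces whose pairwise mean squared differences are 1.0
    (category 6 cm: traces 0 vs 1) and 0.16 (category 10 cm: 0.2 vs 0.6),
    so the stratified profile is (1.0 + 0.16) / 2 = 0.58 at every step.
    """
    meta = _meta(
        [
            ("P1", "social", 0, 6.0),
            ("P2", "social", 0, 6.0),
            ("P1", "social", 1, 10.0),
            ("P2", "social", 1, 10.0),
        ]
    )
    values = np.stack(
        [
            np.full((22, 3), 0.0),
            np.full((22, 3), 1.0),
            np.full((22, 3), 0.2),
            np.full((22, 3), 0.6),
        ]
    )
    table = meta.assign(reproduced_cm=meta["presented_cm"])
    cats = build_length_categories(table, threshold=1)
    return ActivationTensor(values, meta, normalization="unit-interval"), cats


class TestLengthCategories:
    def test_eleven_categories_on_undropped_data(self):
        # an unjittered, undropped cohort: every presented length is a design length
        from tendnet.synthetic import StimulusDesign

        design = StimulusDesign(jitter_sd_cm=0.0, dropout_mean_trials=66)
        clean = generate_cohort(n_participants=6, design=design, seed=0)
        cats = build_length_categories(clean, default_category_threshold(6, 6))
        assert cats.categories.size == 11
        assert cats.n_dropped == 0

    def test_threshold_zero_keeps_every_distinct_length(self):
        table = _meta([("P1", "social", i, v) for i, v in enumerate([6.0, 6.0, 8.0, 9.0])])
        cats = build_length_categories(table.assign(reproduced_cm=1.0), threshold=0)
        np.testing.assert_array_equal(cats.categories, [6.0, 8.0, 9.0])

    def test_nearest_assignment_on_hand_built_trials(self):
        """Jittered lengths bin to the nearest category; outliers drop."""
        table = _meta(
            [
                ("P1", "social", 0, 6.0),
                ("P1", "social", 1, 6.0),
                ("P1", "social", 2, 10.0),
                ("P1", "social", 3, 10.0),
                ("P1", "social", 4, 6.3),  # 0.3 cm from 6 -> assigned to 6
            ]
        )
        cats = build_length_categories(table.assign(reproduced_cm=1.0), threshold=1)
        np.testing.assert_array_equal(cats.categories, [6.0, 10.0])
        np.testing.assert_array_equal(cats.assignment, [0, 0, 1, 1, 0])

    def test_no_surviving_category_rejected(self):
        table = _meta([("P1", "social", 0, 6.0)])
        with pytest.raises(ValueError, match="lower the threshold"):
            build_length_categories(table.assign(reproduced_cm=1.0), threshold=10)


class TestDistanceProfile:
    def test_hand_computed_oracle(self):
        tensor, cats = _hand_tensor()
        profile = within_condition_distances_single(tensor, cats)
        assert len(profile) == 22
        np.testing.assert_allclose(profile["distance"], 0.58, rtol=1e-12)

    def test_single_neuron_unit_distance(self):
        meta = _meta([("P1", "social", 0, 6.0), ("P2", "social", 0, 6.0)])
        values = np.stack([np.zeros((22, 1)), np.ones((22, 1))])
        tensor = ActivationTensor(values, meta, normalization="unit-interval")
        cats = build_length_categories(meta.assign(reproduced_cm=1.0), threshold=1)
        profile = within_condition_distances_single(tensor, cats)
        np.testing.assert_allclose(profile["distance"], 1.0)

    def test_identical_traces_zero_profile(self):
        meta = _meta([("P1", "social", 0, 6.0), ("P2", "social", 0, 6.0)])
        base = np.linspace(0, 1, 22 * 3).reshape(22, 3)
        tensor = ActivationTensor(np.stack([base, base]), meta, normalization="unit-interval")
        cats = build_length_categories(meta.assign(reproduced_cm=1.0), threshold=1)
        assert (within_condition_distances_single(tensor, cats)["distance"] == 0).all()

    def test_participant_relabeling_invariance(self):
        tensor, cats = _hand_tensor()
        relabeled = ActivationTensor(
            tensor.values,
            tensor.meta.assign(participant_id=tensor.meta["participant_id"].map({"P1": "P2", "P2": "P1"})),
            normalization="unit-interval",
        )
        p1 = within_condition_distances_single(tensor, cats)
        p2 = within_condition_distances_single(relabeled, cats)
        np.testing.assert_array_equal(p1["distance"], p2["distance"])

    def test_neuron_permutation_invariance(self):
        tensor, cats = _hand_tensor()
        permuted = ActivationTensor(tensor.values[:, :, [2, 0, 1]], tensor.meta, "unit-interval")
        np.testing.assert_allclose(
            within_condition_distances_single(tensor, cats)["distance"],
            within_condition_distances_single(permuted, cats)["distance"],
            rtol=1e-12,
        )

    def test_category_offset_invariance(self):
        """Shifting all traces of one length category leaves the profile
        unchanged: distances are within-category."""
        tensor, cats = _hand_tensor()
        shifted = tensor.values.copy()
        shifted[2:] += 0.2  # both 10 cm traces: 0.2/0.6 -> 0.4/0.8, still in [0, 1]
        p1 = within_condition_distances_single(tensor, cats)
        p2 = within_condition_distances_single(
            ActivationTensor(shifted, tensor.meta, "unit-interval"), cats
        )
        np.testing.assert_allclose(p1["distance"], p2["distance"], rtol=1e-12)

    def test_lone_participant_category_excluded(self):
        meta = _meta(
            [("P1", "social", 0, 6.0), ("P2", "social", 0, 6.0), ("P1", "social", 1, 10.0)]
        )
        values = np.stack([np.zeros((22, 2)), np.ones((22, 2)), np.full((22, 2), 0.5)])
        tensor = ActivationTensor(values, meta, normalization="unit-interval")
        cats = build_length_categories(meta.assign(reproduced_cm=1.0), threshold=0)
        profile = within_condition_distances_single(tensor, cats)
        np.testing.assert_allclose(profile["distance"], 1.0)  # only the 6 cm pair counts

    def test_requires_normalized_tensor(self):
        tensor, cats = _hand_tensor()
        raw = ActivationTensor(tensor.values, tensor.meta, normalization="raw")
        with pytest.raises(ValueError, match="normalize"):
            within_condition_distances_single(raw, cats)

    def test_ensemble_mean_and_se(self):
        tensor, cats = _hand_tensor()
        out = within_condition_distances([tensor, tensor], cats)
        np.testing.assert_allclose(out["mean_distance"], 0.58, rtol=1e-12)
        np.testing.assert_allclose(out["se"], 0.0, atol=1e-15)


class TestRecordedTensor:
    def test_shape_and_initial_state_slice(self, trained_bundles, recovery_cohort):
        table, _ = recovery_cohort
        bundle = trained_bundles[0]
        tensor = record_activation_tensor(bundle, table)
        assert tensor.values.shape == (len(table), 22, 25)
        # the t = 0 activations equal the squashed initial states of each
        # trial's cell, independent of the stimulus
        for cell, row in list(bundle.bank.index.items())[:3]:
            mask = (
                (tensor.meta["participant_id"] == cell[0])
                & (tensor.meta["condition"] == cell[1])
            ).to_numpy()
            expected = np.broadcast_to(
                np.tanh(bundle.bank.states[row]), (int(mask.sum()), 25)
            )
            np.testing.assert_allclose(tensor.values[mask, 0, :], expected, rtol=1e-12)

    def test_unit_interval_normalization(self, trained_bundles, recovery_cohort):
        table, _ = recovery_cohort
        tensor = record_activation_tensor(trained_bundles[0], table).normalized()
        assert tensor.values.min() == 0.0
        assert tensor.values.max() == 1.0
        assert tensor.normalization == "unit-interval"


class TestPCAEmbedding:
    def _planar_tensor(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        v1, v2 = np.zeros(25), np.zeros(25)
        v1[0], v2[1] = 1.0, 1.0
        coeffs = rng.normal(0, 1, (n, 22, 2))
        values = coeffs[..., :1] * v1 + coeffs[..., 1:] * v2
        meta = _meta([("P%d" % (i % 4), "social", i, 6.0) for i in range(n)])
        return ActivationTensor(values, meta)

    def test_two_dim_data_fully_explained(self):
        emb = pca_embedding(self._planar_tensor(), (0, 21))
        assert emb.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert emb.components.shape == (2, 25)
        # orthonormal components
        np.testing.assert_allclose(emb.components @ emb.components.T, np.eye(2), atol=1e-10)

    def test_explained_variance_non_increasing_and_bounded(self):
        emb = pca_embedding(self._planar_tensor(seed=3), (0,))
        evr = emb.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_rank_deficient_reports_fewer_components(self):
        meta = _meta([("P1", "social", i, 6.0) for i in range(5)])
        line = np.arange(5)[:, None, None] * np.ones((1, 22, 25))  # rank-1 cloud
        emb = pca_embedding(ActivationTensor(line, meta), (0,))
        assert emb.components.shape[0] == 1
        assert (emb.points["pc2"] == 0).all()

    def test_condition_stats_present(self, trained_bundles, recovery_cohort):
        table, _ = recovery_cohort
        tensor = record_activation_tensor(trained_bundles[0], table)
        emb = pca_embedding(tensor, (0, 21))
        assert set(emb.condition_stats["condition"]) == {"individual", "mechanical", "social"}
        assert set(emb.condition_stats["time_step"]) == {0, 21}

    def test_invalid_time_step_rejected(self):
        with pytest.raises(ValueError):
            pca_embedding(self._planar_tensor(), (25,))
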