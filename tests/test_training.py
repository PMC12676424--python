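"""Curriculum mechanics, joint re-weighted training, and aggregation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from layerlens import (
    CurriculumSchedule,
    DifficultyState,
    TrainConfig,
    aggregate_predictions,
    air_forward,
    build_dataset,
    build_model,
    exposure_fraction,
    predict_dataset,
    select_easiest,
    train,
    update_difficulty,
)
from layerlens.models import LinearVolumeClassifier, VoxelGateGenerator
from layerlens.training import exposure_count


class TestDifficultyEMA:
    def test_first_observation_initializes(self):
        state = DifficultyState(momentum=0.9)
        update_difficulty(state, "a", 1.0)
        assert state.scores["a"] == 1.0

    def test_ema_update_example(self):
        state = DifficultyState(momentum=0.9)
        update_difficulty(state, "a", 1.0)
        update_difficulty(state, "a", 0.5)
        assert state.scores["a"] == pytest.approx(0.95)

    def test_memoryless_limit(self):
        state = DifficultyState(momentum=0.0)
        for loss in (2.0, 0.7, 0.3):
            update_difficulty(state, "a", loss)
        assert state.scores["a"] == pytest.approx(0.3)

    def test_constant_loss_fixed_point(self):
        state = DifficultyState(momentum=0.9)
        for _ in range(25):
            update_difficulty(state, "a", 0.42)
        assert state.scores["a"] == pytest.approx(0.42, abs=1e-15)

    def test_matches_expanded_geometric_sum(self):
        rng = np.random.default_rng(0)
        losses = rng.uniform(0, 2, 12)
        beta = 0.8
        state = DifficultyState(momentum=beta)
        for l in losses:
            update_difficulty(state, "a", l)
        expected = losses[0]
        for l in losses[1:]:
            expected = beta * expected + (1 - beta) * l
        assert state.scores["a"] == pytest.approx(expected, abs=1e-14)

    def test_non_finite_loss_rejected(self):
        state = DifficultyState()
        with pytest.raises(ValueError):
            update_difficulty(state, "a", float("nan"))


class TestExposureSchedule:
    SCHED = CurriculumSchedule(f_min=0.2, total_epochs=10, dataset_size=50)

    def test_endpoints_and_midpoint(self):
        assert exposure_fraction(self.SCHED, 0) == pytest.approx(0.2)
        assert exposure_fraction(self.SCHED, 9) == pytest.approx(1.0)
        assert exposure_fraction(self.SCHED, 4) == pytest.approx(0.2 + 0.8 * 4 / 9)

    def test_single_epoch_uses_full_dataset(self):
        sched = CurriculumSchedule(f_min=0.2, total_epochs=1, dataset_size=7)
        assert exposure_fraction(sched, 0) == 1.0
        assert exposure_count(sched, 0) == 7

    def test_monotone_counts_reach_n(self):
        counts = [exposure_count(self.SCHED, e) for e in range(10)]
        assert counts == sorted(counts)
        assert counts[-1] == 50

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            exposure_fraction(self.SCHED, 10)


class TestEasyFirstSelection:
    def test_sort_oracle(self):
        state = DifficultyState()
        for sid, loss in [("a", 0.2), ("b", 0.9), ("c", 0.5)]:
            update_difficulty(state, sid, loss)
        assert set(select_easiest(state, 2)) == {"a", "c"}
        assert select_easiest(state, 3) == ["a", "c", "b"]

    def test_tie_breaks_by_registration_order(self):
        state = DifficultyState()
        update_difficulty(state, "x", 0.5)
        update_difficulty(state, "y", 0.5)
        assert select_easiest(state, 1) == ["x"]

    def test_unvisited_sort_easiest(self):
        state = DifficultyState()
        state.register(["fresh"])
        update_difficulty(state, "seen", 0.0)
        assert select_easiest(state, 1) == ["fresh"]

    def test_membership_monotone_under_easier_score(self):
        rng = np.random.default_rng(1)
        state = DifficultyState()
        for i in range(10):
            update_difficulty(state, f"s{i}", float(rng.uniform(0.1, 1)))
        chosen = set(select_easiest(state, 4))
        sid = next(iter(chosen))
        state.scores[sid] *= 0.5  # easier => never dropped at the same N_e
        assert sid in set(select_easiest(state, 4))


class TestAirForward:
    SHAPE = (1, 4, 4, 4)

    def _classifier(self, seed=0):
        return LinearVolumeClassifier(self.SHAPE, seed=seed, init_scale=0.1)

    def test_identity_weighting_matches_plain(self):
        clf = self._classifier()
        x = np.random.default_rng(0).uniform(size=self.SHAPE)

        class Ones:
            def __call__(self, v):
                return np.ones(v.shape[1:])

        assert air_forward(Ones(), clf, x) == pytest.approx(clf.predict_proba(x))

    def test_annihilating_weights_give_empty_prediction(self):
        clf = self._classifier()
        x = np.random.default_rng(0).uniform(size=self.SHAPE)

        class Zeros:
            def __call__(self, v):
                return np.zeros(v.shape[1:])

        assert air_forward(Zeros(), clf, x) == pytest.approx(
            clf.predict_proba(np.zeros_like(x)))

    def test_linear_logit_oracle_with_fixed_gate(self):
        clf = self._classifier()
        x = np.random.default_rng(1).uniform(size=self.SHAPE)
        gen = VoxelGateGenerator(self.SHAPE[1:], seed=3, init_scale=0.5)
        g = gen(x)
        # affine classifier: logit(C(g*x)) = mean(w * g * x) + b
        expected = float(np.mean(clf.params["w"] * g[None] * x) + clf.params["b"])
        p = air_forward(gen, clf, x)
        assert np.log(p / (1 - p)) == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        clf = self._classifier()

        class Bad:
            def __call__(self, v):
                return np.ones((2, 2, 2))

        with pytest.raises(ValueError):
            air_forward(Bad(), clf, np.zeros(self.SHAPE))


class TestTrainLoop:
    @staticmethod
    def _toy_dataset(n=24, seed=0):
        """Linearly separable 2-voxel-signal volumes."""
        rng = np.random.default_rng(seed)
        values, targets, ids = [], [], []
        for i in range(n):
            y = i % 2
            x = rng.normal(0, 0.1, (1, 4, 4, 4))
            x[0, :2, :2, :2] = y + rng.normal(0, 0.05)  # 8-voxel signal block
            values.append(x)
            targets.append(y)
            ids.append(f"s{i}")
        manifest = pd.DataFrame({"scan_id": ids, "patient_id": ids})
        from layerlens.training import ScanDataset

        return ScanDataset(ids, values, np.array(targets), manifest, ("bmode",))

    def test_loss_decreases_on_separable_toy(self):
        ds = self._toy_dataset()
        cfg = TrainConfig(epochs=40, learning_rate=0.3, weight_decay=0.0,
                          generator=None, seed=0)
        _, _, hist = train(ds, cfg)
        assert hist.epoch_loss[-1] <= 0.5 * hist.epoch_loss[0]

    def test_seeded_determinism(self):
        ds = self._toy_dataset()
        cfg = TrainConfig(epochs=6, seed=11)
        _, _, h1 = train(ds, cfg)
        _, _, h2 = train(ds, cfg)
        assert h1.epoch_loss == h2.epoch_loss

    def test_exposure_history_follows_schedule(self):
        ds = self._toy_dataset()
        cfg = TrainConfig(epochs=5, f_min=0.25, seed=0)
        _, _, hist = train(ds, cfg)
        assert hist.exposure[0] == round(0.25 * len(ds))
        assert hist.exposure[-1] == len(ds)
        assert hist.exposure == sorted(hist.exposure)

    def test_single_class_warns_but_trains(self):
        ds = self._toy_dataset(n=6)
        ds.targets[:] = 1
        with pytest.warns(UserWarning, match="single class"):
            train(ds, TrainConfig(epochs=2, seed=0))

    def test_empty_dataset_rejected(self):
        ds = self._toy_dataset(n=4)
        ds.sample_ids, ds.values = [], []
        ds.targets = np.array([])
        with pytest.raises(ValueError):
            train(ds, TrainConfig(epochs=1))


class TestAggregation:
    @staticmethod
    def _records(probs, **meta):
        base = {"patient_id": "p0", "visit": 1, "side": "left", "site": "MF"}
        base.update(meta)
        rows = []
        for i, p in enumerate(probs):
            rows.append({"scan_id": f"s{i}", "probability": p,
                         "repetition": i + 1, **base})
        return pd.DataFrame(rows)

    def test_arithmetic_mean(self):
        out = aggregate_predictions(self._records([0.2, 0.4, 0.6]), "side")
        assert out["probability"].iloc[0] == pytest.approx(0.4)
        assert out["logit"].iloc[0] == pytest.approx(np.log(0.4 / 0.6))

    def test_single_member_identity(self):
        out = aggregate_predictions(self._records([0.73]), "site")
        assert out["probability"].iloc[0] == pytest.approx(0.73)

    def test_nested_equals_flat_for_equal_group_sizes(self):
        a = self._records([0.1, 0.2, 0.3], site="MF")
        b = self._records([0.5, 0.6, 0.7], site="ES")
        records = pd.concat([a, b], ignore_index=True)
        sites = aggregate_predictions(records, "site")
        nested = aggregate_predictions(sites, "side")
        flat = aggregate_predictions(records, "side")
        assert nested["probability"].iloc[0] == pytest.approx(
            flat["probability"].iloc[0])

    def test_aggregate_within_member_range(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.01, 0.99, 12)
        out = aggregate_predictions(self._records(probs), "patient")
        assert probs.min() <= out["probability"].iloc[0] <= probs.max()

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            aggregate_predictions(self._records([0.5]), "hospital")


class TestEndToEndOnCohort:
    def test_train_and_predict_on_tiny_cohort(self, tiny_cohort):
        ds = build_dataset(tiny_cohort, ("bmode",))
        model, state, hist = train(ds, TrainConfig(epochs=3, seed=0))
        preds = predict_dataset(model, ds)
        assert len(preds) == len(ds)
        assert preds["probability"].between(0, 1).all()
        # every sample visited at least once by the final (full) epoch
        assert set(state.scores) == set(ds.sample_ids)
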