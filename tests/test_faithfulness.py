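"""Insertion/deletion curves, trapezoidal summaries, IROF, ranker harness."""

import itertools

import numpy as np
import pytest

from layerlens import (
    AffineLogitModel,
    LayerLabelMap,
    RankedLayerList,
    auc_delta,
    auc_deletion,
    auc_insertion,
    compare_rankers,
    deletion_curve,
    evaluate_ranking,
    insertion_curve,
    irof,
)
from layerlens.faithfulness import random_ranker, volume_ranker


class ConstantModel:
    def predict_logit(self, x):
        return 1.3


@pytest.fixture(scope="module")
def positive_model(toy_scan):
    """Affine logit, non-negative weights, zero bias: every layer has a
    non-negative analytic contribution."""
    rng = np.random.default_rng(5)
    w = rng.uniform(0.0, 0.1, (2, *toy_scan.shape))
    return AffineLogitModel(w, bias=0.0)


def _contributions(model, scan, labels):
    values = scan.values()
    return {c: float(np.sum(model.weights[:, labels.labels == c]
                            * values[:, labels.labels == c]))
            for c in range(1, 7)}


class TestCurves:
    def test_constant_model_flat_curves(self, toy_scan, six_layer_labels):
        ranking = RankedLayerList((1, 2, 3, 4, 5, 6))
        ins = insertion_curve(ConstantModel(), toy_scan, six_layer_labels, ranking)
        dele = deletion_curve(ConstantModel(), toy_scan, six_layer_labels, ranking)
        assert len(ins) == len(dele) == 7
        np.testing.assert_allclose(ins, 1.3)
        np.testing.assert_allclose(dele, 1.3)

    def test_insertion_steps_match_analytic_contributions(
            self, toy_scan, six_layer_labels, positive_model):
        contrib = _contributions(positive_model, toy_scan, six_layer_labels)
        order = (3, 1, 5, 2, 6, 4)
        ins = insertion_curve(positive_model, toy_scan, six_layer_labels, order)
        assert ins[0] == pytest.approx(0.0, abs=1e-12)  # empty volume, zero bias
        for k, code in enumerate(order, start=1):
            assert ins[k] - ins[k - 1] == pytest.approx(contrib[code], abs=1e-10)
        assert ins[-1] == pytest.approx(
            positive_model.predict_logit(toy_scan.values()), abs=1e-10)

    def test_deletion_of_everything_reaches_empty_logit(
            self, toy_scan, six_layer_labels, positive_model):
        dele = deletion_curve(positive_model, toy_scan, six_layer_labels,
                              (1, 2, 3, 4, 5, 6))
        assert dele[-1] == pytest.approx(
            positive_model.predict_logit(np.zeros_like(toy_scan.values())),
            abs=1e-12)

    def test_insertion_deletion_antisymmetry_for_affine_model(
            self, toy_scan, six_layer_labels, positive_model):
        """Additive contributions give i_k + d_k = i_0 + i_K at every step."""
        order = (5, 3, 1, 6, 2, 4)
        ins = insertion_curve(positive_model, toy_scan, six_layer_labels, order)
        dele = deletion_curve(positive_model, toy_scan, six_layer_labels, order)
        np.testing.assert_allclose(ins + dele, ins[0] + ins[-1], atol=1e-10)

    def test_mirror_identity_for_equal_contributions(self, six_layer_labels):
        """With equal per-layer contributions, d_k equals i_{K-k}."""
        from layerlens import MultimodalScan, ScanMetadata, VolumeGrid

        values = np.ones(six_layer_labels.shape)
        scan = MultimodalScan("eq", [VolumeGrid(values)],
                              ScanMetadata(patient_id="p"))
        model = AffineLogitModel(np.full((1, *six_layer_labels.shape), 0.02))
        order = (2, 4, 6, 1, 3, 5)
        ins = insertion_curve(model, scan, six_layer_labels, order)
        dele = deletion_curve(model, scan, six_layer_labels, order)
        np.testing.assert_allclose(dele, ins[::-1], atol=1e-12)

    def test_single_layer_ranking_gives_two_points(self, toy_scan,
                                                   six_layer_labels):
        ins = insertion_curve(ConstantModel(), toy_scan, six_layer_labels, (4,))
        assert len(ins) == 2


class TestSummaries:
    def test_trapezoid_hand_example(self):
        assert auc_insertion([0.0, 1.0, 2.0]) == pytest.approx(1.0)

    def test_constant_curve_auc_is_constant(self):
        assert auc_insertion([0.8] * 7) == pytest.approx(0.8)

    def test_auc_delta_is_difference(self):
        rng = np.random.default_rng(0)
        ins, dele = rng.normal(size=7), rng.normal(size=7)
        assert auc_delta(ins, dele) == auc_insertion(ins) - auc_deletion(dele)
        assert auc_delta(ins, ins) == 0.0

    def test_curve_too_short_rejected(self):
        with pytest.raises(ValueError):
            auc_insertion([1.0])

    @pytest.mark.parametrize(
        "ins,dele,value,flagged",
        [([0.0, 2.0], [0.5, 1.0], 4.0, False),
         ([0.0, 0.0], [0.0, 0.5], 0.0, True),
         ([1.0, 2.0], [-0.5, 1.0], -4.0, True)],
    )
    def test_irof_examples(self, ins, dele, value, flagged):
        res = irof(ins, dele, eps=1e-8)
        assert res.value == pytest.approx(value, rel=1e-6)
        assert res.flagged == flagged


class TestRankingOptimality:
    def test_true_contribution_order_maximizes_auc_insertion(
            self, toy_scan, six_layer_labels, positive_model):
        """Exhaustive check over all 720 layer permutations: descending
        analytic contribution attains the maximum AUC-insertion."""
        contrib = _contributions(positive_model, toy_scan, six_layer_labels)
        best_order = tuple(sorted(contrib, key=contrib.get, reverse=True))
        target = auc_insertion(insertion_curve(
            positive_model, toy_scan, six_layer_labels, best_order))
        aucs = []
        values = toy_scan.values()
        i0 = 0.0
        for perm in itertools.permutations(range(1, 7)):
            # closed-form insertion AUC for the affine model avoids 720*7
            # forward passes: each contribution enters (K - k + 1/2)/K trapezoids
            auc = i0 + sum(contrib[c] * (6 - k + 0.5) / 6
                           for k, c in enumerate(perm, start=1))
            aucs.append((auc, perm))
        max_auc, argmax = max(aucs)
        assert argmax == best_order
        assert target == pytest.approx(max_auc, abs=1e-9)


class TestRankerHarness:
    def test_single_scan_metrics_equal_scan_level(self, toy_scan,
                                                  six_layer_labels,
                                                  positive_model):
        dataset = [(toy_scan.values(), six_layer_labels)]
        rankers = {"volume": volume_ranker()}
        per_scan, summary = compare_rankers(positive_model, dataset, rankers)
        assert len(per_scan) == 1
        row = summary.iloc[0]
        assert row["auc_delta"] == pytest.approx(per_scan["auc_delta"].iloc[0])

    def test_oracle_ranking_beats_reversed(self, toy_scan, six_layer_labels,
                                           positive_model):
        contrib = _contributions(positive_model, toy_scan, six_layer_labels)
        best = tuple(sorted(contrib, key=contrib.get, reverse=True))
        _, m_best = evaluate_ranking(positive_model, toy_scan.values(),
                                     six_layer_labels, best)
        _, m_worst = evaluate_ranking(positive_model, toy_scan.values(),
                                      six_layer_labels, best[::-1])
        assert m_best.auc_insertion > m_worst.auc_insertion
        assert m_best.auc_delta > m_worst.auc_delta

    def test_random_ranker_deterministic_per_seed(self, six_layer_labels):
        a, b = random_ranker(7), random_ranker(7)
        assert a(3, None, six_layer_labels).layers == b(3, None, six_layer_labels).layers
        assert a(3, None, six_layer_labels).layers != a(4, None, six_layer_labels).layers

    def test_metrics_invariant_to_consistent_relabeling(
            self, toy_scan, six_layer_labels, positive_model):
        """Swapping layer codes 1 <-> 6 everywhere leaves all metrics equal."""
        perm = {0: 0, 1: 6, 2: 2, 3: 3, 4: 4, 5: 5, 6: 1}
        relabeled = LayerLabelMap(
            np.vectorize(perm.get)(six_layer_labels.labels).astype(np.int16))
        order = (3, 1, 5, 2, 6, 4)
        order_re = tuple(perm[c] for c in order)
        _, m1 = evaluate_ranking(positive_model, toy_scan.values(),
                                 six_layer_labels, order)
        _, m2 = evaluate_ranking(positive_model, toy_scan.values(),
                                 relabeled, order_re)
        assert m1.auc_insertion == pytest.approx(m2.auc_insertion, abs=1e-12)
        assert m1.auc_delta == pytest.approx(m2.auc_delta, abs=1e-12)

    def test_duplicate_ranking_rejected(self):
        with pytest.raises(ValueError):
            RankedLayerList((1, 1, 2))
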