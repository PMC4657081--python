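"""Boosting trainer and weighted-vote predictor."""

import itertools
import math

import numpy as np
import pytest

from mirnaclassify import (
    EnsembleModel,
    GaussianBenchSpec,
    MinMaxParams,
    TrainingConfig,
    WeightedSampleSet,
    error_rate,
    gen_gaussian_bench,
    init_weights,
    theta_from_phi,
    train_ensemble,
    train_instance,
    update_weights,
)
from mirnaclassify.ensemble import BaseInstance
from mirnaclassify.errors import BalanceContractError, LabelError


class FixedPredictor:
    """Stub learner returning a frozen prediction vector."""

    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=int)

    def predict(self, X):
        return self.preds[: len(X)]


def stub_model(instances, dim=2):
    scaler = MinMaxParams(mins=np.zeros(dim), ranges=np.ones(dim))
    return EnsembleModel(
        instances=instances,
        config=TrainingConfig(T=len(instances)),
        scaler=scaler,
        feature_names=[f"f{i}" for i in range(dim)],
    )


def instance_from_phi(phi, preds):
    theta = theta_from_phi(phi)
    return BaseInstance(FixedPredictor(preds), phi, theta,
                        math.log(1 / theta), [])


class TestInitWeights:
    def test_stated_formula(self):
        w = init_weights([1, 1, 0, 0, 0], C_P=1.0, C_N=0.6)
        assert np.allclose(w, [0.2, 0.2, 0.12, 0.12, 0.12])

    def test_equal_costs_give_equal_weights(self):
        w = init_weights([1, 0, 1, 0], C_P=0.5, C_N=0.5)
        assert np.allclose(w, w[0])

    def test_positives_outweigh_negatives_at_default_costs(self):
        w = init_weights([1, 0, 0, 0, 0, 0], C_P=1.0, C_N=0.6)
        assert w[0] > w[1:].max()

    def test_non_binary_labels_rejected(self):
        with pytest.raises(LabelError):
            init_weights([1, 2, 0], 1.0, 0.6)

    def test_single_class_rejected(self):
        with pytest.raises(LabelError):
            init_weights([1, 1, 1], 1.0, 0.6)


class TestErrorRate:
    def test_perfect_classifier_clamped_to_epsilon(self):
        y = np.array([1] * 3 + [0] * 3)
        phi = error_rate(FixedPredictor(y), np.zeros((6, 2)), y)
        assert phi == pytest.approx(1e-6)

    def test_one_sided_classifier_clamped_below_half(self):
        y = np.array([1] * 3 + [0] * 3)
        phi = error_rate(FixedPredictor(np.ones(6, dtype=int)),
                         np.zeros((6, 2)), y)
        assert phi == pytest.approx(0.5 - 1e-6)

    def test_error_is_one_minus_geometric_mean(self):
        # SE = 0.96 (96/100 positives), SP = 0.81 (81/100 negatives)
        y = np.array([1] * 100 + [0] * 100)
        pred = np.concatenate([
            np.ones(96), np.zeros(4), np.ones(19), np.zeros(81)
        ]).astype(int)
        phi = error_rate(FixedPredictor(pred), np.zeros((200, 2)), y)
        assert phi == pytest.approx(1 - math.sqrt(0.96 * 0.81))


class TestThetaFromPhi:
    @pytest.mark.parametrize("phi,expected", [
        (0.2, 0.25),
        (0.1, 1 / 9),
        (0.5 - 1e-9, pytest.approx(1.0, abs=1e-8)),
    ])
    def test_odds_transform(self, phi, expected):
        assert theta_from_phi(phi) == pytest.approx(expected)

    @pytest.mark.parametrize("phi", [0.0, 0.5, 0.7, -0.1])
    def test_domain_enforced(self, phi):
        with pytest.raises(ValueError):
            theta_from_phi(phi)


class TestUpdateWeights:
    def test_misclassified_weight_unchanged_before_normalization(self):
        w = np.array([0.4, 0.6])
        y, p = np.array([1, 0]), np.array([0, 0])  # first sample wrong
        out = update_weights(w, y, p, theta=0.25)
        # pre-normalization: [0.4, 0.15]; mass restored to 1.0
        assert np.allclose(out, np.array([0.4, 0.15]) * (1.0 / 0.55))
        assert out[0] / out[1] == pytest.approx(0.4 / 0.15)

    def test_correct_weight_scaled_by_theta(self):
        w = np.array([1.0, 1.0])
        out = update_weights(w, np.array([1, 0]), np.array([1, 1]), theta=0.25)
        assert out[0] / out[1] == pytest.approx(0.25)

    def test_all_correct_is_identity_after_normalization(self):
        w = np.array([0.3, 0.5, 0.2])
        y = np.array([1, 0, 1])
        out = update_weights(w, y, y, theta=0.1)
        assert np.allclose(out, w)

    def test_total_mass_preserved(self):
        w = np.array([0.1, 0.2, 0.7])
        out = update_weights(w, np.array([1, 0, 0]), np.array([1, 1, 0]), 0.3)
        assert out.sum() == pytest.approx(w.sum())

    def test_relative_weight_never_decreases_for_always_wrong_sample(self):
        w = np.ones(4) / 4
        y = np.array([1, 0, 0, 0])
        pred = np.array([0, 0, 0, 0])  # sample 0 always misclassified
        for theta in (0.3, 0.5, 0.2):
            w = update_weights(w, y, pred, theta)
        assert w[0] == w.max()

    def test_prenormalization_weights_non_increasing(self):
        w = np.array([0.2, 0.8])
        y, p = np.array([1, 0]), np.array([1, 1])
        theta = 0.4
        pre = np.where(y == p, w * theta, w)
        assert (pre <= w).all()


class TestTrainInstance:
    def test_separable_data_fits_exactly(self, separable_xy):
        X, y = separable_xy
        learner = train_instance(X, y, None, {"C": 1.0, "kernel": "rbf",
                                              "gamma": "scale"}, seed=0)
        assert (learner.predict(X) == y).all()

    def test_balance_contract_enforced(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(BalanceContractError):
            train_instance(X[:30], y[:30], None,
                           {"C": 1.0, "kernel": "rbf", "gamma": "scale"}, 0)

    def test_double_weight_equals_duplication(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(3, 1, (10, 2))])
        y = np.array([1] * 10 + [0] * 10)
        params = {"C": 1.0, "kernel": "rbf", "gamma": 0.5}
        w = np.ones(20)
        w[3] = 2.0
        weighted = train_instance(X, y, w, params, seed=0)
        # duplication oracle: sample 3 twice, plus a duplicated negative to
        # keep the set balanced at its weight total
        Xd = np.vstack([X, X[3], X[15]])
        yd = np.concatenate([y, [y[3]], [y[15]]])
        wd = np.ones(22)
        wd[15] = 2.0
        wd[3] = wd[20] = wd[21] = 1.0
        # compare on a probe grid via decision-function sign
        duplicated = train_instance(Xd, yd, None, params, seed=0)
        probe = rng.normal(1.5, 2.0, (50, 2))
        agree = (weighted.predict(probe) == duplicated.predict(probe)).mean()
        assert agree >= 0.95

    def test_deterministic_for_fixed_seed(self, separable_xy):
        X, y = separable_xy
        params = {"C": 1.0, "kernel": "rbf", "gamma": "scale"}
        a = train_instance(X, y, None, params, seed=3)
        b = train_instance(X, y, None, params, seed=3)
        probe = np.random.default_rng(0).normal(2.5, 2, (30, 2))
        assert np.array_equal(a.decision_function(probe),
                              b.decision_function(probe))


class TestTrainEnsemble:
    def test_single_iteration_reduces_to_first_instance(self, small_bench):
        model = train_ensemble(small_bench, TrainingConfig(T=1, seed=0))
        assert len(model.instances) == 1
        labels, _ = model.predict(small_bench.features)
        solo = model.instances[0].learner.predict(
            model.scaler.transform(small_bench.features))
        assert np.array_equal(labels, solo)

    def test_identical_seed_gives_identical_traces(self, small_bench):
        cfg = TrainingConfig(T=5, seed=9)
        a = train_ensemble(small_bench, cfg)
        b = train_ensemble(small_bench, cfg)
        assert [r["phi"] for r in a.training_log] == \
               [r["phi"] for r in b.training_log]
        assert [r["indices_digest"] for r in a.training_log] == \
               [r["indices_digest"] for r in b.training_log]

    def test_every_instance_trained_balanced(self, small_bench):
        model = train_ensemble(small_bench, TrainingConfig(T=5, seed=2))
        y = small_bench.labels
        k = small_bench.n_pos
        for inst in model.instances:
            sub = y[inst.training_indices]
            assert (sub == 1).sum() == k
            assert (sub == 0).sum() == k

    def test_misclassified_negatives_gain_selection_probability(self, small_bench):
        """After one update, negatives misclassified by M_1 carry strictly
        more weight (hence selection probability) than initially
        equal-weight negatives it classified correctly."""
        y = small_bench.labels
        model = train_ensemble(small_bench, TrainingConfig(T=2, seed=0))
        m1 = model.instances[0]
        pred = m1.learner.predict(model.scaler.transform(small_bench.features))
        w = init_weights(y, 1.0, 0.6)
        w1 = update_weights(w, y, pred, m1.theta)
        neg = y == 0
        wrong_neg = neg & (pred != y)
        right_neg = neg & (pred == y)
        assert wrong_neg.any() and right_neg.any()
        assert w1[wrong_neg].min() > w1[right_neg].max()

    def test_single_class_input_rejected(self):
        data = WeightedSampleSet(
            features=np.random.default_rng(0).random((10, 3)),
            labels=np.ones(10, dtype=int))
        with pytest.raises(LabelError):
            train_ensemble(data, TrainingConfig(T=1))

    def test_vote_weight_decreases_with_error(self):
        phis = [0.05, 0.15, 0.3, 0.45]
        votes = [math.log(1 / theta_from_phi(p)) for p in phis]
        assert all(a > b for a, b in zip(votes, votes[1:]))
        assert all(v > 0 for v in votes)


class TestPredict:
    def test_unanimous_instances_give_extreme_scores(self):
        inst = [instance_from_phi(0.2, np.ones(4, dtype=int)),
                instance_from_phi(0.3, np.ones(4, dtype=int))]
        labels, scores = stub_model(inst).predict(np.zeros((4, 2)))
        assert (labels == 1).all() and (scores == 1.0).all()

    def test_heavier_instance_dominates_disagreement(self):
        # vote weights 2 log 2 vs log 2: phi chosen so theta = 0.25, 0.5
        strong = instance_from_phi(0.2, np.ones(3, dtype=int))
        weak = instance_from_phi(1 / 3, np.zeros(3, dtype=int))
        assert strong.vote_weight == pytest.approx(2 * math.log(2))
        assert weak.vote_weight == pytest.approx(math.log(2))
        labels, _ = stub_model([strong, weak]).predict(np.zeros((3, 2)))
        assert (labels == 1).all()

    def test_exact_tie_resolves_positive(self):
        a = instance_from_phi(0.25, np.ones(2, dtype=int))
        b = instance_from_phi(0.25, np.zeros(2, dtype=int))
        labels, scores = stub_model([a, b]).predict(np.zeros((2, 2)))
        assert (labels == 1).all()
        assert scores == pytest.approx([0.5, 0.5])

    def test_vote_matches_bruteforce_enumeration(self):
        """Weighted vote agrees with explicit per-sample mass summation
        over all instance-prediction combinations (<= 5 instances)."""
        rng = np.random.default_rng(6)
        n_samples = 20
        for n_inst in range(1, 6):
            phis = rng.uniform(0.05, 0.45, n_inst)
            preds = rng.integers(0, 2, size=(n_inst, n_samples))
            insts = [instance_from_phi(p, pr) for p, pr in zip(phis, preds)]
            labels, scores = stub_model(insts).predict(np.zeros((n_samples, 2)))
            total = sum(i.vote_weight for i in insts)
            for s in range(n_samples):
                mass = sum(i.vote_weight for i, pr in zip(insts, preds)
                           if pr[s] == 1)
                assert labels[s] == (1 if mass >= total / 2 else 0)
                assert scores[s] == pytest.approx(mass / total)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, small_bench, tmp_path):
        import json
        model = train_ensemble(small_bench, TrainingConfig(T=3, seed=1))
        path = tmp_path / "model.json"
        model.save(path)
        back = EnsembleModel.load(path)
        l1, s1 = model.predict(small_bench.features)
        l2, s2 = back.predict(small_bench.features)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)
        with open(path) as fh:
            payload = json.load(fh)
        assert payload["schema_version"] == 1


class TestCostSensitivity:
    def test_lower_negative_cost_raises_instance_sensitivity(self):
        """The cost asymmetry enters the base-learner fit: with C_N = 0.6
        the positives carry relatively more fit weight than with
        C_N = 1.0, so the first instance recovers more real positives on
        a holdout (directional mean across seeds).

        The instance level is where the cost bias acts mechanically; over
        many boosting iterations its net ensemble-level effect depends on
        the weight dynamics of the data at hand (heavily favored
        positives also decay faster once classified correctly).
        """
        m1_se = {0.6: [], 1.0: []}
        for seed in range(1, 13):
            spec = GaussianBenchSpec(n_pos=60, n_neg=1200, dim=10,
                                     separation=2.0, neg_clusters=2, seed=seed)
            data = gen_gaussian_bench(spec)
            holdout = gen_gaussian_bench(
                GaussianBenchSpec(n_pos=60, n_neg=1200, dim=10,
                                  separation=2.0, neg_clusters=2,
                                  seed=seed + 500))
            for cn in (0.6, 1.0):
                model = train_ensemble(
                    data, TrainingConfig(C_P=1.0, C_N=cn, T=1, seed=seed))
                labels, _ = model.predict(holdout.features)
                m1_se[cn].append(labels[holdout.labels == 1].mean())
        assert np.mean(m1_se[0.6]) >= np.mean(m1_se[1.0])
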