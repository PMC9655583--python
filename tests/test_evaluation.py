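import itertools

import numpy as np
import pytest

from seqdsn.datasets import DomainDataset, make_cv_plan
from seqdsn.evaluation import (average_precision, compute_metrics,
                               roc_auc, run_baseline, run_cross_validation)
from seqdsn.model import ModelConfig
from seqdsn.sequence_io import SiteRecord
from seqdsn.training import TrainConfig


from tests_support import brute_force_ap, brute_force_auc


class TestRankingMetrics:
    def test_auc_matches_all_pairs_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = rng.integers(10, 60)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = rng.random(n)
            if trial % 3 == 0:
                scores = np.round(scores, 1)  # force ties
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-9)

    def test_ap_matches_rank_precision_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(10, 60)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = rng.random(n)  # continuous, untied
            assert average_precision(labels, scores) == pytest.approx(
                brute_force_ap(labels, scores), abs=1e-9)

    def test_against_sklearn(self):
        from sklearn.metrics import average_precision_score, roc_auc_score
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        scores = np.round(rng.random(200), 2)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)
        assert average_precision(labels, scores) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)

    def test_perfect_separation(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.linspace(0, 1, 10)
        assert roc_auc(labels, scores) == 1.0
        assert average_precision(labels, scores) == 1.0

    def test_random_labels_auc_half(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 10000)
        scores = rng.random(10000)
        assert roc_auc(labels, scores) == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert roc_auc(np.ones(5, int), np.random.rand(5)) is None
        with pytest.warns(UserWarning, match="undefined"):
            assert average_precision(np.zeros(5, int), np.random.rand(5)) is None


class TestThresholdMetrics:
    def test_worked_example(self):
        # counts TP=9, FN=1, TN=99, FP=1
        scores = np.array([0.9] * 9 + [0.1] + [0.05] * 99 + [0.8])
        labels = np.array([1] * 10 + [0] * 100)
        rep = compute_metrics(scores, labels)
        assert (rep.counts.tp, rep.counts.fn, rep.counts.tn,
                rep.counts.fp) == (9, 1, 99, 1)
        assert rep.acc == pytest.approx(108 / 110)
        assert rep.spe == pytest.approx(0.99)
        assert rep.pre == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(0.9)

    def test_exhaustive_small_count_grid(self):
        """Every confusion table with counts <= 5 matches the formulas."""
        for tp, tn, fp, fn in itertools.product(range(6), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            scores = np.concatenate([
                np.ones(tp), np.zeros(fn),        # positives
                np.ones(fp), np.zeros(tn),        # negatives
            ])
            labels = np.concatenate([
                np.ones(tp + fn, int), np.zeros(fp + tn, int)])
            rep = compute_metrics(scores, labels)
            total = tp + tn + fp + fn
            assert rep.acc == pytest.approx((tn + tp) / total)
            assert rep.spe == pytest.approx(tn / (tn + fp))
            pre = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn)
            assert rep.pre == pytest.approx(pre)
            f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
            assert rep.f1 == pytest.approx(f1)
            assert rep.counts.total == total

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.2], [1])


def _toy_dataset(n, domain, seed, separable=False, constant=False, L=8):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n // 2, int), np.zeros(n - n // 2, int)])
    if constant:
        rows = np.zeros((n, L), dtype=int)
    else:
        rows = rng.integers(0, 4, size=(n, L))
        if separable:
            rows[labels == 1, :3] = [2, 3, 3]  # plant GUU in positives
    enc = np.eye(4)[rows]
    prov = [SiteRecord(f"{domain}{i}", 0, int(labels[i]), domain)
            for i in range(n)]
    return DomainDataset(enc, labels, domain, prov)


class TestBaselines:
    def test_logistic_on_separable_windows(self):
        train = _toy_dataset(200, "source", 0, separable=True)
        test = _toy_dataset(100, "target", 1, separable=True)
        rep = run_baseline("logistic", train, test)
        assert rep.auc > 0.95

    def test_constant_features_chance_level(self):
        train = _toy_dataset(100, "source", 2, constant=True)
        test = _toy_dataset(100, "target", 3, constant=True)
        rep = run_baseline("random_forest", train, test)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_unknown_name_lists_options(self):
        train = _toy_dataset(20, "source", 4)
        with pytest.raises(ValueError, match="naive_bayes"):
            run_baseline("mlp", train, train)

    def test_seeded_learner_deterministic(self):
        train = _toy_dataset(100, "source", 5, separable=True)
        test = _toy_dataset(60, "target", 6, separable=True)
        a = run_baseline("random_forest", train, test, seed=1)
        b = run_baseline("random_forest", train, test, seed=1)
        assert a.as_dict() == b.as_dict()

    @pytest.mark.parametrize("name", ["naive_bayes", "knn", "svm", "xgboost"])
    def test_all_baselines_run(self, name):
        train = _toy_dataset(60, "source", 7, separable=True)
        test = _toy_dataset(40, "target", 8, separable=True)
        rep = run_baseline(name, train, test)
        assert 0.0 <= rep.auc <= 1.0


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def cv_result(self):
        from seqdsn.synthetic import preset_config, generate_domain_pair
        cfg = preset_config("easy", seed=0, n_source_pos=60, n_source_neg=60,
                            n_target_pos=24, n_target_neg=48)
        source, target, _ = generate_domain_pair(cfg)
        pos = [r.key for r in target.provenance if r.label == 1]
        neg = [r.key for r in target.provenance if r.label == 0]
        plan = make_cv_plan(pos, neg, groups=2, seed=0)
        tc = TrainConfig(epochs=1, seed=0, mode="dual_classifier")
        reports, mean = run_cross_validation(
            source, target, plan, tc,
            ModelConfig(window_length=cfg.length, conv_filters=4, repr_dim=4))
        return plan, reports, mean

    def test_toy_plan_yields_four_reports(self, cv_result):
        _, reports, mean = cv_result
        assert len(reports) == 4
        assert mean["n_folds"] == 4

    def test_mean_is_arithmetic(self, cv_result):
        _, reports, mean = cv_result
        accs = [rep.acc for _, rep in reports]
        assert mean["acc"] == pytest.approx(np.mean(accs))

    def test_plan_id_mismatch_rejected(self, cv_result):
        plan, _, _ = cv_result
        from seqdsn.synthetic import preset_config, generate_domain_pair
        cfg = preset_config("easy", seed=3, n_source_pos=30, n_source_neg=30,
                            n_target_pos=12, n_target_neg=24)
        source, target, _ = generate_domain_pair(cfg)
        with pytest.raises(ValueError, match="plan ids"):
            run_cross_validation(source, target, plan,
                                 TrainConfig(epochs=1, seed=0,
                                             mode="dual_classifier"))
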