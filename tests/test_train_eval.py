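"""Splitting, threshold selection, metrics, SeedMatch, and a training smoke."""

import numpy as np
import pytest

from duplexmap import (FeaturizerConfig, PairRecord, RnaSequence, SynthConfig,
                       TrainConfig, compute_metrics, generate_pairs,
                       seedmatch_score, seedmatch_scores, select_threshold,
                       stratified_folds, train_model)


def rank_sum_auc(scores, labels):
    """Mann-Whitney AUC with tie correction (independent ROC-AUC oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))


def youden_sweep_oracle(scores, labels):
    """Best J over every possible cut point, by exhaustive evaluation."""
    best_j = -np.inf
    for t in np.unique(np.concatenate([scores, [0.0, 1.0],
                                       (np.sort(scores)[:-1] +
                                        np.sort(scores)[1:]) / 2])):
        calls = scores >= t
        tpr = (calls & (labels == 1)).sum() / (labels == 1).sum()
        fpr = (calls & (labels == 0)).sum() / (labels == 0).sum()
        best_j = max(best_j, tpr - fpr)
    return best_j


class TestStratifiedFolds:
    def test_balanced_partition(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = stratified_folds(y, k=5, seed=42)
        assert sorted(np.concatenate(folds).tolist()) == list(range(100))
        for f in folds:
            assert len(f) == 20
            assert (y[f] == 1).sum() == 10

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 30)
        a = stratified_folds(y, k=3, seed=7)
        b = stratified_folds(y, k=3, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_ratio_within_one_sample(self):
        y = np.array([0] * 33 + [1] * 20)
        folds = stratified_folds(y, k=4, seed=0)
        global_ratio = 20 / 53
        for f in folds:
            assert abs((y[f] == 1).sum() - global_ratio * len(f)) <= 1

    def test_k_exceeding_class_count_rejected(self):
        y = np.array([0] * 20 + [1] * 2)
        with pytest.raises(ValueError):
            stratified_folds(y, k=3, seed=0)


class TestThresholdSelection:
    def test_maximizes_youden_j(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            scores = rng.random(n).round(2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            t = select_threshold(scores, labels)
            calls = scores >= t
            tpr = (calls & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (calls & (labels == 0)).sum() / (labels == 0).sum()
            assert tpr - fpr == pytest.approx(
                youden_sweep_oracle(scores, labels))

    def test_hand_example(self):
        scores = np.array([0.1, 0.35, 0.4, 0.8])
        labels = np.array([0, 1, 0, 1])
        t = select_threshold(scores, labels)
        # J = 0.5 at any cut in (0.1, 0.35]; tie rule picks the smallest
        # candidate, the midpoint 0.225
        assert t == pytest.approx(0.225)

    def test_perfect_separation_picks_smallest_gap_candidate(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = select_threshold(scores, labels)
        assert t == pytest.approx(0.5)  # midpoint of 0.2 and 0.8
        assert 0.2 < t <= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.3, 0.6]), np.array([1, 1]))


class TestComputeMetrics:
    def test_perfect_ranking(self):
        rep = compute_metrics(np.array([0.9, 0.8, 0.2, 0.1]),
                              np.array([1, 1, 0, 0]), 0.5)
        assert rep.roc_auc == 1.0
        assert rep.accuracy == 1.0
        assert rep.f1 == 1.0

    def test_constant_scores_are_chance(self):
        rep = compute_metrics(np.full(20, 0.5),
                              np.array([0, 1] * 10), 0.5)
        assert rep.roc_auc == pytest.approx(0.5)

    def test_hand_confusion_matrix(self):
        rep = compute_metrics(np.array([0.9, 0.8, 0.3, 0.2]),
                              np.array([1, 0, 1, 0]), 0.5)
        assert rep.accuracy == 0.5
        assert rep.recall == 0.5
        assert rep.roc_auc == pytest.approx(0.75)

    def test_roc_auc_equals_rank_sum_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 60))
            scores = rng.random(n).round(1)  # force ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            rep = compute_metrics(scores, labels, 0.5)
            assert rep.roc_auc == pytest.approx(
                rank_sum_auc(scores, labels), abs=1e-12)

    def test_no_positive_calls_flags_undefined_precision(self):
        rep = compute_metrics(np.array([0.1, 0.2, 0.3, 0.4]),
                              np.array([0, 1, 0, 1]), 0.9)
        assert rep.precision == 0.0
        assert rep.precision_undefined

    def test_f1_is_harmonic_mean(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        rep = compute_metrics(scores, labels, 0.5)
        if rep.precision + rep.recall > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall))


class TestSeedMatch:
    def _rec(self, p, m):
        return PairRecord(RnaSequence(p), RnaSequence(m), 1)

    def test_perfect_complement(self):
        assert seedmatch_score(self._rec("AAAAAAA", "UUUUUUU")) == 1.0

    def test_no_complementarity(self):
        assert seedmatch_score(self._rec("AAAAAAA", "AAAAAAA")) == 0.0

    def test_monotone_in_added_complementarity(self):
        p = "GGGGGGG"
        prev = -1.0
        for n_comp in range(8):
            m = "C" * n_comp + "A" * (7 - n_comp)
            score = seedmatch_score(self._rec(p, m))
            assert score >= prev
            prev = score
        assert prev == 1.0

    def test_antiparallel_alignment(self):
        # 5'-GGGAAAA / site read 3'->5' must complement the window
        p = "GGGAAAA"
        m = "UUUUCCC"  # reversed complement of GGGAAAA
        assert seedmatch_score(self._rec(p, m)) == 1.0

    def test_wobble_excluded_by_default(self):
        score = seedmatch_score(self._rec("GGGGGGG", "UUUUUUU"))
        assert score == 0.0
        score_gu = seedmatch_score(self._rec("GGGGGGG", "UUUUUUU"),
                                   allow_gu=True)
        assert score_gu == 1.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            seedmatch_score(self._rec("ACGU", "ACGUACGUA"), w=7)


class TestTrainModel:
    def test_learns_planted_signal(self):
        records = generate_pairs(SynthConfig(n_pairs=600, seed=42))
        tcfg = TrainConfig(seed=42, max_epochs=8)
        model, info = train_model(records, tcfg)
        assert len(info["history"]) <= tcfg.max_epochs
        best_auc = max(h["val_roc_auc"] for h in info["history"])
        assert best_auc > 0.75  # quick smoke; spec-scale run lives elsewhere
        assert best_auc > info["history"][0]["val_roc_auc"] - 1e-9
        assert 0.0 <= info["threshold"] <= 1.0

    def test_seeded_runs_are_identical(self):
        records = generate_pairs(SynthConfig(n_pairs=300, seed=42))
        tcfg = TrainConfig(seed=42, max_epochs=2)
        _, a = train_model(records, tcfg)
        _, b = train_model(records, tcfg)
        assert a["history"][0]["train_loss"] == b["history"][0]["train_loss"]
        assert a["threshold"] == b["threshold"]
        assert [h["val_roc_auc"] for h in a["history"]] == \
            [h["val_roc_auc"] for h in b["history"]]

    def test_single_class_rejected(self):
        records = [r for r in generate_pairs(SynthConfig(n_pairs=40, seed=1))
                   if r.label == 1]
        with pytest.raises(ValueError):
            train_model(records, TrainConfig(max_epochs=1))
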