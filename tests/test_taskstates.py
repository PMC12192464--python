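"""Pair-counting metric oracles, clustering and classification contracts.

The formula-defined metrics are verified against exhaustive pair
enumeration and against scikit-learn's reference implementations as an
independent cross-check.
"""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import (adjusted_rand_score, fowlkes_mallows_score,
                             normalized_mutual_info_score)

from fcdyn.dynamics import WindowedFC
from fcdyn.taskstates import (adjusted_rand, classify_tasks,
                              cluster_windows, clustering_metrics,
                              embed_tsne, normalized_mutual_information,
                              pair_counts, time_stratified_folds)


def brute_pair_counts(Y, T):
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(len(Y)), 2):
        sy, st = Y[i] == Y[j], T[i] == T[j]
        if sy and st:
            tp += 1
        elif st and not sy:
            fp += 1
        elif sy and not st:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestPairCounts:
    def test_identity_labeling(self):
        pc = pair_counts(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]))
        assert (pc.TP, pc.FP, pc.FN, pc.TN) == (2, 0, 0, 4)

    def test_worked_example(self):
        """T=[0,0,1,1], Y=[0,1,1,1]: hand enumeration of all 6 pairs."""
        pc = pair_counts(np.array([0, 1, 1, 1]), np.array([0, 0, 1, 1]))
        assert (pc.TP, pc.FP, pc.FN, pc.TN) == (1, 1, 2, 2)

    def test_conservation(self, rng):
        for _ in range(20):
            Y = rng.integers(0, 3, 7)
            T = rng.integers(0, 3, 7)
            pc = pair_counts(Y, T)
            assert pc.total == 21

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            Y = rng.integers(0, 3, n)
            T = rng.integers(0, 3, n)
            pc = pair_counts(Y, T)
            assert (pc.TP, pc.FP, pc.FN, pc.TN) == brute_pair_counts(Y, T)


class TestClusteringMetrics:
    def test_perfect_agreement(self):
        rep = clustering_metrics(np.array([0, 0, 1, 1, 2]),
                                 np.array(["a", "a", "b", "b", "c"]))
        for v in (rep.MI, rep.FM, rep.AR, rep.RI, rep.accuracy, rep.BAS):
            assert v == pytest.approx(1.0)

    def test_worked_example_fm_and_ri(self):
        rep = clustering_metrics(np.array([0, 1, 1, 1]), np.array([0, 0, 1, 1]))
        assert rep.FM == pytest.approx(1 / math.sqrt(6))
        assert rep.RI == pytest.approx(0.5)

    def test_label_permutation_invariance(self, rng):
        T = rng.integers(0, 3, 30)
        Y = rng.integers(0, 3, 30)
        rep1 = clustering_metrics(Y, T)
        remap = {0: 2, 1: 0, 2: 1}
        rep2 = clustering_metrics(np.array([remap[v] for v in Y]), T)
        for attr in ("MI", "FM", "AR", "RI", "accuracy", "BAS"):
            assert getattr(rep1, attr) == pytest.approx(getattr(rep2, attr))

    def test_mi_symmetric(self, rng):
        Y = rng.integers(0, 4, 40)
        T = rng.integers(0, 3, 40)
        assert normalized_mutual_information(Y, T) == pytest.approx(
            normalized_mutual_information(T, Y))

    def test_against_sklearn_reference(self, rng):
        """Own formula implementations vs scikit-learn on random labelings."""
        for _ in range(50):
            n = int(rng.integers(5, 40))
            Y = rng.integers(0, 4, n)
            T = rng.integers(0, 3, n)
            assert normalized_mutual_information(Y, T) == pytest.approx(
                normalized_mutual_info_score(T, Y), abs=1e-10)
            assert adjusted_rand(Y, T) == pytest.approx(
                adjusted_rand_score(T, Y), abs=1e-10)
            rep = clustering_metrics(Y, T)
            assert rep.FM == pytest.approx(fowlkes_mallows_score(T, Y),
                                           abs=1e-10)

    def test_random_labelings_have_chance_level_ar(self, rng):
        ars = []
        for _ in range(100):
            Y = rng.integers(0, 3, 200)
            T = rng.integers(0, 3, 200)
            ars.append(adjusted_rand(Y, T))
        assert abs(float(np.mean(ars))) < 0.05

    def test_single_class_conventions(self):
        assert normalized_mutual_information(np.zeros(4), np.zeros(4)) == 1.0
        assert normalized_mutual_information(np.array([0, 1, 0, 1]),
                                             np.zeros(4)) == 0.0


def constant_matrix_wfc(centers, counts, noise_sd, seed, n=4):
    """Windows drawn around per-class constant FC matrices."""
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    t = 0.0
    for c, (center, count) in enumerate(zip(centers, counts)):
        for _ in range(count):
            m = np.clip(center + noise_sd * rng.standard_normal((n, n)), 0, 1)
            np.fill_diagonal(m, 0)
            mats.append(m)
            labels.append(f"task{c}")
    windows = [(5.0 * k, 5.0 * k + 5.0) for k in range(len(mats))]
    return WindowedFC(windows, np.array(mats), labels)


def two_center_wfc(seed=0, counts=(12, 12), noise_sd=0.01):
    rng = np.random.default_rng(seed)
    c1 = np.clip(rng.random((4, 4)), 0, 1)
    c2 = np.clip(rng.random((4, 4)), 0, 1)
    return constant_matrix_wfc([c1, c2], counts, noise_sd, seed + 1)


class TestClusterWindows:
    def test_separable_populations_perfect_ri(self):
        wfc = two_center_wfc()
        for algo in ("spectral", "birch"):
            pred = cluster_windows(wfc, 2, algo, seed=0)
            rep = clustering_metrics(pred, np.array(wfc.task_labels))
            assert rep.RI == 1.0, algo

    def test_k_larger_than_windows_rejected(self):
        wfc = two_center_wfc(counts=(3, 3))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_windows(wfc, 10, "birch")

    def test_three_task_sessions_high_mi(self, three_task_wfcs):
        """Both algorithms recover the task structure (MI >= 0.9 on average
        over independent sessions)."""
        mis = {"spectral": [], "birch": []}
        for wfc in three_task_wfcs:
            true = np.array(wfc.non_mixed().task_labels)
            for algo in mis:
                pred = cluster_windows(wfc, 3, algo, seed=0)
                mis[algo].append(clustering_metrics(pred, true).MI)
        for algo, vals in mis.items():
            assert float(np.mean(vals)) >= 0.9, (algo, vals)


class TestEmbedTSNE:
    def test_shape_and_determinism(self):
        wfc = two_center_wfc(counts=(20, 20))
        xy1 = embed_tsne(wfc, perplexity=5.0, seed=1)
        xy2 = embed_tsne(wfc, perplexity=5.0, seed=1)
        assert xy1.shape == (40, 2)
        np.testing.assert_array_equal(xy1, xy2)

    def test_duplicate_rows_map_nearby(self):
        wfc = two_center_wfc(counts=(20, 20), noise_sd=0.05)
        mats = wfc.matrices.copy()
        mats[1] = mats[0]          # exact duplicate
        dup = WindowedFC(wfc.windows, mats, wfc.task_labels)
        xy = embed_tsne(dup, perplexity=5.0, seed=0)
        d01 = np.linalg.norm(xy[0] - xy[1])
        from scipy.spatial.distance import pdist
        assert d01 <= np.percentile(pdist(xy), 5)

    def test_perplexity_out_of_range(self):
        wfc = two_center_wfc(counts=(5, 5))
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(wfc, perplexity=10.0)


class TestTimeStratifiedFolds:
    def test_fold_proportions_within_one_window(self):
        labels = ["a"] * 20 + ["b"] * 15 + ["c"] * 25
        folds = time_stratified_folds(labels, 5)
        labels_arr = np.array(labels)
        global_prop = {c: (labels_arr == c).mean() for c in "abc"}
        for f in folds:
            for c in "abc":
                count = (labels_arr[f] == c).sum()
                expected = global_prop[c] * len(f)
                assert abs(count - expected) <= 1.0

    def test_test_sets_partition_all_windows(self):
        labels = ["a"] * 10 + ["b"] * 10
        folds = time_stratified_folds(labels, 5)
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(20))

    def test_class_segments_contiguous(self):
        labels = ["a"] * 10 + ["b"] * 10
        for f in time_stratified_folds(labels, 5):
            for cls_range in (range(0, 10), range(10, 20)):
                idx = [i for i in f if i in cls_range]
                if idx:
                    assert idx == list(range(min(idx), max(idx) + 1))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            time_stratified_folds(["a"] * 10 + ["b"] * 3, 5)


class TestClassifyTasks:
    def test_separable_classes_perfect(self):
        wfc = two_center_wfc(counts=(15, 15))
        for model in ("rfc", "svm"):
            rep = classify_tasks(wfc, model, K=5, seed=0)
            assert rep.accuracy == 1.0
            assert rep.hamming_loss == 0.0

    def test_hamming_equals_one_minus_accuracy(self, three_task_wfcs):
        rep = classify_tasks(three_task_wfcs[0], "rfc", K=5, seed=0)
        assert rep.hamming_loss == pytest.approx(1.0 - rep.accuracy)

    def test_shuffled_labels_fall_to_chance(self):
        """Label-permutation control: accuracy within the binomial 95% band
        around 1/3 for 3 balanced classes."""
        rng = np.random.default_rng(2)
        centers = [np.clip(rng.random((4, 4)), 0, 1) for _ in range(3)]
        wfc = constant_matrix_wfc(centers, (20, 20, 20), 0.05, seed=5)
        rep = classify_tasks(wfc, "rfc", K=5, seed=1, shuffle_labels=True)
        n = 60
        band = 1.96 * math.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(rep.accuracy - 1 / 3) <= band + 1e-9

    def test_aggregated_close_to_per_fold_mean(self):
        """Aggregated-fold accuracy is within 0.05 of the mean per-fold
        accuracy on balanced synthetic data."""
        wfc = two_center_wfc(counts=(15, 15), noise_sd=0.3)
        rep = classify_tasks(wfc, "rfc", K=5, seed=0)
        # recompute per-fold accuracies independently
        from fcdyn.taskstates import _drop_overlapping, _make_classifier
        sub = wfc.non_mixed()
        X = sub.vectorized()
        y = np.asarray(sub.task_labels)
        folds = time_stratified_folds(list(y), 5)
        accs = []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            train_idx = _drop_overlapping(train_idx, test_idx, sub.windows)
            mu, sd = X[train_idx].mean(0), X[train_idx].std(0)
            sd[sd < 1e-15] = 1.0
            clf = _make_classifier("rfc", 0 + f)
            clf.fit((X[train_idx] - mu) / sd, y[train_idx])
            accs.append(float(np.mean(
                clf.predict((X[test_idx] - mu) / sd) == y[test_idx])))
        assert abs(rep.accuracy - float(np.mean(accs))) <= 0.05

    def test_three_task_sessions_accuracy(self, three_task_wfcs):
        accs = [classify_tasks(w, "rfc", K=5, seed=0).accuracy
                for w in three_task_wfcs]
        assert float(np.mean(accs)) >= 0.9
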