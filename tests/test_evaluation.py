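import itertools

import numpy as np
import pytest
from scipy import stats

from nmfpost import (
    ClusterAssignment,
    ExperimentResult,
    ExpressionMatrix,
    clustering_accuracy,
    compare_methods,
    noise_perturb,
    run_experiment,
    top_varying_subset,
)


def _brute_force_accuracy(pred, truth):
    """Maximize agreement over injective predicted-to-true label maps."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pu, tu = np.unique(pred), np.unique(truth)
    best = 0
    small, large, p_is_small = (
        (pu, tu, True) if pu.size <= tu.size else (tu, pu, False)
    )
    for perm in itertools.permutations(large, small.size):
        mapping = dict(zip(small, perm))
        if p_is_small:
            agree = sum(mapping[p] == t for p, t in zip(pred, truth))
        else:
            agree = sum(p == mapping[t] for p, t in zip(pred, truth))
        best = max(best, agree)
    return best / pred.size * 100.0


class TestClusteringAccuracy:
    def test_perfect_and_relabeled(self):
        a = ClusterAssignment(np.array([1, 1, 2, 2]), 2)
        b = ClusterAssignment(np.array([2, 2, 1, 1]), 2)
        assert clustering_accuracy(a, a) == 100.0
        assert clustering_accuracy(a, b) == 100.0

    def test_hand_computed_partial_agreement(self):
        pred = ClusterAssignment(np.array([1, 1, 1, 2]), 2)
        truth = ClusterAssignment(np.array([1, 1, 2, 2]), 2)
        assert clustering_accuracy(pred, truth) == 75.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_accuracy(
                ClusterAssignment(np.array([1, 2]), 2),
                ClusterAssignment(np.array([1, 2, 1]), 2),
            )

    def test_matches_brute_force_on_random_assignments(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 10))
            pred = rng.integers(1, 4, m)
            truth = rng.integers(1, 4, m)
            assert clustering_accuracy(
                ClusterAssignment(pred, 3), ClusterAssignment(truth, 3)
            ) == pytest.approx(_brute_force_accuracy(pred, truth))

    def test_symmetric_under_relabeling(self, rng):
        pred = rng.integers(1, 4, 12)
        truth = rng.integers(1, 4, 12)
        relabel = {1: 3, 2: 1, 3: 2}
        pred2 = np.array([relabel[p] for p in pred])
        assert clustering_accuracy(
            ClusterAssignment(pred, 3), ClusterAssignment(truth, 3)
        ) == clustering_accuracy(
            ClusterAssignment(pred2, 3), ClusterAssignment(truth, 3)
        )

    def test_unequal_cluster_counts_use_rectangular_matching(self):
        pred = ClusterAssignment(np.array([1, 2, 3, 4]), 4)
        truth = ClusterAssignment(np.array([1, 1, 2, 2]), 2)
        # best injective map matches two predicted clusters, one sample each
        assert clustering_accuracy(pred, truth) == 50.0


class TestRunExperiment:
    def test_deterministic_and_sem_consistent(self, easy_dataset):
        r1 = run_experiment(
            easy_dataset.A, easy_dataset.true_labels, n_runs=5, base_seed=3
        )
        r2 = run_experiment(
            easy_dataset.A, easy_dataset.true_labels, n_runs=5, base_seed=3
        )
        assert np.array_equal(r1.per_seed_accuracy, r2.per_seed_accuracy)
        assert r1.sem == pytest.approx(
            np.std(r1.per_seed_accuracy, ddof=1) / np.sqrt(5), abs=1e-10
        )
        assert r1.mean == pytest.approx(r1.per_seed_accuracy.mean())

    def test_single_run_sem_zero_with_warning(self, easy_dataset):
        with pytest.warns(UserWarning, match="SEM"):
            r = run_experiment(
                easy_dataset.A, easy_dataset.true_labels, n_runs=1, base_seed=0
            )
        assert r.sem == 0.0


class TestCompareMethods:
    def _result(self, acc):
        acc = np.asarray(acc, float)
        return ExperimentResult("x", acc, acc.mean(),
                                np.std(acc, ddof=1) / np.sqrt(acc.size), acc.size)

    def test_identical_results_give_p_one(self):
        r = self._result([90, 95, 100])
        with pytest.warns(UserWarning):
            d, p = compare_methods(r, r)
        assert d == 0.0 and p == 1.0

    def test_constant_shift_zero_variance_gives_p_zero(self):
        rA = self._result([90, 95, 100])
        rB = self._result([85, 90, 95])
        with pytest.warns(UserWarning):
            d, p = compare_methods(rA, rB)
        assert d == 5.0 and p == 0.0

    def test_matches_closed_form_t_statistic(self, rng):
        a = rng.uniform(80, 100, 30)
        b = a - 5 + rng.normal(0, 2, 30)
        d, p = compare_methods(self._result(a), self._result(b))
        diff = a - b
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(30))
        p_expected = 2 * stats.t.sf(abs(t), df=29)
        assert p == pytest.approx(p_expected, rel=1e-10)
        assert d == pytest.approx(diff.mean())

    def test_swapping_arguments_flips_sign_same_p(self, rng):
        a = self._result(rng.uniform(80, 100, 20))
        b = self._result(rng.uniform(80, 100, 20))
        d1, p1 = compare_methods(a, b)
        d2, p2 = compare_methods(b, a)
        assert d1 == -d2 and p1 == pytest.approx(p2)

    def test_unequal_n_runs_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(self._result([1, 2]), self._result([1, 2, 3]))


class TestTopVaryingSubset:
    def _em(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(
            values,
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
        )

    def test_full_size_is_identity(self, rng):
        A = self._em(rng.uniform(0, 5, (10, 4)))
        sub = top_varying_subset(A, 10)
        assert np.array_equal(sub.values, A.values)
        assert sub.gene_ids == A.gene_ids

    def test_constant_gene_dropped_first(self):
        A = self._em([[2, 2, 2], [1, 5, 9]])
        sub = top_varying_subset(A, 1)
        assert sub.gene_ids == ["g1"]

    def test_agrees_with_sort_oracle(self, rng):
        A = self._em(rng.uniform(0, 10, (50, 10)))
        sub = top_varying_subset(A, 20)
        var = np.var(A.values, axis=1, ddof=1)
        expected = sorted(np.argsort(-var, kind="stable")[:20])
        assert sub.gene_ids == [f"g{i}" for i in expected]

    def test_oversized_request_rejected(self, rng):
        A = self._em(rng.uniform(0, 1, (5, 3)))
        with pytest.raises(ValueError):
            top_varying_subset(A, 6)


class TestNoisePerturb:
    def _em(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(
            values,
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
        )

    def test_zero_noise_is_identity(self, rng):
        A = self._em(rng.uniform(0, 9, (6, 4)))
        assert np.array_equal(noise_perturb(A, 0.0, seed=1).values, A.values)

    def test_entrywise_bounds(self, rng):
        A = self._em(rng.uniform(0, 9, (20, 10)))
        mu = 0.3
        Ap = noise_perturb(A, mu, seed=5)
        assert np.all(Ap.values >= A.values)
        assert np.all(Ap.values <= A.values + mu * A.values.max() + 1e-12)

    def test_mean_increment_matches_uniform_moment(self, rng):
        A = self._em(rng.uniform(1, 10, (200, 50)))
        mu = 0.5
        Ap = noise_perturb(A, mu, seed=2)
        inc = Ap.values - A.values
        expected = mu * A.values.max() / 2
        se = mu * A.values.max() / np.sqrt(12 * inc.size)
        assert abs(inc.mean() - expected) < 3 * se

    def test_negative_mu_rejected(self, rng):
        A = self._em(rng.uniform(0, 1, (3, 3)))
        with pytest.raises(ValueError):
            noise_perturb(A, -0.1, seed=0)
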