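"""Group Procrustes distances, CVA ordination, and rank tests."""

import numpy as np
import pytest
from scipy import stats

from morphotraj.groups import (
    cva_scores,
    group_distance_permutation,
    kruskal_posthoc,
    kruskal_wallis,
)
from morphotraj.procrustes import gpa, procrustes_distance


def _aligned_shapes(n, k=9, noise=0.05, offset=None, seed=0):
    """Flattened Procrustes coordinates for one group around a base shape."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(k, 3))
    base -= base.mean(axis=0)
    base /= np.sqrt((base**2).sum())
    stack = base[None] + noise * rng.normal(size=(n, k, 3))
    if offset is not None:
        stack = stack + offset.reshape(1, k, 3)
    return gpa(stack).flattened()


class TestGroupDistances:
    def test_reported_distance_matches_direct_computation(self):
        rng = np.random.default_rng(1)
        data = np.vstack([
            _aligned_shapes(8, seed=2),
            _aligned_shapes(8, seed=3),
        ])
        labels = ["a"] * 8 + ["b"] * 8
        table = group_distance_permutation(data, labels, n_permutations=99,
                                           seed=4)
        mean_a = data[:8].mean(axis=0).reshape(-1, 3)
        mean_b = data[8:].mean(axis=0).reshape(-1, 3)
        expected = procrustes_distance(mean_a, mean_b)
        i, j = table.labels.index("a"), table.labels.index("b")
        assert table.distances[i, j] == pytest.approx(expected, abs=1e-12)

    def test_extreme_separation_attains_minimal_p(self):
        rng = np.random.default_rng(5)
        offset = rng.normal(size=27) * 0.5
        base = _aligned_shapes(10, seed=6, noise=0.005)
        shifted = _aligned_shapes(10, seed=6, noise=0.005,
                                  offset=offset)
        data = np.vstack([base, shifted])
        labels = ["a"] * 10 + ["b"] * 10
        table = group_distance_permutation(data, labels, n_permutations=199,
                                           seed=7)
        assert table.p_values[0, 1] == pytest.approx(1 / 200)

    def test_null_calibration_of_permutation_p(self):
        # both groups drawn from one distribution: rejection rate at 5%
        # within its binomial interval over replicates
        n_replicates = 120
        rejections = 0
        for seed in range(n_replicates):
            rng = np.random.default_rng(1000 + seed)
            data = _aligned_shapes(16, noise=0.05, seed=1000 + seed)
            labels = np.array(["a"] * 8 + ["b"] * 8)
            table = group_distance_permutation(
                data, labels, n_permutations=99, seed=seed)
            rejections += table.p_values[0, 1] <= 0.05
        low, high = stats.binom.interval(0.999, n_replicates, 0.05)
        assert low <= rejections <= high

    def test_specimen_order_invariance(self):
        data = np.vstack([
            _aligned_shapes(6, seed=8),
            _aligned_shapes(7, seed=9),
        ])
        labels = np.array(["a"] * 6 + ["b"] * 7)
        t1 = group_distance_permutation(data, labels, n_permutations=99, seed=0)
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(labels))
        t2 = group_distance_permutation(data[perm], labels[perm],
                                        n_permutations=99, seed=0)
        a1, b1 = t1.labels.index("a"), t1.labels.index("b")
        a2, b2 = t2.labels.index("a"), t2.labels.index("b")
        assert t1.distances[a1, b1] == pytest.approx(
            t2.distances[a2, b2], abs=1e-12)

    def test_reproducible_under_fixed_seed(self):
        data = np.vstack([
            _aligned_shapes(6, seed=11),
            _aligned_shapes(6, seed=12),
        ])
        labels = ["a"] * 6 + ["b"] * 6
        t1 = group_distance_permutation(data, labels, n_permutations=199, seed=3)
        t2 = group_distance_permutation(data, labels, n_permutations=199, seed=3)
        np.testing.assert_array_equal(t1.p_values, t2.p_values)

    def test_group_of_one_rejected(self):
        data = _aligned_shapes(5, seed=13)
        with pytest.raises(ValueError, match="fewer than 2"):
            group_distance_permutation(data, ["a"] * 4 + ["b"],
                                       n_permutations=99)


class TestCVA:
    def test_cv1_aligns_with_mean_difference_for_two_groups(self):
        rng = np.random.default_rng(14)
        sep = np.array([3.0, 0.0])
        data = np.vstack([
            rng.normal(size=(40, 2)),
            rng.normal(size=(40, 2)) + sep,
        ])
        labels = ["a"] * 40 + ["b"] * 40
        scores, mahal, names, evals = cva_scores(data, labels,
                                                 n_retained_pcs=2)
        group_means = [scores[np.array(labels) == g].mean(axis=0)
                       for g in names]
        # groups separate along CV1, not CV2
        assert abs(group_means[0][0] - group_means[1][0]) > 2.0
        assert mahal[0, 1] > 2.0

    def test_mahalanobis_invariant_under_linear_transform(self):
        rng = np.random.default_rng(15)
        data = np.vstack([
            rng.normal(size=(30, 2)),
            rng.normal(size=(30, 2)) + np.array([2.0, 1.0]),
        ])
        labels = ["a"] * 30 + ["b"] * 30
        _, mahal1, _, _ = cva_scores(data, labels, n_retained_pcs=2)
        transform = np.array([[2.0, 0.7], [-0.3, 1.4]])
        _, mahal2, _, _ = cva_scores(data @ transform, labels,
                                     n_retained_pcs=2)
        assert mahal1[0, 1] == pytest.approx(mahal2[0, 1], rel=1e-8)

    def test_random_labels_give_small_between_group_eigenvalues(self):
        rng = np.random.default_rng(16)
        data = rng.normal(size=(60, 4))
        random_labels = rng.choice(["a", "b"], 60)
        sep_labels = np.where(data[:, 0] > 0, "a", "b")
        _, _, _, evals_random = cva_scores(data, random_labels,
                                           n_retained_pcs=4)
        _, _, _, evals_sep = cva_scores(data, sep_labels, n_retained_pcs=4)
        assert evals_random[0] < 0.2 * evals_sep[0]

    def test_too_many_pcs_rejected(self):
        rng = np.random.default_rng(17)
        data = rng.normal(size=(10, 8))
        with pytest.raises(ValueError):
            cva_scores(data, ["a"] * 5 + ["b"] * 5, n_retained_pcs=9)


class TestKruskalWallis:
    def test_hand_computed_three_group_partition(self):
        # ranks 1..9 in three blocks: H = 12/(9*10) * 3*((2-5)^2+0+(8-5)^2)
        #                               = 7.2 (no ties)
        values = np.arange(1.0, 10.0)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        result = kruskal_wallis(values, groups)
        assert result.chi_square == pytest.approx(7.2)
        assert result.df == 2

    def test_identical_observations_give_zero_statistic(self):
        result = kruskal_wallis(np.ones(12), ["a", "b", "c"] * 4)
        assert result.chi_square == 0.0
        assert result.p_value == 1.0

    def test_null_distribution_matches_chi_square_tail(self):
        rng = np.random.default_rng(18)
        stats_h = []
        for _ in range(400):
            values = rng.normal(size=90)
            groups = np.repeat(["a", "b", "c"], 30)
            stats_h.append(kruskal_wallis(values, groups).chi_square)
        # empirical upper-5% tail frequency vs chi2(2)
        critical = stats.chi2.ppf(0.95, 2)
        tail = np.mean(np.array(stats_h) > critical)
        low, high = stats.binom.interval(0.999, 400, 0.05)
        assert low <= tail * 400 <= high


class TestKruskalPosthoc:
    def test_widely_separated_groups_all_significant(self):
        rng = np.random.default_rng(19)
        values = np.concatenate([
            rng.normal(0, 0.1, 25),
            rng.normal(5, 0.1, 25),
            rng.normal(10, 0.1, 25),
        ])
        groups = np.repeat(["a", "b", "c"], 25)
        table = kruskal_posthoc(values, groups, alpha=0.05)
        assert table["significant"].all()

    def test_identical_groups_rarely_reject(self):
        n_replicates = 100
        false_positives = 0
        n_pairs = 3
        for seed in range(n_replicates):
            rng = np.random.default_rng(3000 + seed)
            values = rng.normal(size=45)
            groups = np.repeat(["a", "b", "c"], 15)
            table = kruskal_posthoc(values, groups, alpha=0.05)
            false_positives += int(table["significant"].sum())
        # familywise alpha 0.05 over pairs: expected pairwise rate is below
        # alpha; allow the 99.9% binomial envelope at alpha per pair
        low, high = stats.binom.interval(
            0.999, n_replicates * n_pairs, 0.05)
        assert false_positives <= high

    def test_two_group_decision_consistent_with_h_test(self):
        rng = np.random.default_rng(20)
        for seed in range(30):
            rng2 = np.random.default_rng(seed)
            shift = 1.2 if seed % 2 else 0.0
            values = np.concatenate([
                rng2.normal(0, 1, 20), rng2.normal(shift, 1, 20)])
            groups = np.repeat(["a", "b"], 20)
            h = kruskal_wallis(values, groups)
            post = kruskal_posthoc(values, groups, alpha=0.05)
            # with two groups the posthoc criterion reduces to the same
            # normal approximation as the H test: decisions agree except at
            # the boundary
            h_sig = h.p_value < 0.05
            p_sig = bool(post["significant"].iloc[0])
            if abs(h.p_value - 0.05) > 0.02:
                assert h_sig == p_sig
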