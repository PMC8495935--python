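"""The cluster-specificity screen: GOF test, dominance, permutation null,
classification, and the windowed abundance scan."""

import math

import numpy as np
import pytest

from svpanel import (
    ClusterAssignment,
    ClusterSpecificConfig,
    carrier_counts_by_cluster,
    classify_cluster_specific,
    dominant_fraction,
    gof_test,
    permutation_test,
    windowed_abundance_scan,
)

from conftest import make_matrix


class TestCarrierCounts:
    def test_worked_example_counts_recovered(self, worked_example_matrix):
        matrix, assignment = worked_example_matrix
        observed, nonmissing = carrier_counts_by_cluster(matrix.row(0), assignment)
        assert list(observed) == [1, 2, 1, 0, 2, 19, 0, 1]
        assert list(nonmissing) == [32, 31, 31, 30, 35, 53, 44, 30]

    def test_no_carriers(self):
        assignment = ClusterAssignment(
            sample_ids=[f"s{i}" for i in range(6)],
            labels=np.array([1, 1, 2, 2, 3, 3]), k=3,
        )
        observed, nonmissing = carrier_counts_by_cluster(
            np.array([0.0, 0, 0, np.nan, 0, 0]), assignment
        )
        assert list(observed) == [0, 0, 0]
        assert list(nonmissing) == [2, 1, 2]

    def test_single_cluster(self):
        assignment = ClusterAssignment(
            sample_ids=["a", "b", "c"], labels=np.array([1, 1, 1]), k=1
        )
        observed, nonmissing = carrier_counts_by_cluster(
            np.array([1.0, 1, 0]), assignment
        )
        assert list(observed) == [2] and list(nonmissing) == [3]


class TestGofTest:
    def test_worked_example_p_value(self, worked_example):
        observed, nonmissing = worked_example
        chi2, p = gof_test(observed, nonmissing)
        assert p == pytest.approx(4.314e-9, rel=0.01)

    def test_proportional_counts_fit_perfectly(self):
        nonmissing = np.array([10, 20, 30])
        chi2, p = gof_test(np.array([1, 2, 3]), nonmissing)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_cluster_closed_form(self):
        # expected [1, 1]; chi2 = 1 + 1 = 2; df = 1
        chi2, p = gof_test(np.array([2, 0]), np.array([10, 10]))
        assert chi2 == pytest.approx(2.0)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        observed = rng.integers(0, 10, size=5)
        observed[0] += 1
        nonmissing = rng.integers(5, 40, size=5)
        chi2, _ = gof_test(observed, nonmissing)
        expected = observed.sum() * nonmissing / nonmissing.sum()
        assert chi2 == pytest.approx(np.sum((observed - expected) ** 2 / expected))

    def test_requires_a_carrier(self):
        with pytest.raises(ValueError):
            gof_test(np.array([0, 0]), np.array([5, 5]))


class TestDominantFraction:
    def test_worked_example(self, worked_example):
        observed, _ = worked_example
        cluster, fraction = dominant_fraction(observed)
        assert cluster == 6
        assert fraction == pytest.approx(19 / 26)
        assert round(100 * fraction) == 73

    def test_exclusive_carrier(self):
        assert dominant_fraction(np.array([5, 0, 0])) == (1, 1.0)

    def test_tie_breaks_to_lowest_cluster(self):
        assert dominant_fraction(np.array([3, 3])) == (1, 0.5)


def exact_dominance_tail(total, nonmissing, focal, threshold):
    """Exact P(focal cluster holds >= threshold of `total` carriers) under
    uniform placement without replacement — hypergeometric enumeration."""
    M = sum(nonmissing)
    m = nonmissing[focal - 1]
    need = math.ceil(threshold * total)
    prob = 0.0
    for x in range(need, total + 1):
        if x <= m and total - x <= M - m:
            prob += (
                math.comb(m, x) * math.comb(M - m, total - x) / math.comb(M, total)
            )
    return prob


class TestPermutationTest:
    def test_worked_example_zero_exceedances(self, worked_example):
        _, nonmissing = worked_example
        config = ClusterSpecificConfig(seed=0)
        exceed = permutation_test(26, nonmissing, 6, config)
        assert exceed == 0
        # the exact tail is far below 1/100, so 0/100 is the expected draw
        assert exact_dominance_tail(26, list(nonmissing), 6, 0.70) < 1e-6

    def test_single_cluster_always_exceeds(self):
        config = ClusterSpecificConfig(seed=0)
        exceed = permutation_test(5, np.array([20]), 1, config)
        assert exceed == config.n_permutations

    def test_single_carrier_two_equal_clusters(self):
        # exact tail probability is 1/2; 99% binomial bounds for 100 draws
        config = ClusterSpecificConfig(seed=3)
        exceed = permutation_test(1, np.array([5, 5]), 1, config)
        assert 37 <= exceed <= 63

    @pytest.mark.parametrize(
        "total,nonmissing,focal",
        [
            (3, (6, 10), 1),
            (8, (12, 9, 7), 2),
            (12, (20, 15, 10), 3),
            (5, (4, 4, 12), 1),
        ],
    )
    def test_matches_exact_enumeration(self, total, nonmissing, focal):
        exact = exact_dominance_tail(total, list(nonmissing), focal, 0.70)
        config = ClusterSpecificConfig(seed=17, n_permutations=10_000)
        exceed = permutation_test(total, np.array(nonmissing), focal, config)
        # 99% binomial envelope around the exact probability
        sd = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(exceed / 10_000 - exact) <= max(2.58 * sd, 5e-4)

    def test_any_cluster_scope_is_at_least_focal(self):
        nonmissing = np.array([10, 10, 10])
        focal = permutation_test(
            6, nonmissing, 1, ClusterSpecificConfig(seed=5, permutation_scope="focal")
        )
        anyc = permutation_test(
            6, nonmissing, 1, ClusterSpecificConfig(seed=5, permutation_scope="any")
        )
        assert anyc >= focal


class TestClassify:
    def test_worked_example_site_is_specific(self, worked_example_matrix):
        matrix, assignment = worked_example_matrix
        results = classify_cluster_specific(
            matrix, assignment, ClusterSpecificConfig(seed=0)
        )
        (res,) = results
        assert res.is_specific
        assert res.stage == "specific"
        assert res.dominant_cluster == 6
        assert res.perm_exceedances == 0

    def test_proportional_site_is_not_specific(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        assignment = ClusterAssignment(
            sample_ids=[f"s{i}" for i in range(100)], labels=labels, k=4
        )
        row = np.zeros(100)
        for c in range(4):  # 3 carriers in every cluster of 25
            row[25 * c : 25 * c + 3] = 1.0
        results = classify_cluster_specific(make_matrix(row[None, :]), assignment)
        assert not results[0].is_specific
        assert results[0].stage == "gof"

    def test_null_false_positive_rate_below_alpha(self):
        # carriers placed exchangeably: the screen should fire on well under
        # gof_alpha of sites
        rng = np.random.default_rng(21)
        n, k = 200, 4
        labels = np.repeat(np.arange(1, k + 1), n // k)
        assignment = ClusterAssignment(
            sample_ids=[f"s{i}" for i in range(n)], labels=labels, k=k
        )
        rows = np.zeros((300, n))
        for i in range(300):
            rows[i, rng.choice(n, size=rng.integers(10, 40), replace=False)] = 1.0
        results = classify_cluster_specific(
            make_matrix(rows), assignment, ClusterSpecificConfig(seed=1)
        )
        rate = np.mean([r.is_specific for r in results])
        assert rate <= 0.05

    def test_invariant_to_cluster_relabeling(self, worked_example_matrix):
        matrix, assignment = worked_example_matrix
        # reverse the cluster labels 1..8 -> 8..1
        flipped = ClusterAssignment(
            sample_ids=assignment.sample_ids,
            labels=9 - assignment.labels,
            k=8,
        )
        a = classify_cluster_specific(matrix, assignment, ClusterSpecificConfig(seed=2))
        b = classify_cluster_specific(matrix, flipped, ClusterSpecificConfig(seed=2))
        assert a[0].is_specific == b[0].is_specific
        assert a[0].dominant_cluster == 9 - b[0].dominant_cluster
        assert a[0].chi2 == pytest.approx(b[0].chi2)


class TestWindowedAbundanceScan:
    def _assignment(self, n=80, k=4):
        labels = np.repeat(np.arange(1, k + 1), n // k)
        return ClusterAssignment(
            sample_ids=[f"s{i}" for i in range(n)], labels=labels, k=k
        )

    def test_homogeneous_windows_not_significant(self):
        assignment = self._assignment()
        rows = np.zeros((10, 80))
        rows[:, ::10] = 1.0  # two carriers per cluster at every site
        m = make_matrix(rows, starts=[1000 * (i + 1) for i in range(10)])
        results = windowed_abundance_scan(m, assignment, window_bp=5000)
        assert not any(r.significant for r in results)

    def test_concentrated_window_flagged_under_bonferroni(self):
        assignment = self._assignment()
        # 99 homogeneous windows plus one where all carriers sit in cluster 1
        rows = []
        starts = []
        for w in range(100):
            row = np.zeros(80)
            if w == 0:
                row[:15] = 1.0  # cluster 1 occupies the first 20 samples
            else:
                row[::10] = 1.0
            rows.append(row)
            starts.append(w * 5000 + 100)
        m = make_matrix(np.array(rows), starts=starts)
        results = windowed_abundance_scan(m, assignment, window_bp=5000)
        assert len([r for r in results if r.p is not None]) == 100
        assert results[0].significant
        assert sum(r.significant for r in results) == 1

    def test_empty_matrix_gives_empty_result(self):
        m = make_matrix(np.zeros((0, 8)).reshape(0, 8))
        assert windowed_abundance_scan(m, self._assignment(8, 2)) == []

    def test_zero_carrier_window_excluded_from_denominator(self):
        assignment = self._assignment()
        rows = np.zeros((2, 80))
        rows[1, ::10] = 1.0
        m = make_matrix(rows, starts=[100, 7000])
        results = windowed_abundance_scan(m, assignment, window_bp=5000)
        assert results[0].p is None
        assert results[1].p is not None
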