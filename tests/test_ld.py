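"""Pairwise r-squared, the decay profile, and the half-decay distance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpanel import (
    LDProfile,
    decay_profile,
    ld_half,
    pairwise_r2,
    stratify_sites,
)
from svpanel.annotation import FeatureOverlap

from conftest import make_matrix


class TestPairwiseR2:
    def test_identical_sites(self):
        x = np.array([1.0, 1, 0, 0, 1, 0])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_balanced_independence(self):
        assert pairwise_r2(
            np.array([1.0, 1, 0, 0]), np.array([1.0, 0, 1, 0])
        ) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # D^2 / (pA qA pB qB) with pA = 3/8, pB = 2/8, pAB = 2/8 gives 5/9
        x = np.array([1.0, 1, 1, 0, 0, 0, 0, 0])
        y = np.array([1.0, 1, 0, 0, 0, 0, 0, 0])
        assert pairwise_r2(x, y) == pytest.approx(0.5556, abs=1e-4)

    def test_pairwise_complete_missing_handling(self):
        x = np.array([1.0, 1, 0, 0, np.nan, 1])
        y = np.array([1.0, np.nan, 0, 0, 1, 1])
        # shared nonmissing entries: indices 0, 2, 3, 5 -> identical there
        assert pairwise_r2(x, y) == pytest.approx(1.0)

    def test_monomorphic_shared_set_undefined(self):
        with pytest.raises(ValueError):
            pairwise_r2(np.array([1.0, 1, 1]), np.array([1.0, 0, 1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=16))
    def test_symmetry_and_label_flip_invariance(self, pairs):
        x = np.array([float(a) for a, _ in pairs])
        y = np.array([float(b) for _, b in pairs])
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r2 = pairwise_r2(x, y)
        assert pairwise_r2(y, x) == pytest.approx(r2)
        assert pairwise_r2(1 - x, y) == pytest.approx(r2)
        assert pairwise_r2(x, 1 - y) == pytest.approx(r2)
        assert 0.0 <= r2 <= 1.0 + 1e-12


class TestDecayProfile:
    def test_single_pair_lands_in_its_distance_bin(self):
        rows = np.tile([1.0, 1, 0, 0, 1, 0], (2, 1))
        m = make_matrix(rows, starts=[100, 250])
        prof = decay_profile(m, max_dist_bp=1000, bin_width_bp=100)
        assert prof.bin_mid_distances.tolist() == [150.0]
        assert prof.mean_r2[0] == pytest.approx(1.0)
        assert prof.n_pairs[0] == 1

    def test_cross_chromosome_pairs_excluded(self):
        rows = np.tile([1.0, 1, 0, 0, 1, 0], (2, 1))
        m = make_matrix(rows, chrom=["Chr01", "Chr02"], starts=[100, 250])
        prof = decay_profile(m, max_dist_bp=1000, bin_width_bp=100)
        assert prof.mean_r2.size == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(5)
        rows = rng.choice([0.0, 1.0, np.nan], size=(6, 30), p=[0.45, 0.45, 0.1])
        starts = [100, 180, 260, 500, 810, 1200]
        m = make_matrix(rows, starts=starts)
        prof = decay_profile(m, max_dist_bp=2000, bin_width_bp=100)
        # oracle: enumerate every pair, bin by distance, average r2
        bins = {}
        for i, j in itertools.combinations(range(6), 2):
            try:
                r2 = pairwise_r2(rows[i], rows[j])
            except ValueError:
                continue
            b = abs(starts[j] - starts[i]) // 100
            bins.setdefault(b, []).append(r2)
        expected = {b * 100 + 50.0: np.mean(v) for b, v in sorted(bins.items())}
        assert dict(zip(prof.bin_mid_distances, prof.mean_r2)) == pytest.approx(expected)


class TestLdHalf:
    def test_first_bin_at_or_below_half_of_max(self):
        prof = LDProfile(
            bin_width_bp=100,
            bin_mid_distances=np.array([50.0, 150, 250, 350]),
            mean_r2=np.array([0.4, 0.3, 0.2, 0.1]),
            n_pairs=np.array([10, 10, 10, 10]),
        )
        assert ld_half(prof) == 250.0

    def test_flat_profile_has_no_half_point(self):
        prof = LDProfile(
            bin_width_bp=100,
            bin_mid_distances=np.array([50.0, 150]),
            mean_r2=np.array([0.3, 0.3]),
            n_pairs=np.array([5, 5]),
        )
        assert ld_half(prof) is None

    def test_exponential_decay_closed_form(self):
        # r2(d) = 0.5 exp(-d / 10000) halves at 10000 ln 2 = 6931 bp
        width = 500
        mids = np.arange(width / 2, 30_000, width)
        prof = LDProfile(
            bin_width_bp=width,
            bin_mid_distances=mids,
            mean_r2=0.5 * np.exp(-mids / 10_000),
            n_pairs=np.full(mids.size, 100),
        )
        assert abs(ld_half(prof) - 10_000 * np.log(2)) <= width

    def test_maximum_is_largest_bin_mean_not_first(self):
        prof = LDProfile(
            bin_width_bp=100,
            bin_mid_distances=np.array([50.0, 150, 250, 350]),
            mean_r2=np.array([0.3, 0.6, 0.4, 0.25]),
            n_pairs=np.array([4, 4, 4, 4]),
        )
        # half of max (0.6) is 0.3: first bin at or below is the *first* bin
        assert ld_half(prof) == 50.0


class TestStratifySites:
    def _overlaps(self, genic, cds):
        return [
            FeatureOverlap(site_id=f"site{i}", in_gene=g, in_cds=c)
            for i, (g, c) in enumerate(zip(genic, cds))
        ]

    def test_all_stratum_is_identity(self):
        m = make_matrix(np.zeros((3, 4)))
        assert stratify_sites(m, [], "all") is m

    def test_genic_stratum_hand_count(self):
        rng = np.random.default_rng(0)
        m = make_matrix((rng.random((10, 4)) < 0.5).astype(float))
        genic = [True, False, True, False, False, True, False, False, False, False]
        sub = stratify_sites(m, self._overlaps(genic, [False] * 10), "genic")
        assert sub.n_sites == 3
        assert sub.site_ids == ["site0", "site2", "site5"]

    def test_empty_cds_stratum(self):
        m = make_matrix(np.zeros((4, 4)))
        sub = stratify_sites(
            m, self._overlaps([True] * 4, [False] * 4), "cds"
        )
        assert sub.n_sites == 0
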