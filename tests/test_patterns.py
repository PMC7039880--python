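"""Tests for the pattern statistics (nestedness, SAD, DOC, ordination)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micrm import patterns
from micrm.patterns import (
    MAX_JS_DISTANCE,
    additivity_r2,
    doc_analysis,
    fit_fisher,
    js_distance_matrix,
    nodf,
    overlap_dissimilarity,
    pcoa,
    presence_absence,
    sad_fisher,
    subsample_reads,
    truncated_gaussian_null,
)

NESTED_TOY = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


class TestPresenceAbsence:
    def test_all_positive_is_all_ones(self):
        pa = presence_absence(np.full((4, 3), 2.0))
        assert np.all(pa.values == 1)

    def test_sorting_orders_by_prevalence_and_richness(self):
        # samples x taxa input; taxon prevalences (3, 2, 1)
        table = pd.DataFrame(NESTED_TOY.T)
        pa = presence_absence(table)
        assert np.array_equal(pa.values, NESTED_TOY)
        assert pa.values.sum(axis=1).tolist() == [3, 2, 1]

    def test_nested_input_stays_nested_after_shuffling(self):
        rng = np.random.default_rng(0)
        rp, cp = rng.permutation(3), rng.permutation(3)
        shuffled = NESTED_TOY[np.ix_(rp, cp)]
        pa = presence_absence(shuffled.T)
        assert np.array_equal(pa.values, NESTED_TOY)


class TestNODF:
    def test_perfect_staircase_scores_100(self):
        assert nodf(NESTED_TOY) == 100.0

    def test_checkerboard_scores_0(self):
        assert nodf(np.array([[1, 0], [0, 1]])) == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            m = (rng.random((6, 7)) < 0.5).astype(int)
            if m.sum() == 0 or m.shape[0] < 2:
                continue

            def brute(mat):
                # mirror the scorer's restriction to occupied rows/columns
                mat = mat[mat.sum(axis=1) > 0][:, mat.sum(axis=0) > 0]
                scores = []
                for axis_mat in (mat, mat.T):
                    tot = axis_mat.sum(axis=1)
                    n = axis_mat.shape[0]
                    for i in range(n):
                        for j in range(n):
                            if i < j:
                                hi, lo = (i, j) if tot[i] > tot[j] else (j, i)
                                if tot[hi] == tot[lo] or tot[lo] == 0:
                                    scores.append(0.0)
                                else:
                                    scores.append(
                                        100.0 * (axis_mat[hi] & axis_mat[lo]).sum() / tot[lo]
                                    )
                return float(np.mean(scores))

            assert nodf(m) == pytest.approx(brute(m), abs=1e-12)

    def test_invariant_under_permutation_then_resorting(self):
        rng = np.random.default_rng(3)
        m = (rng.random((8, 9)) < 0.4).astype(int)
        base = nodf(presence_absence(m.T))
        perm = m[np.ix_(rng.permutation(8), rng.permutation(9))]
        assert nodf(presence_absence(perm.T)) == pytest.approx(base)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            nodf(np.zeros((3, 3), dtype=int))


class TestRarefaction:
    def test_full_depth_reproduces_counts(self):
        counts = np.array([5, 3, 2])
        hist = subsample_reads(counts, depth=10, n_reps=3, rng_seed=0)
        expected = np.zeros(11)
        expected[[5, 3, 2]] = 1
        assert np.allclose(hist, expected)

    def test_hypergeometric_mean_per_species(self):
        counts = np.array([100, 50, 10, 1])
        rng = np.random.default_rng(1)
        depth, reps = 80, 2000
        totals = np.zeros(4)
        for _ in range(reps):
            totals += rng.multivariate_hypergeometric(counts, depth, method="marginals")
        mean = totals / reps
        expected = depth * counts / counts.sum()
        se = np.sqrt(np.maximum(expected * (1 - depth / counts.sum()), 1e-9) / reps)
        assert np.all(np.abs(mean - expected) < 4 * np.maximum(se, 0.05))

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            subsample_reads(np.array([1, 2]), depth=10)


class TestFisher:
    def test_round_trip_identities(self):
        fit = fit_fisher(100, 10_000)
        assert -fit.alpha * np.log(1 - fit.x) == pytest.approx(100, rel=1e-9)
        assert fit.alpha * fit.x / (1 - fit.x) == pytest.approx(10_000, rel=1e-9)

    def test_against_independent_bisection(self):
        S, N = 100.0, 10_000.0
        lo, hi = 1e-12, 1 - 1e-12
        for _ in range(200):  # plain bisection oracle
            mid = 0.5 * (lo + hi)
            val = mid / ((1 - mid) * (-np.log1p(-mid)))
            if val < N / S:
                lo = mid
            else:
                hi = mid
        fit = fit_fisher(S, N)
        assert fit.x == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_sad_series_sums_to_totals(self):
        fit = fit_fisher(57, 1000)
        n = np.arange(1, 200_000)
        s = sad_fisher(fit, n)
        assert s.sum() == pytest.approx(57, rel=1e-6)
        assert (n * s).sum() == pytest.approx(1000, rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(ratio=st.floats(0.002, 0.98))
    def test_round_trip_across_ratios(self, ratio):
        N = 50_000.0
        S = ratio * N
        fit = fit_fisher(S, N)
        assert -fit.alpha * np.log(1 - fit.x) == pytest.approx(S, rel=1e-9)
        assert fit.alpha * fit.x / (1 - fit.x) == pytest.approx(N, rel=1e-9)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            fit_fisher(100, 100)


class TestTruncatedGaussianNull:
    def test_half_survival_centers_threshold_at_mean(self):
        # survival 0.5 puts the fitness mean at zero: abundances are
        # half-normal; the histogram should match a larger independent
        # Monte-Carlo run within sampling error
        h1 = truncated_gaussian_null(0.5, S=50, N=100, n_iter=400, rng_seed=1)
        h2 = truncated_gaussian_null(0.5, S=50, N=100, n_iter=4000, rng_seed=2)
        sel = slice(1, 10)
        se = np.sqrt(h2[sel] / 400) + 1e-9
        assert np.all(np.abs(h1[sel] - h2[sel]) < 5 * se + 0.5)

    def test_bad_survival_fraction(self):
        with pytest.raises(ValueError):
            truncated_gaussian_null(1.5, S=10, N=10, n_iter=1)


class TestOverlapDissimilarity:
    def test_identical_communities(self):
        v = np.array([1.0, 2.0, 3.0])
        O, D, S = overlap_dissimilarity(v, v)
        assert O == pytest.approx(1.0)
        assert D == pytest.approx(0.0, abs=1e-12)
        assert S == 3

    def test_hand_worked_pair(self):
        # mu = (1,1,2) on {A,B,C}; nu = (1,3) on {A,B}:
        # O = ((1+1)/4 + (1+3)/4)/2 = 0.75,
        # D = sqrt(0.5 * 0.06764...) ~ 0.18391
        N_mu = np.array([1.0, 1.0, 2.0])
        N_nu = np.array([1.0, 3.0, 0.0])
        O, D, S = overlap_dissimilarity(N_mu, N_nu)
        assert S == 2
        assert O == pytest.approx(0.75)
        assert D == pytest.approx(0.1839, abs=2e-4)

    def test_disjoint_supports(self):
        O, D, S = overlap_dissimilarity(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert O == 0.0 and S == 0 and np.isnan(D)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 10), st.floats(0, 10)), min_size=2, max_size=12
        )
    )
    def test_symmetry_and_bounds(self, data):
        a = np.array([x for x, _ in data])
        b = np.array([y for _, y in data])
        if a.sum() == 0 or b.sum() == 0:
            return
        O1, D1, S1 = overlap_dissimilarity(a, b)
        O2, D2, S2 = overlap_dissimilarity(b, a)
        assert O1 == pytest.approx(O2)
        assert S1 == S2
        assert 0.0 <= O1 <= 1.0 + 1e-12
        if S1 > 0:
            assert D1 == pytest.approx(D2, abs=1e-12)
            assert -1e-12 <= D1 <= MAX_JS_DISTANCE + 1e-9


class TestDOC:
    def test_pair_count_capped_at_all_pairs(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.random((6, 10)))
        res = doc_analysis(table, n_pairs=1000, rng_seed=1)
        assert len(res.pairs) + res.n_disjoint == 15

    def test_requested_subset_size(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.random((20, 10)) + 0.1)
        res = doc_analysis(table, n_pairs=50, rng_seed=1)
        assert len(res.pairs) == 50


class TestOrdination:
    def test_identical_profiles_have_zero_distance(self):
        table = pd.DataFrame([[1, 2, 3], [2, 4, 6]], dtype=float)
        d = js_distance_matrix(table)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_profiles_reach_maximum(self):
        table = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        d = js_distance_matrix(table)
        assert d.iloc[0, 1] == pytest.approx(MAX_JS_DISTANCE, rel=1e-9)

    def test_pcoa_recovers_equilateral_triangle(self):
        side = 0.4
        D = np.full((3, 3), side)
        np.fill_diagonal(D, 0.0)
        coords, evals = pcoa(D, k=2)
        got = coords.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(got[i] - got[j]) == pytest.approx(side, rel=1e-9)

    def test_pcoa_matches_reference_implementation(self):
        # independent check against the scikit-bio ordination routine
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        rng = np.random.default_rng(5)
        pts = rng.random((6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours, _ = pcoa(D, k=2)
        ref = skbio_pcoa(DistanceMatrix(D)).samples.iloc[:, :2].to_numpy()
        for col in range(2):  # eigenvector signs are arbitrary
            ref_col = ref[:, col]
            our_col = ours.to_numpy()[:, col]
            assert min(
                np.abs(our_col - ref_col).max(), np.abs(our_col + ref_col).max()
            ) < 1e-6


class TestAdditivity:
    def test_exact_mixture_gives_r2_one(self):
        rng = np.random.default_rng(0)
        N1, N2 = rng.random(30), rng.random(30)
        a = 0.3
        mix = (1 - a) * N1 + a * N2
        _, r2 = additivity_r2(mix, N1, N2, a)
        assert r2 == pytest.approx(1.0)

    def test_matches_brute_force_residuals(self):
        rng = np.random.default_rng(1)
        N1, N2, mix = rng.random(50), rng.random(50), rng.random(50)
        a = 0.5
        pred, r2 = additivity_r2(mix, N1, N2, a)
        ss_res = sum((m - p) ** 2 for m, p in zip(mix, pred))
        ss_tot = sum((m - mix.mean()) ** 2 for m in mix)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            additivity_r2(np.ones(5), np.ones(5), np.ones(5), 0.5)
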