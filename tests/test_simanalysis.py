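"""Similarity statistics: assembly, conversion, smoothing, MDS, reliability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

import percepsim as ps
from percepsim import simanalysis as sa

from conftest import brute_force_confusion_similarity, helix_distance


def _matrix(values, ids=None, **kw):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return sa.SimilarityMatrix(ids=tuple(ids), values=values, **kw)


class TestAssembleMatrix:
    def test_mean_of_identical_ratings(self):
        recs = [sa.RatingRecord("r", "a", "b", 0.6, k) for k in range(10)]
        M = sa.assemble_matrix(recs, ["a", "b"])
        assert M.values[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert M.counts[0, 1] == 10

    def test_mean_of_opposite_ratings(self):
        recs = [sa.RatingRecord("r", "a", "b", 0.0, 0), sa.RatingRecord("r", "b", "a", 1.0, 1)]
        M = sa.assemble_matrix(recs, ["a", "b"])
        assert M.values[0, 1] == 0.5

    def test_full_pitch_coverage_fills_300_upper_cells(self, helix_ratings, pitch_ladder):
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        iu = np.triu_indices(25, k=1)
        filled = ~np.isnan(M.values[iu])
        assert filled.sum() == 300  # C(25, 2)

    def test_unrated_cells_are_missing(self):
        M = sa.assemble_matrix([sa.RatingRecord("r", "a", "b", 0.5, 0)], ["a", "b", "c"])
        assert np.isnan(M.values[0, 2])

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            sa.assemble_matrix([sa.RatingRecord("r", "a", "zzz", 0.5, 0)], ["a", "b"])


class TestConfusionToSimilarity:
    def test_identity_confusion_gives_identity_similarity(self):
        C = sa.ConfusionMatrix(ids=("a", "b", "c"), probs=np.eye(3))
        S = sa.confusion_to_similarity(C)
        assert np.array_equal(S.values, np.eye(3))

    def test_hand_computed_two_by_two(self):
        C = sa.ConfusionMatrix(ids=("a", "b"), probs=np.array([[0.8, 0.2], [0.4, 0.6]]))
        S = sa.confusion_to_similarity(C)
        assert S.values[0, 1] == pytest.approx(math.sqrt(0.2 * 0.4 / (0.8 * 0.6)), abs=1e-12)
        assert S.values[0, 1] == pytest.approx(0.40825, abs=1e-5)

    @pytest.mark.parametrize("n", [4, 5, 7, 10])
    def test_matches_elementwise_oracle_on_random_matrices(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            raw = rng.uniform(0.05, 1.0, size=(n, n)) + np.eye(n) * 2
            probs = raw / raw.sum(axis=1, keepdims=True)
            C = sa.ConfusionMatrix(ids=tuple(f"s{i}" for i in range(n)), probs=probs)
            S = sa.confusion_to_similarity(C)
            oracle = brute_force_confusion_similarity(probs)
            iu = np.triu_indices(n, 1)
            assert np.allclose(S.values[iu], oracle[iu], atol=1e-12)
            assert np.array_equal(S.values, S.values.T)
            assert np.array_equal(np.diag(S.values), np.ones(n))

    def test_zero_diagonal_instructive_error(self):
        probs = np.array([[0.0, 1.0], [0.5, 0.5]])
        C = sa.ConfusionMatrix(ids=("a", "b"), probs=probs)
        with pytest.raises(ValueError, match="smoothing"):
            sa.confusion_to_similarity(C)


class TestSymmetrize:
    def test_averages_across_diagonal(self):
        M = _matrix([[1.0, 0.4], [0.6, 1.0]])
        S = sa.symmetrize(M)
        assert S.values[0, 1] == S.values[1, 0] == 0.5

    @given(st_h.integers(min_value=2, max_value=8), st_h.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=40)
    def test_idempotent_and_symmetric(self, n, seed):
        rng = np.random.default_rng(seed)
        M = _matrix(rng.uniform(size=(n, n)))
        S1 = sa.symmetrize(M)
        S2 = sa.symmetrize(S1)
        assert np.array_equal(S1.values, S1.values.T)
        assert np.array_equal(S1.values, S2.values)


class TestSmoothingAndProfile:
    def test_constant_matrix_unchanged(self):
        M = _matrix(np.full((4, 4), 0.3))
        assert np.allclose(sa.smooth_toeplitz(M).values, 0.3)

    def test_subdiagonal_mean(self):
        M = _matrix([[1.0, 0.2, 0.0], [0.2, 1.0, 0.4], [0.0, 0.4, 1.0]])
        S = sa.smooth_toeplitz(M)
        assert S.values[0, 1] == S.values[1, 2] == pytest.approx(0.3)

    def test_output_is_toeplitz(self, helix_ratings, pitch_ladder):
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        S = sa.smooth_toeplitz(M)
        for s in range(1, 25):
            diag = np.diagonal(S.values, offset=s)
            assert np.allclose(diag, diag[0])

    def test_profile_pair_counts_on_ladder(self, helix_ratings, pitch_ladder):
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        profile = sa.interval_profile(M)
        assert profile.separations == tuple(range(1, 25))
        assert profile.pair_counts == tuple(25 - s for s in range(1, 25))
        assert all(0.0 <= m <= 1.0 for m in profile.mean_similarity)

    def test_profile_of_toeplitz_equals_first_row(self):
        first_row = np.array([1.0, 0.7, 0.5, 0.4])
        from scipy.linalg import toeplitz

        M = _matrix(toeplitz(first_row))
        profile = sa.interval_profile(M)
        assert profile.mean_similarity == pytest.approx(tuple(first_row[1:]))


class TestOctavePeak:
    def test_injected_bump_is_found(self):
        means = [0.9, 0.8, 0.7, 0.6, 0.8, 0.4, 0.3, 0.2]
        profile = sa.IntervalProfile(tuple(range(1, 9)), tuple(means), tuple([1] * 8))
        peak = sa.octave_peak(profile)
        assert peak.separation == 5
        assert peak.contrast > 0

    def test_convex_profile_reports_nonpositive_contrast(self):
        means = tuple(np.exp(-np.arange(1, 10) / 3.0))
        profile = sa.IntervalProfile(tuple(range(1, 10)), means, tuple([1] * 9))
        assert sa.octave_peak(profile).contrast <= 0

    def test_noiseless_helix_profile_peaks_at_octave(self):
        """Closed-form helix distances give c(12) ~ 0.046, dominating all others."""
        means = tuple(math.exp(-helix_distance(s)) for s in range(1, 25))
        profile = sa.IntervalProfile(tuple(range(1, 25)), means, tuple(25 - s for s in range(1, 25)))
        peak = sa.octave_peak(profile)
        assert peak.separation == 12
        assert peak.contrast == pytest.approx(0.046, abs=0.005)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            sa.octave_peak(sa.IntervalProfile((1, 2), (0.5, 0.4), (2, 1)))


class TestCorrelation:
    def test_self_correlation_is_one(self, helix_ratings, pitch_ladder):
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        res = sa.correlate_upper_triangles(M, M)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.n_pairs == 300

    def test_affine_invariance(self, helix_ratings, pitch_ladder):
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        B = sa.SimilarityMatrix(ids=M.ids, values=3.0 * M.values + 2.0)
        assert sa.correlate_upper_triangles(M, B).r == pytest.approx(1.0, abs=1e-12)

    def test_independent_matrices_are_near_zero(self):
        rng = np.random.default_rng(17)
        ids = tuple(f"s{i}" for i in range(25))
        A = _matrix(0.5 * (lambda x: x + x.T)(rng.uniform(size=(25, 25))), ids=ids)
        B = _matrix(0.5 * (lambda x: x + x.T)(rng.uniform(size=(25, 25))), ids=ids)
        assert abs(sa.correlate_upper_triangles(A, B).r) < 0.15  # ~2/sqrt(300)

    def test_id_mismatch_rejected(self):
        A = _matrix(np.eye(3), ids=["a", "b", "c"])
        B = _matrix(np.eye(3), ids=["a", "b", "z"])
        with pytest.raises(ValueError):
            sa.correlate_upper_triangles(A, B)


class TestBootstrapCorrelation:
    def test_point_estimate_matches_plain_correlation(self, helix_ratings, helix, pitch_ladder):
        truth = _truth_matrix(helix, pitch_ladder.ids)
        M = sa.assemble_matrix(helix_ratings, pitch_ladder.ids)
        plain = sa.correlate_upper_triangles(M, truth)
        boot = sa.bootstrap_correlation(helix_ratings, truth, n_boot=50, seed=0)
        assert boot.r == pytest.approx(plain.r, abs=1e-12)

    def test_ci_tight_and_high_under_generative_model(self, helix_ratings, helix, pitch_ladder):
        truth = _truth_matrix(helix, pitch_ladder.ids)
        res = sa.bootstrap_correlation(helix_ratings, truth, n_boot=1000, seed=3)
        assert res.ci_low > 0.9
        assert res.ci_low <= res.r <= res.ci_high

    def test_zero_noise_gives_zero_width_ci(self, helix, all_pitch_pairs, pitch_ladder):
        respondent = ps.SimilarityRespondent(space=helix, noise_sd=0.0, seed=0)
        recs = ps.simulate_similarity_ratings(respondent, all_pitch_pairs, 5)
        truth = _truth_matrix(helix, pitch_ladder.ids)
        res = sa.bootstrap_correlation(recs, truth, n_boot=200, seed=1)
        assert res.ci_low == res.ci_high == pytest.approx(res.r, abs=1e-12)


class TestReliability:
    @pytest.mark.parametrize(
        "r, expected", [(0.9, 2 * 0.9 / 1.9), (0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)]
    )
    def test_spearman_brown_formula(self, r, expected):
        assert sa.spearman_brown(r) == pytest.approx(expected, abs=1e-12)

    def test_spearman_brown_monotone_fixing_zero_and_one(self):
        grid = np.linspace(-0.99, 1.0, 200)
        vals = [sa.spearman_brown(r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert sa.spearman_brown(0.0) == 0.0
        assert sa.spearman_brown(1.0) == 1.0

    def test_two_identical_raters_give_unit_irr(self, helix, all_pitch_pairs, pitch_ladder):
        respondent = ps.SimilarityRespondent(space=helix, noise_sd=0.0, seed=0, rater_id="r1")
        recs1 = ps.simulate_similarity_ratings(respondent, all_pitch_pairs, 1)
        recs2 = [sa.RatingRecord("r2", r.stim_a, r.stim_b, r.rating, r.repetition) for r in recs1]
        res = sa.split_half_reliability(recs1 + recs2, pitch_ladder.ids, n_boot=20, seed=0)
        assert res.corrected_r == pytest.approx(1.0, abs=1e-12)
        assert res.ci_low == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_raters_rejected(self, pitch_ladder):
        recs = [sa.RatingRecord("only", "tone_00", "tone_01", 0.5, 0)]
        with pytest.raises(ValueError):
            sa.split_half_reliability(recs, pitch_ladder.ids, n_boot=5, seed=0)


class TestQualityBonus:
    @pytest.mark.parametrize(
        "original, repeated, expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 0.1),       # s = 1
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], 0.0),       # s = -1, clamped
        ],
    )
    def test_boundary_cases(self, original, repeated, expected):
        qa = sa.quality_bonus(original, repeated)
        assert qa.bonus == pytest.approx(expected, abs=1e-12)

    def test_half_consistency_gives_half_bonus(self):
        # rankings chosen so Spearman s = 0.5 exactly
        qa = sa.quality_bonus([1, 2, 3, 4], [2, 1, 4, 3])
        assert qa.consistency_spearman == pytest.approx(0.6, abs=1e-12)
        assert qa.bonus == pytest.approx(0.06, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sa.quality_bonus([1, 2, 3], [1, 2])


class TestClassicalMDS:
    def test_three_equidistant_points_form_equilateral_triangle(self):
        M = _matrix(np.where(np.eye(3, dtype=bool), 1.0, 0.4))
        emb = sa.classical_mds(M, 2)
        from scipy.spatial.distance import pdist

        d = pdist(emb.coordinates)
        assert np.allclose(d, d[0], atol=1e-9)

    def test_recovers_planar_geometry(self):
        # compact cloud (distances <~ 1) so exp(-d) stays near-affine in d
        rng = np.random.default_rng(5)
        pts = 0.5 * rng.uniform(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        M = _matrix(np.exp(-D))
        emb = sa.classical_mds(M, 2)
        from scipy import stats

        rank = stats.spearmanr(pdist(emb.coordinates), pdist(pts)).statistic
        assert rank > 0.99

    def test_eigenvalues_nonincreasing(self, helix_ratings, pitch_ladder):
        M = sa.smooth_toeplitz(sa.assemble_matrix(helix_ratings, pitch_ladder.ids))
        emb = sa.classical_mds(M, 5)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()

    def test_k_out_of_range_rejected(self):
        M = _matrix(np.eye(4))
        with pytest.raises(ValueError):
            sa.classical_mds(M, 4)


class TestProcrustesDistanceCorrelation:
    def test_exact_recovery_from_own_distances(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(pts))
        M = _matrix(-D)  # affine in distance: classical MDS is exact
        emb = sa.classical_mds(M, 3)
        space = ps.LatentSpace({f"s{i}": pts[i] for i in range(10)})
        assert sa.procrustes_distance_correlation(emb, space) == pytest.approx(1.0, abs=1e-6)

    def test_random_embedding_is_uncorrelated(self, helix, pitch_ladder):
        rng = np.random.default_rng(2)
        emb = sa.EmbeddingResult(
            ids=pitch_ladder.ids, coordinates=rng.normal(size=(25, 3)),
            eigenvalues=np.array([3.0, 2.0, 1.0]),
        )
        assert sa.procrustes_distance_correlation(emb, helix) < 0.5

    def test_invariant_to_rigid_rotation(self, helix, pitch_ladder):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        coords = np.array([helix.coordinates[i] for i in pitch_ladder.ids])
        emb1 = sa.EmbeddingResult(pitch_ladder.ids, coords, np.zeros(3))
        emb2 = sa.EmbeddingResult(pitch_ladder.ids, coords @ Q, np.zeros(3))
        r1 = sa.procrustes_distance_correlation(emb1, helix)
        r2 = sa.procrustes_distance_correlation(emb2, helix)
        assert r1 == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(r1, abs=1e-9)


class TestTermFrequencies:
    def test_fraction_of_texts_containing_token(self):
        freqs = sa.term_frequencies(["a b", "a", "c"])
        assert freqs == {"a": 2 / 3, "b": 1 / 3, "c": 1 / 3}

    def test_repeated_token_in_one_text_counts_once(self):
        assert sa.term_frequencies(["blue sky", "deep blue blue"])["blue"] == 1.0

    def test_exclusion_list(self):
        freqs = sa.term_frequencies(["similar blue", "similar red"], exclude=["similar"])
        assert "similar" not in freqs

    def test_sorted_descending(self):
        freqs = sa.term_frequencies(["a b", "a c", "a", "b"])
        assert list(freqs)[0] == "a"


def _truth_matrix(space, ids):
    ids = list(ids)
    n = len(ids)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = math.exp(-space.distance(ids[i], ids[j]))
    return sa.SimilarityMatrix(ids=tuple(ids), values=m, symmetric=True)
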