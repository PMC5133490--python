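import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pathvc as pv
from pathvc.similarity import (
    ALL_METHODS,
    DISTANCE_METHODS,
    SIMILARITY_METHODS,
    canonical_method,
)

from _oracles import naive_similarity_matrix


def profile(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pv.ProfileSet(
        X, [f"I{i}" for i in range(X.shape[0])], [f"P{j}" for j in range(X.shape[1])]
    )


class TestPairwiseDistance:
    def test_euclidean_hand_example(self):
        D = pv.pairwise_distance(profile([[0.0, 0.0], [3.0, 4.0]]), "eucl")
        assert D[0, 1] == pytest.approx(5.0)

    def test_bhattacharyya_hand_example(self):
        # single-probe profiles 4 and 1: sqrt((2 - 1)^2) = 1
        with pytest.warns(UserWarning, match="single probe"):
            P = profile([[4.0], [1.0]])
        D = pv.pairwise_distance(P, "bhja")
        assert D[0, 1] == pytest.approx(1.0)

    def test_divergence_hand_example(self):
        D = pv.pairwise_distance(profile([[1.0, 0.0], [0.0, 1.0]]), "dive")
        assert D[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("method", DISTANCE_METHODS)
    def test_identical_rows_have_zero_distance(self, method):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, size=6)
        D = pv.pairwise_distance(profile(np.vstack([x, x, rng.uniform(0.1, 1, 6)])), method)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(D), 0.0)

    @pytest.mark.parametrize("method", DISTANCE_METHODS)
    def test_symmetric_nonnegative(self, method):
        rng = np.random.default_rng(4)
        D = pv.pairwise_distance(profile(rng.uniform(0.05, 1.0, size=(6, 5))), method)
        assert np.allclose(D, D.T)
        assert D.min() >= 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pv.pairwise_distance(profile(np.ones((2, 3))), "nope")

    def test_mahalanobis_singular_covariance_ridged(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(4, 6))  # more probes than individuals
        with pytest.warns(UserWarning, match="ridge"):
            D = pv.pairwise_distance(profile(X), "maha")
        assert np.isfinite(D).all()


class TestDistanceToSimilarity:
    def test_formula_values(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        sim = pv.distance_to_similarity(D)
        assert sim.S[0, 0] == 1.0  # d = 0
        assert sim.S[0, 1] == 0.5  # d = 1

    def test_monotone_decreasing_toward_zero(self):
        D = np.array([[0.0, 1.0, 1e9], [1.0, 0.0, 2.0], [1e9, 2.0, 0.0]])
        S = pv.distance_to_similarity(D).S
        assert S[0, 2] < S[0, 1] < S[0, 0]
        assert S[0, 2] < 1e-8

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pv.distance_to_similarity(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestDirectSimilarity:
    def test_correlation_self_and_reversal(self):
        S = pv.direct_similarity(profile([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]), "corr").S
        assert S[0, 0] == pytest.approx(1.0)
        assert S[0, 1] == pytest.approx(-1.0)

    def test_extended_jaccard_hand_examples(self):
        S = pv.direct_similarity(profile([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), "ejac").S
        assert S[0, 1] == pytest.approx(0.5)  # 1 / (1 + 2 - 1)
        assert S[0, 2] == pytest.approx(0.0)  # orthogonal
        assert np.allclose(np.diag(S), 1.0)

    def test_constant_profile_correlation_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            S = pv.direct_similarity(
                profile([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]]), "corr"
            ).S
        assert S[0, 1] == 0.0
        assert S[0, 0] == 1.0

    def test_all_zero_row_cosine_convention(self):
        with pytest.warns(UserWarning, match="all-zero"):
            S = pv.direct_similarity(profile([[0.0, 0.0], [0.3, 0.4]]), "cosine").S
        assert S[0, 0] == 1.0
        assert S[0, 1] == 0.0


class TestOracleEquivalence:
    """Vectorized kernels vs a naive double-loop of each printed formula."""

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_all_16_metrics_match_naive_loop(self, method):
        rng = np.random.default_rng(42)
        X = rng.uniform(0.0, 1.0, size=(5, 4))
        expected = naive_similarity_matrix(X, method)
        if method in SIMILARITY_METHODS:
            got = pv.direct_similarity(profile(X), method).S
        else:
            got = pv.distance_to_similarity(
                pv.pairwise_distance(profile(X), method), method
            ).S
        assert np.abs(got - expected).max() < 1e-10


class TestMakePsd:
    def test_identity_untouched(self):
        sim = pv.SimilarityMatrix(np.eye(3), ["a", "b", "c"], "corr")
        out = pv.make_psd(sim)
        assert not out.psd_repaired
        assert np.allclose(out.S, np.eye(3))

    def test_indefinite_2x2_clipped_reconstruction(self):
        # eigenvalues 2.5 and -0.5; clipping the negative one leaves
        # 2.5 * vv' with v = (1,1)/sqrt(2), i.e. all entries 1.25
        sim = pv.SimilarityMatrix(
            np.array([[1.0, 1.5], [1.5, 1.0]]), ["a", "b"], "eucl"
        )
        out = pv.make_psd(sim)
        assert out.psd_repaired
        assert out.min_eigenvalue_before_repair == pytest.approx(-0.5)
        assert np.allclose(out.S, 1.25 * np.ones((2, 2)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_output_always_psd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 6))
        sim = pv.SimilarityMatrix(0.5 * (A + A.T), [f"i{k}" for k in range(6)], "eucl")
        out = pv.make_psd(sim)
        assert np.linalg.eigvalsh(out.S).min() >= -1e-8


class TestStandardize:
    def test_unit_diagonal_unchanged(self):
        S = np.array([[1.0, 0.2], [0.2, 1.0]])
        out = pv.standardize_vc_matrix(pv.SimilarityMatrix(S, ["a", "b"], "corr"))
        assert np.allclose(out.S, S)

    def test_scaled_identity_restored(self):
        out = pv.standardize_vc_matrix(
            pv.SimilarityMatrix(2.0 * np.eye(3), ["a", "b", "c"], "eucl")
        )
        assert np.allclose(out.S, np.eye(3))

    def test_mean_diagonal_exactly_one(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(5, 5))
        S = A @ A.T
        out = pv.standardize_vc_matrix(
            pv.SimilarityMatrix(S, [f"i{k}" for k in range(5)], "eucl")
        )
        assert np.trace(out.S) / 5 == pytest.approx(1.0)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            pv.standardize_vc_matrix(
                pv.SimilarityMatrix(np.zeros((2, 2)), ["a", "b"], "eucl")
            )


class TestKernelProperties:
    def test_correlation_kernel_is_psd_without_repair(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(40, 15))
        S = pv.direct_similarity(profile(X), "corr").S
        assert np.linalg.eigvalsh(S).min() >= -1e-8

    @pytest.mark.parametrize("method", ["corr", "ejac", "eucl", "bhja", "dive"])
    def test_permutation_equivariance(self, method):
        rng = np.random.default_rng(13)
        X = rng.uniform(0.05, 1, size=(7, 5))
        perm = rng.permutation(7)
        S = pv.compute_similarity(profile(X), method, psd_repair=False).S
        S_perm = pv.compute_similarity(profile(X[perm]), method, psd_repair=False).S
        assert np.allclose(S_perm, S[np.ix_(perm, perm)])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.integers(0, 2**31 - 1),
        st.sampled_from([m for m in DISTANCE_METHODS if m != "mahalanobis"]),
    )
    def test_distance_similarities_in_unit_interval(self, seed, method):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(5, 4))
        S = pv.distance_to_similarity(pv.pairwise_distance(profile(X), method)).S
        assert S.min() > 0.0 and S.max() <= 1.0 + 1e-12
        assert np.allclose(np.diag(S), 1.0)

    def test_alias_resolution(self):
        assert canonical_method("bhja") == "bhattacharyya"
        assert canonical_method("Extended-Jaccard") == "extended_jaccard"
        assert canonical_method("tschebyscheff") == "chebyshev"


class TestSklearnCrossCheck:
    """Independent library cross-check for the metrics scikit-learn shares."""

    @pytest.mark.parametrize(
        "ours, theirs",
        [
            ("euclidean", "euclidean"),
            ("manhattan", "manhattan"),
            ("chebyshev", "chebyshev"),
            ("canberra", "canberra"),
            ("braycurtis", "braycurtis"),
        ],
    )
    def test_distances_match_sklearn(self, ours, theirs):
        from sklearn.metrics import pairwise_distances

        rng = np.random.default_rng(77)
        X = rng.uniform(0.05, 1.0, size=(8, 6))
        D = pv.pairwise_distance(profile(X), ours)
        assert np.abs(D - pairwise_distances(X, metric=theirs)).max() < 1e-10

    def test_cosine_matches_sklearn(self):
        from sklearn.metrics.pairwise import cosine_similarity

        rng = np.random.default_rng(78)
        X = rng.uniform(0.05, 1.0, size=(8, 6))
        S = pv.direct_similarity(profile(X), "cosine").S
        assert np.abs(S - cosine_similarity(X)).max() < 1e-10
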