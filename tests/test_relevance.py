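import numpy as np
import pytest

from eegrel import (
    SynthSpec,
    extract_observation_matrix,
    fit_subspace,
    generate_dataset,
    per_class_weights,
    relevance_profile,
    relevance_weights,
    weights_from_observations,
)
from eegrel.exceptions import (
    DegenerateCovarianceError,
    InsufficientDataError,
    ShapeError,
)
from eegrel.features import ObservationMatrix
from eegrel.relevance import EigenBasis, RelevanceProfile
from eegrel.synth import ClassProfile

BANDS = ["delta", "theta", "alpha", "beta"]


def _om(X, labels, p=1, n_m=1):
    X = np.asarray(X, dtype=float)
    T = X.shape[0] // (p * n_m)
    return ObservationMatrix(
        X=X, labels=list(labels), band_names=BANDS[:p], n_M=n_m, n_frames=T
    )


class TestFitSubspace:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gram_trick_matches_dense_eigendecomposition(self, seed):
        # snapshot path (d > M) against a brute-force dense covariance eig
        rng = np.random.default_rng(seed)
        d, M = 24, 6
        X = rng.normal(size=(d, M))
        basis = fit_subspace(X, var_threshold=1.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        lam_o, V_o = np.linalg.eigh(Xc @ Xc.T / M)
        lam_o = lam_o[::-1]
        V_o = V_o[:, ::-1]
        r = basis.rank
        assert r == M - 1  # centering removes one dimension
        assert np.allclose(basis.eigenvalues, lam_o[:r], atol=1e-8)
        for k in range(r):
            assert abs(abs(basis.eigenvectors[:, k] @ V_o[:, k]) - 1.0) < 1e-8

    def test_mapped_eigenvectors_are_orthonormal(self, rng):
        X = rng.normal(size=(30, 10))
        basis = fit_subspace(X)
        V = basis.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_small_dimension_uses_dense_path_consistently(self, rng):
        X = rng.normal(size=(4, 50))
        basis = fit_subspace(X, var_threshold=1.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        lam_o = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / 50))[::-1]
        assert np.allclose(basis.eigenvalues, lam_o[: basis.rank], atol=1e-8)

    def test_isotropic_data_has_flat_spectrum(self, rng):
        X = 2.0 * rng.normal(size=(3, 4000))
        basis = fit_subspace(X, var_threshold=1.0)
        assert np.all(np.abs(basis.eigenvalues - 4.0) / 4.0 < 0.2)
        # explained variance accrues roughly linearly
        assert basis.explained_variance[0] < 0.45

    def test_full_retention_keeps_rank_components(self, rng):
        X = rng.normal(size=(10, 5))
        basis = fit_subspace(X, var_threshold=1.0)
        assert basis.q == basis.rank == 4

    def test_q_monotone_in_threshold(self, rng):
        X = rng.normal(size=(20, 8))
        qs = [fit_subspace(X, var_threshold=v).q for v in (0.2, 0.5, 0.8, 0.95, 1.0)]
        assert qs == sorted(qs)

    def test_identical_columns_are_degenerate(self):
        X = np.ones((6, 4))
        with pytest.raises(DegenerateCovarianceError):
            fit_subspace(X)

    def test_too_few_objects(self):
        with pytest.raises(InsufficientDataError):
            fit_subspace(np.ones((6, 1)))


class TestRelevanceProfile:
    def test_single_component_mass_propagates_to_its_block(self):
        p, T = 4, 3
        v = np.zeros(p * T)
        v[T : 2 * T] = 1.0 / np.sqrt(T)  # theta block
        basis = EigenBasis(
            eigenvalues=np.array([2.0]),
            eigenvectors=v[:, None],
            q=1,
            explained_variance=np.array([1.0]),
            centered=True,
            var_threshold=0.95,
            dims=(p, 1, T),
        )
        prof = relevance_profile(basis, band_names=BANDS)
        assert np.all(prof.g[1] > 0)
        assert np.allclose(prof.g[[0, 2, 3]], 0.0)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(12, 6))
        basis = fit_subspace(X)
        prof = relevance_profile(basis, dims=(4, 3))
        g_direct = (
            np.abs(basis.eigenvectors[:, : basis.q]) @ basis.eigenvalues[: basis.q]
        ).reshape(4, 3)
        assert np.allclose(prof.g, g_direct)

    def test_coefficient_axis_is_averaged(self, rng):
        X = rng.normal(size=(4 * 2 * 3, 5))
        basis = fit_subspace(X)
        prof = relevance_profile(basis, dims=(4, 2, 3))
        g_raw = np.abs(basis.eigenvectors[:, : basis.q]) @ basis.eigenvalues[: basis.q]
        assert np.allclose(prof.g, g_raw.reshape(4, 2, 3).mean(axis=1))

    def test_dimension_mismatch_raises(self, rng):
        basis = fit_subspace(rng.normal(size=(12, 5)))
        with pytest.raises(ShapeError):
            relevance_profile(basis, dims=(5, 3))


class TestRelevanceWeights:
    def test_constant_profile_averages_to_itself(self):
        g = np.array([[0.3, 0.3], [0.9, 0.9], [0.1, 0.1], [0.5, 0.5]])
        w = relevance_weights(RelevanceProfile(g=g, band_names=BANDS))
        assert np.allclose(w.gamma, [0.3, 0.9, 0.1, 0.5])
        assert w.ranking == ["theta", "beta", "delta", "alpha"]

    def test_ties_break_in_canonical_band_order(self):
        g = np.full((4, 2), 1.0)
        w = relevance_weights(RelevanceProfile(g=g, band_names=BANDS))
        assert w.ranking == BANDS

    def test_scaling_observations_scales_gamma_quadratically(self, rng):
        X = rng.normal(size=(12, 6))
        w1 = weights_from_observations(_om(X, list("abcdef"), p=4))
        w3 = weights_from_observations(_om(3.0 * X, list("abcdef"), p=4))
        assert np.allclose(w3.gamma, 9.0 * w1.gamma, rtol=1e-8)
        assert w3.ranking == w1.ranking


class TestPerClassWeights:
    def test_identical_classes_get_identical_weights(self, rng):
        X = rng.normal(size=(12, 4))
        om = _om(np.hstack([X, X]), ["a"] * 4 + ["b"] * 4, p=4)
        weights = per_class_weights(om)
        assert np.allclose(weights["a"].gamma, weights["b"].gamma)

    def test_normalized_maximum_is_exactly_one(self, small_om):
        weights = per_class_weights(small_om)
        for w in weights.values():
            assert w.normalized
            assert float(w.gamma.max()) == 1.0

    def test_single_object_class_raises_with_class_name(self, rng):
        om = _om(rng.normal(size=(8, 3)), ["a", "a", "b"], p=4, n_m=1)
        with pytest.raises(InsufficientDataError, match="'b'"):
            per_class_weights(om)


class TestRelevanceRecovery:
    def test_band_with_extra_power_ranks_first(self):
        # classes identical except for theta-band power; the pooled
        # relevance analysis should single out theta
        flat = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0}
        boosted = dict(flat, theta=3.0)
        hits = 0
        for seed in range(5):
            spec = SynthSpec(
                n_segments=40,
                seed=100 + seed,
                profiles={
                    "a": ClassProfile(flat, 50.0),
                    "b": ClassProfile(boosted, 50.0),
                },
            )
            _, segs = generate_dataset(spec, ["a", "b"])
            om = extract_observation_matrix(segs)
            w = weights_from_observations(om)
            hits += w.ranking[0] == "theta"
        assert hits >= 4

    def test_ictal_class_ranks_delta_then_theta(self, small_om):
        weights = per_class_weights(small_om)
        assert weights["ictal"].ranking == ["delta", "theta", "alpha", "beta"]
        assert weights["normal"].ranking[0] == "alpha"
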