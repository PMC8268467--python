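import numpy as np
import pytest

from corrdistort.distortion import (
    GroupSummary,
    distorted_correlation,
    distorted_mean,
    distorted_std,
    distortion_profile,
    phi_profile_batch,
    reduced_dimension_sequence,
)
from corrdistort.spectral import decompose, phi


@pytest.fixture
def gaussian_group():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((25, 6))
    return X, GroupSummary.from_matrix(X)


class TestDistortedMean:
    def test_natural_weights_at_large_group(self, gaussian_group):
        _, s = gaussian_group
        # at n = 200 the group keeps ~0.995 of the weight, the sample ~0.005
        assert round(200 / 201, 3) == 0.995
        b_tilde = distorted_mean(s, np.zeros(s.n_features), 200)
        np.testing.assert_allclose(b_tilde, (200 / 201) * s.b_g, rtol=1e-12)

    def test_natural_weights_at_three(self, gaussian_group):
        _, s = gaussian_group
        x = np.ones(s.n_features)
        np.testing.assert_allclose(
            distorted_mean(s, x, 3), 0.75 * s.b_g + 0.25 * x, rtol=1e-12
        )

    def test_group_mean_is_fixed_point(self, gaussian_group):
        _, s = gaussian_group
        for n_eff in (2, 5, s.n_g):
            np.testing.assert_allclose(distorted_mean(s, s.b_g, n_eff), s.b_g, atol=1e-12)

    def test_exact_at_full_dimension(self, gaussian_group):
        X, s = gaussian_group
        rng = np.random.default_rng(1)
        x = rng.standard_normal(s.n_features)
        np.testing.assert_allclose(
            distorted_mean(s, x, s.n_g), np.vstack([X, x]).mean(axis=0), atol=1e-12
        )

    def test_length_mismatch_rejected(self, gaussian_group):
        _, s = gaussian_group
        with pytest.raises(ValueError, match="features"):
            distorted_mean(s, np.zeros(s.n_features + 1), 5)


class TestDistortedStd:
    def test_group_mean_sample_shrinks_std(self, gaussian_group):
        _, s = gaussian_group
        for n_eff in (2, 10, s.n_g):
            out = distorted_std(s, s.b_g, s.b_g, n_eff)
            np.testing.assert_allclose(out, s.sigma_g * np.sqrt((n_eff - 1) / n_eff), rtol=1e-12)

    def test_exact_at_full_dimension(self, gaussian_group):
        X, s = gaussian_group
        rng = np.random.default_rng(2)
        x = rng.standard_normal(s.n_features)
        b_tilde = distorted_mean(s, x, s.n_g)
        np.testing.assert_allclose(
            distorted_std(s, x, b_tilde, s.n_g),
            np.vstack([X, x]).std(axis=0, ddof=1),
            atol=1e-10,
        )

    def test_monotone_in_sample_deviation(self, gaussian_group):
        _, s = gaussian_group
        b_tilde = s.b_g
        small = distorted_std(s, s.b_g + 0.5, b_tilde, 10)
        large = distorted_std(s, s.b_g + 2.0, b_tilde, 10)
        assert np.all(large >= small)


class TestDistortedCorrelation:
    def test_oracle_equivalence_at_full_dimension(self):
        # the update algebra is exact: at n_eff = n_g it must reproduce the
        # Pearson correlation of the stacked matrix
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            m = int(rng.integers(2, 21))
            X = rng.standard_normal((n, m))
            x = rng.standard_normal(m)
            s = GroupSummary.from_matrix(X)
            res = distorted_correlation(s, x, n)
            oracle = np.corrcoef(np.vstack([X, x]), rowvar=False)
            assert np.max(np.abs(res.S_tilde - oracle)) < 1e-8

    def test_symmetric_and_unit_diagonal_for_any_n_eff(self, gaussian_group):
        _, s = gaussian_group
        rng = np.random.default_rng(4)
        x = rng.standard_normal(s.n_features)
        for n_eff in (2, 7, s.n_g):
            S_t = distorted_correlation(s, x, n_eff).S_tilde
            np.testing.assert_allclose(S_t, S_t.T, atol=1e-12)
            # sigma~ absorbs all three diagonal contributions exactly
            np.testing.assert_allclose(np.diag(S_t), 1.0, atol=1e-8)

    def test_group_mean_sample_annihilates_shift_terms(self, gaussian_group):
        _, s = gaussian_group
        res = distorted_correlation(s, s.b_g, s.n_g)
        scale = np.sqrt((s.n_g - 1) / s.n_g)
        d = s.sigma_g / (s.sigma_g * scale)
        expected = ((s.n_g - 1) / s.n_g) * np.outer(d, d) * s.S_g
        np.testing.assert_allclose(res.S_tilde, expected, atol=1e-10)
        assert np.all(np.sign(res.S_tilde) == np.sign(s.S_g))

    def test_sample_term_weight_grows_as_n_eff_shrinks(self, gaussian_group):
        _, s = gaussian_group
        assert 1 / 2 > 1 / s.n_g  # weight of the new-sample outer product


class TestDistortionProfile:
    def test_sequence_and_count(self, gaussian_group):
        _, s = gaussian_group
        results = distortion_profile(s, s.b_g, n_max=10, delta_n=2)
        assert [r.n_red for r in results] == [2, 4, 6, 8, 10]

    def test_minimal_ladder(self, gaussian_group):
        _, s = gaussian_group
        results = distortion_profile(s, s.b_g, n_max=2, delta_n=5)
        assert len(results) == 1 and results[0].n_red == 2

    def test_divisibility_enforced(self, gaussian_group):
        _, s = gaussian_group
        with pytest.raises(ValueError, match="divisible"):
            distortion_profile(s, s.b_g, n_max=7, delta_n=2)

    def test_phi_matches_scalar_route(self, gaussian_group):
        _, s = gaussian_group
        rng = np.random.default_rng(5)
        x = rng.standard_normal(s.n_features)
        ref = decompose(s.S_g, 0.05)
        for res in distortion_profile(s, x, n_max=12, delta_n=5, alpha=0.05):
            expected = phi(ref, decompose(res.S_tilde, 0.05))
            assert res.phi_value == pytest.approx(expected, abs=1e-10)


class TestBatchConsistency:
    def test_batch_equals_scalar_over_rows_and_rungs(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((15, 5))
        s = GroupSummary.from_matrix(X)
        rows = rng.standard_normal((4, 5))
        n_reds = reduced_dimension_sequence(14, 3)
        batch = phi_profile_batch(s, rows, n_reds, alpha=0.05)
        ref = decompose(s.S_g, 0.05)
        for i, x in enumerate(rows):
            for k, n_red in enumerate(n_reds):
                S_t = distorted_correlation(s, x, int(n_red)).S_tilde
                assert batch[i, k] == pytest.approx(phi(ref, decompose(S_t, 0.05)), abs=1e-10)


def test_outlying_sample_distorts_more_than_in_group_draws():
    # at full dimension, a strongly shifted sample must distort the structure
    # far more than draws from the group's own distribution (median over 100)
    rng = np.random.default_rng(7)
    X = rng.standard_normal((30, 8))
    s = GroupSummary.from_matrix(X)
    ref = decompose(s.S_g)
    in_phis = np.abs(phi_profile_batch(s, rng.standard_normal((100, 8)), np.array([s.n_g]))[:, 0])
    shifted = s.b_g + 6.0 * s.sigma_g + rng.standard_normal((100, 8))
    out_phis = np.abs(phi_profile_batch(s, shifted, np.array([s.n_g]))[:, 0])
    assert np.median(out_phis) > 3 * np.median(in_phis)
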