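"""Behavioral PLS: closed-form oracles, resampling inference, invariants."""

import numpy as np
import pandas as pd
import pytest

from hrvbold import (
    behavioral_pls,
    bootstrap_test,
    effect_direction_map,
    fit_pls,
    permutation_test,
    slope_vs_brainscores,
    zscore_columns,
)


def make_blocks(rng, n=40, v=80, signal_voxels=None, noise=0.5):
    """Predictor x and voxel block where listed voxels carry x's signal."""
    x = rng.standard_normal(n)
    Y = rng.standard_normal((n, v)) * noise
    if signal_voxels:
        for j in signal_voxels:
            Y[:, j] += x
    X = zscore_columns(x[:, None])
    Yz = zscore_columns(Y)
    return X, Yz, x


class TestZscore:
    def test_hand_example(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        M = rng.standard_normal((30, 4))
        once = zscore_columns(M)
        np.testing.assert_allclose(zscore_columns(once), once, atol=1e-9)

    def test_constant_column_rejected_by_name(self):
        M = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="log_hf"):
            zscore_columns(M, names=["age", "log_hf"])


class TestFitPls:
    def test_signal_voxel_has_largest_salience(self, rng):
        X, Yz, _ = make_blocks(rng, signal_voxels=[0], noise=0.3)
        model = fit_pls(X, Yz)
        assert np.argmax(np.abs(model.voxel_saliences[:, 0])) == 0

    def test_single_predictor_saliences_proportional_to_correlations(self, rng):
        # SVD of a 1 x v matrix: v-side singular vector is R / ||R||
        X, Yz, _ = make_blocks(rng, signal_voxels=[0, 3], noise=1.0)
        model = fit_pls(X, Yz)
        r = (X[:, 0] @ Yz) / (len(X) - 1)  # mass-univariate correlations
        expected = r / np.linalg.norm(r)
        sal = model.voxel_saliences[:, 0]
        sign = np.sign(sal @ expected)
        np.testing.assert_allclose(sal, sign * expected, atol=1e-10)

    def test_reconstruction_and_cov_explained(self, rng):
        X = zscore_columns(rng.standard_normal((25, 3)))
        Yz = zscore_columns(rng.standard_normal((25, 40)))
        model = fit_pls(X, Yz)
        recon = (
            model.predictor_saliences
            @ np.diag(model.singular_values)
            @ model.voxel_saliences.T
        )
        assert np.max(np.abs(model.R - recon)) < 1e-8
        assert model.cov_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.singular_values) <= 1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(model.voxel_saliences, axis=0), 1.0, atol=1e-9
        )

    def test_brain_scores_match_mass_univariate_oracle(self, rng):
        # p = 1: brain scores are the correlation-weighted voxel sums
        X, Yz, _ = make_blocks(rng, signal_voxels=[1], noise=0.8)
        model = fit_pls(X, Yz)
        r = (X[:, 0] @ Yz) / (len(X) - 1)
        oracle = Yz @ (r / np.linalg.norm(r))
        sign = np.sign(oracle @ model.brain_scores[:, 0])
        np.testing.assert_allclose(
            model.brain_scores[:, 0], sign * oracle, atol=1e-10
        )

    def test_r_entries_are_pearson_correlations(self, rng):
        X = zscore_columns(rng.standard_normal((30, 2)))
        Yz = zscore_columns(rng.standard_normal((30, 5)))
        model = fit_pls(X, Yz)
        for i in range(2):
            for j in range(5):
                assert model.R[i, j] == pytest.approx(
                    np.corrcoef(X[:, i], Yz[:, j])[0, 1], abs=1e-12
                )


class TestPermutation:
    def test_perfect_signal_reaches_floor(self, rng):
        x = rng.standard_normal(30)
        Y = np.tile(x[:, None], (1, 10)) + 0.001 * rng.standard_normal((30, 10))
        model = fit_pls(zscore_columns(x[:, None]), zscore_columns(Y))
        perm = permutation_test(model, n_perm=99, seed=0)
        assert perm.p_values[0] == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        X, Yz, _ = make_blocks(rng)
        model = fit_pls(X, Yz)
        p1 = permutation_test(model, 50, seed=3).p_values
        p2 = permutation_test(model, 50, seed=3).p_values
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_n_perm_rejected(self, rng):
        X, Yz, _ = make_blocks(rng)
        with pytest.raises(ValueError):
            permutation_test(fit_pls(X, Yz), n_perm=0)

    def test_null_type_one_error_calibrated(self):
        # Y independent of X: rejection rate at alpha=.05 near nominal
        rej = 0
        reps = 60
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            X = zscore_columns(r.standard_normal((30, 2)))
            Yz = zscore_columns(r.standard_normal((30, 40)))
            model = fit_pls(X, Yz)
            p = permutation_test(model, 99, seed=rep).p_values[0]
            rej += p < 0.05
        # binomial 99% interval around 0.05 for 60 draws: [0, 8]
        assert rej <= 8


class TestBootstrap:
    def test_planted_voxel_flagged_significant(self, rng):
        X, Yz, _ = make_blocks(rng, n=60, signal_voxels=[2], noise=0.05)
        model = fit_pls(X, Yz)
        boot = bootstrap_test(model, n_boot=200, seed=1)
        assert boot.significant[2, 0]

    def test_threshold_zero_flags_all_nonzero_se(self, rng):
        X, Yz, _ = make_blocks(rng)
        model = fit_pls(X, Yz)
        boot = bootstrap_test(model, n_boot=100, threshold=0.0, seed=2)
        nonzero = boot.salience_se[:, 0] > 0
        assert boot.significant[nonzero, 0].all()

    def test_bsr_identity(self, rng):
        X, Yz, _ = make_blocks(rng)
        boot = bootstrap_test(fit_pls(X, Yz), n_boot=100, seed=4)
        ok = boot.salience_se > 0
        np.testing.assert_allclose(
            boot.bootstrap_ratio[ok],
            boot.mean_salience[ok] / boot.salience_se[ok],
        )
        assert not boot.significant[~ok].any()


class TestSignConventions:
    def test_flipping_nonleading_predictor(self, rng):
        # predictor 0 dominates; predictor 1 is weak, then flipped
        x0 = rng.standard_normal(50)
        x1 = rng.standard_normal(50)
        Y = np.outer(x0, rng.standard_normal(60)) + 0.3 * rng.standard_normal(
            (50, 60)
        )
        P = pd.DataFrame({"a": x0, "b": x1})
        P_flip = pd.DataFrame({"a": x0, "b": -x1})
        m0 = behavioral_pls(P, Y)
        m1 = behavioral_pls(P_flip, Y)
        np.testing.assert_allclose(
            m1.predictor_saliences[1, 0],
            -m0.predictor_saliences[1, 0],
            atol=1e-10,
        )
        np.testing.assert_allclose(
            m1.voxel_saliences[:, 0], m0.voxel_saliences[:, 0], atol=1e-10
        )
        p0 = permutation_test(m0, 50, seed=5).p_values
        p1 = permutation_test(m1, 50, seed=5).p_values
        np.testing.assert_allclose(p0, p1)
        b0 = bootstrap_test(m0, 50, seed=6).bootstrap_ratio[:, 0]
        b1 = bootstrap_test(m1, 50, seed=6).bootstrap_ratio[:, 0]
        np.testing.assert_allclose(np.abs(b0), np.abs(b1), atol=1e-8)

    def test_leading_salience_is_positive(self, rng):
        X = zscore_columns(rng.standard_normal((30, 3)))
        Yz = zscore_columns(rng.standard_normal((30, 20)))
        model = fit_pls(X, Yz)
        for k in range(3):
            col = model.predictor_saliences[:, k]
            assert col[np.argmax(np.abs(col))] > 0


class TestSlopes:
    def test_exact_linearity(self, rng):
        x = rng.uniform(20, 80, 40)
        fit = slope_vs_brainscores(x, 2.0 * x, "age")
        assert fit.beta == pytest.approx(2.0)
        assert fit.p < 1e-10

    def test_matches_normal_equations(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        fit = slope_vs_brainscores(x, y)
        A = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)[1]
        assert fit.beta == pytest.approx(beta, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="predictor"):
            slope_vs_brainscores(np.ones(10), np.arange(10.0))


class TestEffectDirection:
    @pytest.mark.parametrize(
        "salience,beta,expected",
        [(-0.4, -1.0, 1.0), (-0.4, 1.0, -1.0), (0.0, 1.0, 0.0), (0.3, 2.0, 1.0)],
    )
    def test_sign_product(self, salience, beta, expected):
        out = effect_direction_map(np.array([salience]), beta)
        assert out[0] == expected
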