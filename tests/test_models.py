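"""GP regression, the activity classifier, LOO-CV selection, and
block-contribution recovery, checked against dense linear-algebra oracles
and an independent GP implementation."""

import numpy as np
import pytest

from chimeraopt import (
    ActivityClassifier,
    ChimeraEncoder,
    LinearKernelGP,
    block_contributions,
    enumerate_space,
    loo_cv_scan,
)
from chimeraopt.models import default_sigma2_grid

from conftest import random_toy_system


def dense_gp_oracle(X, y, Xq, sigma2, noise, center=True):
    """Posterior mean/variance via an explicit dense inverse."""
    mu = y.mean() if center else 0.0
    K = sigma2 * X @ X.T
    Minv = np.linalg.inv(K + noise * np.eye(len(y)))
    Ks = sigma2 * Xq @ X.T
    mean = Ks @ Minv @ (y - mu) + mu
    var = sigma2 * np.einsum("ij,ij->i", Xq, Xq) - np.einsum(
        "ij,jk,ik->i", Ks, Minv, Ks
    )
    return mean, np.maximum(var, 0.0)


class TestLinearKernelGP:
    def test_prior_with_no_training_data(self):
        gp = LinearKernelGP(sigma2=2.0, noise_variance=1.0).fit(
            np.zeros((0, 3)), np.zeros(0)
        )
        Xq = np.array([[1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        mean, std = gp.predict(Xq, return_std=True)
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(std**2, 2.0 * np.array([5.0, 0.0]))

    def test_interpolates_as_noise_vanishes(self, rng):
        # full-rank kernel needs n <= d for the linear kernel
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        gp = LinearKernelGP(sigma2=1.0, noise_variance=0.0).fit(X, y)
        mean, std = gp.predict(X, return_std=True)
        np.testing.assert_allclose(mean, y, atol=1e-4)
        assert np.all(std < 1e-2)

    def test_matches_dense_inverse_oracle_on_25_random_toys(self, rng):
        for trial in range(25):
            n, d = int(rng.integers(3, 12)), int(rng.integers(2, 8))
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            Xq = rng.normal(size=(5, d))
            sigma2 = float(rng.uniform(0.1, 5.0))
            noise = float(rng.uniform(0.05, 2.0))
            gp = LinearKernelGP(sigma2=sigma2, noise_variance=noise).fit(X, y)
            mean, std = gp.predict(Xq, return_std=True)
            mean_o, var_o = dense_gp_oracle(X, y, Xq, sigma2, noise)
            np.testing.assert_allclose(mean, mean_o, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(std**2, var_o, rtol=1e-8, atol=1e-10)

    def test_equals_bayesian_linear_regression(self, rng):
        # weight-space view: prior w ~ N(0, sigma2 I), noise sigma_n^2
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        sigma2, noise = 0.8, 0.3
        gp = LinearKernelGP(sigma2=sigma2, noise_variance=noise, center_y=False).fit(X, y)
        A = X.T @ X / noise + np.eye(5) / sigma2
        w_hat = np.linalg.solve(A, X.T @ y / noise)
        Xq = rng.normal(size=(4, 5))
        np.testing.assert_allclose(gp.predict(Xq), Xq @ w_hat, rtol=1e-8)
        # predictive variance equals the weight-posterior quadratic form
        _, std = gp.predict(Xq, return_std=True)
        var_w = np.einsum("ij,jk,ik->i", Xq, np.linalg.inv(A), Xq)
        np.testing.assert_allclose(std**2, var_w, rtol=1e-7, atol=1e-10)

    def test_agrees_with_sklearn_gpr(self, rng):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import DotProduct

        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        noise = 0.5
        ours = LinearKernelGP(sigma2=1.0, noise_variance=noise, center_y=False).fit(X, y)
        ref = GaussianProcessRegressor(
            kernel=DotProduct(sigma_0=0.0, sigma_0_bounds="fixed"),
            alpha=noise,
            optimizer=None,
        ).fit(X, y)
        Xq = rng.normal(size=(6, 4))
        m_ref, s_ref = ref.predict(Xq, return_std=True)
        m, s = ours.predict(Xq, return_std=True)
        np.testing.assert_allclose(m, m_ref, rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(s, s_ref, rtol=1e-6, atol=1e-8)

    def test_variance_never_increases_with_more_data(self, rng):
        X = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        Xq = rng.normal(size=(20, 4))
        small = LinearKernelGP(noise_variance=0.5).fit(X[:4], y[:4])
        big = LinearKernelGP(noise_variance=0.5).fit(X, y)
        _, s_small = small.predict(Xq, return_std=True)
        _, s_big = big.predict(Xq, return_std=True)
        assert np.all(s_big <= s_small + 1e-10)

    def test_input_validation(self):
        gp = LinearKernelGP()
        with pytest.raises(ValueError):
            gp.fit(np.ones((3, 2)), np.array([1.0, np.nan, 2.0]))
        gp.fit(np.ones((2, 3)), np.ones(2))
        with pytest.raises(ValueError):
            gp.predict(np.ones((1, 5)))
        with pytest.raises(ValueError):
            LinearKernelGP(sigma2=-1.0).fit(np.ones((2, 2)), np.ones(2))

    def test_sklearn_params_round_trip(self):
        gp = LinearKernelGP(sigma2=3.0, noise_variance=0.2)
        params = gp.get_params()
        assert params["sigma2"] == 3.0
        gp.set_params(sigma2=1.5)
        assert gp.sigma2 == 1.5


class TestActivityClassifier:
    def _separable(self, rng, n=30):
        X = rng.integers(0, 2, size=(n, 6)).astype(float)
        X[: n // 2, 0] = 1.0
        X[n // 2 :, 0] = 0.0
        y = np.where(X[:, 0] > 0.5, 50.0, 0.0)
        return X, y

    def test_separable_toy_recovers_labels(self, rng):
        X, y = self._separable(rng)
        clf = ActivityClassifier(threshold=1.0).fit(X, y)
        p = clf.predict_proba_active(X)
        assert np.all(p[y > 1.0] > 0.99)
        assert np.all(p[y <= 1.0] < 0.01)

    def test_probabilities_sum_to_one(self, rng):
        X, y = self._separable(rng)
        clf = ActivityClassifier().fit(X, y)
        np.testing.assert_allclose(clf.predict_proba(X).sum(axis=1), 1.0)

    def test_priors_recovered(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([10.0] * 3 + [0.0] * 7)
        clf = ActivityClassifier(threshold=1.0).fit(X, y)
        np.testing.assert_allclose(clf.class_prior_, [0.7, 0.3])

    def test_identical_distributions_give_half(self, rng):
        X = np.vstack([np.eye(4), np.eye(4)])
        y = np.array([10.0] * 4 + [0.0] * 4)
        clf = ActivityClassifier().fit(X, y)
        np.testing.assert_allclose(clf.predict_proba_active(np.eye(4)), 0.5, atol=1e-9)

    def test_single_class_warns_and_predicts_constant(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.warns(UserWarning, match="single-class"):
            clf = ActivityClassifier().fit(X, np.full(5, 10.0))
        np.testing.assert_allclose(clf.predict_proba_active(X), 1.0)

    def test_feature_permutation_invariance(self, rng):
        X, y = self._separable(rng)
        perm = rng.permutation(X.shape[1])
        p1 = ActivityClassifier().fit(X, y).predict_proba_active(X)
        p2 = ActivityClassifier().fit(X[:, perm], y).predict_proba_active(X[:, perm])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_boolean_labels_accepted(self, rng):
        X, y = self._separable(rng)
        clf = ActivityClassifier().fit(X, y > 1.0)
        assert clf.predict(X[:1]).dtype == bool


class TestLooCvScan:
    def test_default_grid_shape(self):
        grid = default_sigma2_grid()
        assert len(grid) == 23
        assert grid[0] == pytest.approx(1e-6) and grid[-1] == pytest.approx(1e5)

    def test_recovers_signal_from_linear_model(self, rng):
        n, d = 40, 10
        X = rng.integers(0, 2, size=(n, d)).astype(float)
        w = rng.normal(size=d) * 3.0
        y = X @ w + rng.normal(0, 0.5, size=n)
        report = loo_cv_scan(X, y, noise_variance=0.25)
        best_r = np.nanmax(report.r)
        chosen_idx = list(report.grid).index(report.chosen_sigma2)
        assert best_r > 0.9
        assert report.r[chosen_idx] > 0.85

    def test_single_value_grid_is_chosen(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        report = loo_cv_scan(X, y, grid=[0.37])
        assert report.chosen_sigma2 == 0.37

    def test_loo_matches_independent_refit_loop(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        report = loo_cv_scan(X, y, grid=[1.0], noise_variance=0.5, keep_predictions=True)
        expected = np.empty(8)
        for i in range(8):
            keep = np.arange(8) != i
            gp = LinearKernelGP(sigma2=1.0, noise_variance=0.5).fit(X[keep], y[keep])
            expected[i] = gp.predict(X[i : i + 1])[0]
        np.testing.assert_allclose(report.loo_predictions, expected, rtol=1e-10)

    def test_fast_path_agrees_with_refit(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        slow = loo_cv_scan(X, y, noise_variance=0.7, center_y=False, method="refit")
        fast = loo_cv_scan(X, y, noise_variance=0.7, center_y=False, method="fast")
        np.testing.assert_allclose(fast.mse, slow.mse, rtol=1e-8)
        np.testing.assert_allclose(fast.r, slow.r, rtol=1e-8)
        assert fast.chosen_sigma2 == slow.chosen_sigma2

    def test_constant_targets_fall_back_to_mse(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.warns(UserWarning, match="constant"):
            report = loo_cv_scan(X, np.full(6, 7.0), grid=[0.1, 1.0])
        assert report.chosen_sigma2 in (0.1, 1.0)
        assert np.all(np.isnan(report.r))


class TestBlockContributions:
    def test_recovers_additive_effects(self, rng):
        import chimeraopt as co

        parents, partition = co.synthetic_parents(seed=11)
        cmap = co.synthetic_contact_map(parents.aligned_length, seed=12)
        spec = co.random_landscape(
            parents, partition, cmap, seed=13, inactive_fraction=0.0, n_epistasis=0
        )
        space = co.enumerate_space(parents, partition)
        idx = np.random.default_rng(14).choice(len(space), size=96, replace=False)
        train = [space[i] for i in idx]
        enc = ChimeraEncoder(parents, partition)
        X = enc.encode_many(train)
        y = np.array([co.true_titer(spec, c) for c in train])
        y += np.random.default_rng(15).normal(0, 1.0, size=len(y))
        sigma2 = loo_cv_scan(X, y, noise_variance=1.0).chosen_sigma2
        gp = LinearKernelGP(sigma2=sigma2, noise_variance=1.0).fit(X, y)
        table = block_contributions(gp, space, parents, partition, enc)
        est, truth = [], []
        for b in range(partition.n_blocks):
            ref_label = co.canonicalize(
                co.Chimera("A", ("A",) * partition.n_blocks), parents, partition
            ).atr_blocks[b]
            for p, label in enumerate(parents.names):
                if label == "A":
                    continue
                canon = co.canonicalize(
                    co.Chimera("A", tuple(label if k == b else "A" for k in range(partition.n_blocks))),
                    parents,
                    partition,
                ).atr_blocks[b]
                truth.append(spec.block_effects[(b, canon)] - spec.block_effects[(b, ref_label)])
                est.append(table.iloc[b][label])
        r = np.corrcoef(est, truth)[0, 1]
        assert r > 0.9

    def test_reference_column_is_zero(self, rng):
        parents, partition, _ = random_toy_system(rng)
        enc = ChimeraEncoder(parents, partition)
        space = enumerate_space(parents, partition)
        X = enc.encode_many(space)
        y = rng.normal(size=len(space))
        gp = LinearKernelGP().fit(X, y)
        table = block_contributions(gp, space, parents, partition, enc)
        np.testing.assert_allclose(table["A"], 0.0)

    def test_conserved_labels_share_effects(self, toy_parents, rng):
        parents, partition = toy_parents  # block 2 conserved between A and B
        enc = ChimeraEncoder(parents, partition)
        space = enumerate_space(parents, partition)
        gp = LinearKernelGP().fit(enc.encode_many(space), rng.normal(size=len(space)))
        table = block_contributions(gp, space, parents, partition, enc)
        assert table.loc[2, "B"] == pytest.approx(table.loc[2, "A"])
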