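"""Sequence-function models: linear-kernel GP regression, an active/inactive
Gaussian naive Bayes classifier, leave-one-out hyperparameter selection, and
block-contribution analysis.

The regressor is a Gaussian process with the homogeneous linear kernel

    k(x, x') = sigma2 * (x . x')

over one-hot sequence encodings; the posterior mean and variance follow the
standard Cholesky factorize-and-solve route (factor K + sigma_n^2 I once,
then solve per query).  With this kernel the GP is equivalent to Bayesian
linear regression with an isotropic Gaussian weight prior of variance
sigma2, which both bounds its capacity on small data and makes the posterior
mean a plain dot product with a weight vector — handy for scoring thousands
of candidate chimeras.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and compose
with sklearn model-selection utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.naive_bayes import GaussianNB

from .sequence_space import BlockPartition, Chimera, ChimeraEncoder, ParentSet

__all__ = [
    "LinearKernelGP",
    "ActivityClassifier",
    "CVReport",
    "loo_cv_scan",
    "default_sigma2_grid",
    "block_contributions",
]


def default_sigma2_grid() -> np.ndarray:
    """23 log-spaced points from 1e-6 to 1e5 (half-decade steps)."""
    return np.logspace(-6.0, 5.0, 23)


class LinearKernelGP(RegressorMixin, BaseEstimator):
    """Gaussian-process regressor with the homogeneous linear kernel.

    Parameters
    ----------
    sigma2 : prior variance multiplier of the kernel ``sigma2 * x . x'``.
    noise_variance : observation noise variance sigma_n^2; when zero a small
        jitter keeps the factorization positive definite.
    center_y : subtract the training mean before fitting and restore it at
        prediction (the GP prior mean is the data mean rather than zero).
    jitter : relative jitter scale used when ``noise_variance == 0``.
    """

    def __init__(
        self,
        sigma2: float = 1.0,
        noise_variance: float = 1.0,
        center_y: bool = True,
        jitter: float = 1e-8,
    ) -> None:
        self.sigma2 = sigma2
        self.noise_variance = noise_variance
        self.center_y = center_y
        self.jitter = jitter

    def _effective_noise(self, K: np.ndarray) -> float:
        if self.noise_variance > 0:
            return float(self.noise_variance)
        scale = float(np.mean(np.diag(K))) if K.size else 1.0
        return self.jitter * max(scale, 1.0)

    def fit(self, X, y):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be nonnegative")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the sample count")
        if y.size and not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        self.X_train_ = X.copy()
        self.n_features_in_ = X.shape[1]
        self.y_train_mean_ = float(y.mean()) if (self.center_y and y.size) else 0.0
        resid = y - self.y_train_mean_
        self.y_train_ = y.copy()
        if X.shape[0] == 0:
            self.L_ = np.zeros((0, 0))
            self.alpha_ = np.zeros(0)
            self.weights_ = np.zeros(X.shape[1])
            return self
        K = self.sigma2 * (X @ X.T)
        noise = self._effective_noise(K)
        self.L_ = cholesky(K + noise * np.eye(K.shape[0]), lower=True)
        z = solve_triangular(self.L_, resid, lower=True)
        self.alpha_ = solve_triangular(self.L_.T, z, lower=False)
        self.weights_ = self.sigma2 * (X.T @ self.alpha_)
        return self

    def _check_query(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        return X

    def predict(self, X, return_std: bool = False):
        X = self._check_query(X)
        mean = X @ self.weights_ + self.y_train_mean_
        if not return_std:
            return mean
        prior_var = self.sigma2 * np.einsum("ij,ij->i", X, X)
        if self.X_train_.shape[0] == 0:
            var = prior_var
        else:
            Ks = self.sigma2 * (X @ self.X_train_.T)
            V = solve_triangular(self.L_, Ks.T, lower=True)
            var = prior_var - np.einsum("ij,ij->j", V, V)
        var = np.maximum(var, 0.0)
        return mean, np.sqrt(var)

    def predict_var(self, X) -> np.ndarray:
        _, std = self.predict(X, return_std=True)
        return std**2


class ActivityClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes active/inactive filter over one-hot encodings.

    ``fit`` accepts either boolean activity labels or raw titers, in which
    case a sequence is active when its titer exceeds ``threshold`` (mg/L).
    Per-feature class-conditional variances are floored at ``var_smoothing``
    times the largest feature variance.  Training data containing a single
    class yields a constant predictor (with a warning) rather than an error.
    """

    def __init__(
        self,
        threshold: float = 1.0,
        var_smoothing: float = 1e-9,
        cutoff: float = 0.5,
    ) -> None:
        self.threshold = threshold
        self.var_smoothing = var_smoothing
        self.cutoff = cutoff

    def _labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype == bool:
            return y
        return np.asarray(y, dtype=float) > self.threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        labels = self._labels(y)
        if X.shape[0] != labels.shape[0] or X.shape[0] == 0:
            raise ValueError("X and y must be nonempty and aligned")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        uniq = np.unique(labels)
        if len(uniq) == 1:
            warnings.warn(
                f"single-class training data (all {'active' if uniq[0] else 'inactive'}); "
                "the classifier will predict that class with probability 1"
            )
            self.constant_class_ = bool(uniq[0])
            self.nb_ = None
        else:
            self.constant_class_ = None
            self.nb_ = GaussianNB(var_smoothing=self.var_smoothing).fit(X, labels)
        self.class_prior_ = np.array(
            [np.mean(~labels), np.mean(labels)], dtype=float
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        if self.nb_ is None:
            p_active = np.full(X.shape[0], 1.0 if self.constant_class_ else 0.0)
        else:
            proba = self.nb_.predict_proba(X)
            p_active = proba[:, list(self.nb_.classes_).index(True)]
        return np.column_stack([1.0 - p_active, p_active])

    def predict_proba_active(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba_active(X) >= self.cutoff


@dataclass
class CVReport:
    """Leave-one-out scan over the kernel variance grid."""

    grid: np.ndarray
    r: np.ndarray
    mse: np.ndarray
    chosen_sigma2: float
    loo_predictions: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"sigma2": self.grid, "loo_r": self.r, "loo_mse": self.mse})


def _loo_refit(X: np.ndarray, y: np.ndarray, gp: LinearKernelGP) -> np.ndarray:
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = clone(gp).fit(X[keep], y[keep])
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def _loo_fast(X: np.ndarray, y: np.ndarray, gp: LinearKernelGP) -> np.ndarray:
    """Closed-form LOO means via the inverse-kernel identity.

    Exact for a zero prior mean; ``center_y`` must therefore be off (the
    refit route re-centers within each fold).
    """
    if gp.center_y:
        raise ValueError("the fast LOO path requires center_y=False")
    K = gp.sigma2 * (X @ X.T)
    noise = gp._effective_noise(K)
    Minv = np.linalg.inv(K + noise * np.eye(len(y)))
    alpha = Minv @ y
    return y - alpha / np.diag(Minv)


def loo_cv_scan(
    X,
    y,
    grid: Sequence[float] | None = None,
    noise_variance: float = 1.0,
    center_y: bool = True,
    method: str = "refit",
    keep_predictions: bool = False,
) -> CVReport:
    """Scan kernel variances by leave-one-out cross-validation.

    For each grid value the LOO predictions give a Pearson correlation r and
    a mean squared error; the chosen sigma2 minimizes the summed ranks of
    (-r, MSE), balancing the two objectives deterministically.  Undefined r
    (constant targets or predictions) falls back to MSE-only selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 observations")
    grid = default_sigma2_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty sigma2 grid")
    rs = np.empty(len(grid))
    mses = np.empty(len(grid))
    const_y = np.std(y) == 0
    if const_y:
        warnings.warn("constant targets: LOO correlation undefined, selecting by MSE only")
    for g, s2 in enumerate(grid):
        gp = LinearKernelGP(sigma2=s2, noise_variance=noise_variance, center_y=center_y)
        preds = _loo_refit(X, y, gp) if method == "refit" else _loo_fast(X, y, gp)
        mses[g] = float(np.mean((preds - y) ** 2))
        if const_y or np.std(preds) == 0:
            rs[g] = np.nan
        else:
            rs[g] = float(np.corrcoef(preds, y)[0, 1])
    if np.all(np.isnan(rs)):
        score = rankdata(mses, method="average")
    else:
        r_for_rank = np.where(np.isnan(rs), -np.inf, rs)
        score = rankdata(-r_for_rank, method="average") + rankdata(mses, method="average")
    chosen = int(np.argmin(score))
    report = CVReport(grid, rs, mses, float(grid[chosen]))
    if keep_predictions:
        gp = LinearKernelGP(sigma2=report.chosen_sigma2, noise_variance=noise_variance, center_y=center_y)
        report.loo_predictions = (
            _loo_refit(X, y, gp) if method == "refit" else _loo_fast(X, y, gp)
        )
    return report


def block_contributions(
    model: LinearKernelGP,
    space: Sequence[Chimera],
    parents: ParentSet,
    partition: BlockPartition,
    encoder: ChimeraEncoder,
    reference: str | None = None,
    background: Sequence[Chimera] | None = None,
    max_background: int = 5000,
    seed: int = 0,
):
    """Per-(block, parent label) effect table from a fitted model.

    For every block b and label p the entry is the mean model-predicted
    change in titer when block b of a background chimera is substituted with
    label p instead of the reference parent's label, averaged over the
    background (the whole space by default; a fixed-seed subsample of 1000
    when the space exceeds ``max_background``).  The reference column is
    zero by construction; labels donating identical block sequences get
    identical effects because their encodings coincide.
    """
    import pandas as pd

    if reference is None:
        reference = parents.names[0]
    if background is None:
        if len(space) > max_background:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(space), size=1000, replace=False)
            background = [space[i] for i in idx]
        else:
            background = list(space)
    n_blocks = partition.n_blocks
    effects = np.zeros((n_blocks, parents.n_parents))
    for b in range(n_blocks):
        ref_variants = [c.with_block(b, reference) for c in background]
        ref_pred = model.predict(encoder.encode_many(ref_variants))
        for p, label in enumerate(parents.names):
            if label == reference:
                continue
            variants = [c.with_block(b, label) for c in background]
            pred = model.predict(encoder.encode_many(variants))
            effects[b, p] = float(np.mean(pred - ref_pred))
    return pd.DataFrame(
        effects,
        index=pd.Index(range(1, n_blocks + 1), name="block"),
        columns=list(parents.names),
    )
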