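"""Linear estimation of BMC/BMD from texture features.

The estimators follow a fixed recipe: z-score each feature and the
target over the training sample (sample SD, ddof=1; zero-variance
features are dropped with a logged warning), fit in the normalized
space, and store the normalization statistics so prediction accepts raw
feature matrices and returns answers in original units (g or g/cm²).

Three fitting routes are provided:

* :class:`NormalEquationRegressor` — ordinary least squares with a bias
  term, solved in closed form via the Moore–Penrose pseudoinverse of the
  normal equations.  With more samples than parameters this is the
  plain, unregularized fit; the bias absorbs the target mean, so
  in-sample residuals average exactly zero (which is why the paired
  t-test between in-sample predictions and references is exactly 1).
* :class:`LassoRegressor` — the L1-penalized objective
  ``Σ_i (y_i − ŷ_i)² + λ Σ_j |w_j|`` (bias unpenalized), minimized by
  cyclic coordinate descent with soft thresholding.  λ = 0 recovers the
  least-squares solution; λ ≥ λ_max = max_j |2 x_jᵀ y| shrinks every
  weight to zero.
* :class:`ANNRegressor` — a small fully connected network (hidden sizes
  8, 8, 2; rectified linear units; linear scalar output) trained by
  seeded full-batch gradient descent on MSE.

All three are scikit-learn compatible (``get_params``/``set_params``,
``fit``/``predict``, trailing-underscore fitted attributes) and compose
with sklearn pipelines and model selection.  Module-level functions
(:func:`normalize`, :func:`fit_lr`, :func:`fit_lasso`,
:func:`lasso_path`, :func:`predict`) are thin wrappers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConfigurationError, ConvergenceError, UnderdeterminedError

__all__ = [
    "NormStats",
    "LinearModel",
    "LassoPath",
    "NormalEquationRegressor",
    "LassoRegressor",
    "ANNRegressor",
    "normalize",
    "fit_lr",
    "fit_lasso",
    "lasso_path",
    "default_lambda_grid",
    "lambda_max",
    "predict",
    "soft_threshold",
    "kkt_residuals",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormStats:
    """Z-score statistics of the training sample (sample SD, ddof=1).

    ``kept`` lists the column indices (into the raw feature matrix) that
    survived the zero-variance filter; means/sds are stored per kept
    column.
    """

    feature_means: np.ndarray
    feature_sds: np.ndarray
    target_mean: float
    target_sd: float
    kept: np.ndarray  # int indices into the raw columns
    n_raw_features: int

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_raw_features:
            raise ConfigurationError(
                f"expected {self.n_raw_features} feature columns, got {X.shape[1]}"
            )
        return (X[:, self.kept] - self.feature_means) / self.feature_sds

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.target_mean) / self.target_sd

    def inverse_transform_y(self, y_norm: np.ndarray) -> np.ndarray:
        return np.asarray(y_norm, dtype=float) * self.target_sd + self.target_mean

    def to_dict(self) -> dict:
        return {
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
            "kept": self.kept.tolist(),
            "n_raw_features": self.n_raw_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            target_mean=float(d["target_mean"]),
            target_sd=float(d["target_sd"]),
            kept=np.asarray(d["kept"], dtype=int),
            n_raw_features=int(d["n_raw_features"]),
        )


def _fit_norm_stats(X: np.ndarray, y: np.ndarray) -> NormStats:
    if X.shape[0] < 2:
        raise ConfigurationError("normalization needs at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    dropped = np.flatnonzero(sds == 0)
    if dropped.size:
        logger.warning(
            "dropping %d zero-variance feature column(s): %s",
            dropped.size, dropped.tolist(),
        )
    if kept.size == 0:
        raise ConfigurationError("all feature columns have zero variance")
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise ConfigurationError("target has zero variance")
    return NormStats(
        feature_means=means[kept],
        feature_sds=sds[kept],
        target_mean=float(y.mean()),
        target_sd=y_sd,
        kept=kept,
        n_raw_features=X.shape[1],
    )


def normalize(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, NormStats]:
    """Z-score features and target; returns (X_norm, y_norm, stats)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    stats = _fit_norm_stats(X, y)
    return stats.transform_X(X), stats.transform_y(y), stats


# ---------------------------------------------------------------------------
# closed-form least squares

class NormalEquationRegressor(RegressorMixin, BaseEstimator):
    """Least-squares linear regression solved via the pseudoinverse.

    Features and target are z-scored internally; the fit solves
    ``min_w ||y_norm − (w_0 + X_norm w)||²`` through the Moore–Penrose
    pseudoinverse of the bias-augmented design, which yields the
    minimum-norm solution when the design is rank deficient.

    Parameters
    ----------
    require_overdetermined : bool
        When True (default), raise :class:`UnderdeterminedError` unless
        ``n_samples >= n_features + 1`` — the regime in which the plain
        unregularized fit is justified.  When False, an underdetermined
        design falls through to the minimum-norm solution with a logged
        warning.
    """

    def __init__(self, require_overdetermined: bool = True) -> None:
        self.require_overdetermined = require_overdetermined

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NormalEquationRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if n < p + 1:
            msg = f"samples < features: {n} samples for {p} features (+ bias)"
            if self.require_overdetermined:
                raise UnderdeterminedError(msg)
            logger.warning("%s — using the minimum-norm pseudoinverse solution", msg)
        self.norm_ = _fit_norm_stats(X, y)
        Xn = self.norm_.transform_X(X)
        yn = self.norm_.transform_y(y)
        design = np.hstack([np.ones((n, 1)), Xn])
        coef = np.linalg.pinv(design) @ yn
        self.bias_ = float(coef[0])
        self.weights_ = coef[1:]
        self.lambda_ = 0.0
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X)
        Xn = self.norm_.transform_X(X)
        return self.norm_.inverse_transform_y(self.bias_ + Xn @ self.weights_)


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent

def soft_threshold(z: float, t: float) -> float:
    """The soft-thresholding operator S(z, t) = sign(z)·max(|z|−t, 0)."""
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def lambda_max(X_norm: np.ndarray, y_norm: np.ndarray) -> float:
    """Smallest λ at which the all-zero weight vector is optimal.

    For the objective ``Σ(y−ŷ)² + λΣ|w|`` with centered data this is
    ``max_j |2 x_jᵀ y|``.
    """
    return float(np.max(np.abs(2.0 * X_norm.T @ y_norm))) if X_norm.size else 0.0


class LassoRegressor(RegressorMixin, BaseEstimator):
    """L1-penalized least squares, minimized by coordinate descent.

    Objective (in the internal z-scored space, bias unpenalized)::

        L(w, b) = Σ_i (y_i − b − x_iᵀ w)² + λ Σ_j |w_j|

    Cyclic coordinate descent with the closed-form soft-threshold update
    per coordinate; convergence when the largest weight change in a full
    sweep drops below ``tol``.  λ = 0 reproduces the least-squares fit.

    Parameters
    ----------
    lam : float
        Penalty λ ≥ 0 on the sum of absolute weights.
    tol : float
        Sweep-to-sweep convergence threshold on max |Δw|.
    max_sweeps : int
        Sweep budget; exhaustion raises :class:`ConvergenceError`
        carrying the last iterate.
    warm_start : bool
        Reuse the previous ``fit``'s weights as the starting point.
    """

    def __init__(
        self,
        lam: float = 0.0,
        tol: float = 1e-8,
        max_sweeps: int = 100_000,
        warm_start: bool = False,
    ) -> None:
        self.lam = lam
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.warm_start = warm_start

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoRegressor":
        if self.lam < 0:
            raise ConfigurationError("lam must be >= 0")
        X, y = check_X_y(X, y, y_numeric=True)
        self.norm_ = _fit_norm_stats(X, y)
        Xn = self.norm_.transform_X(X)
        yn = self.norm_.transform_y(y)
        n, p = Xn.shape
        if self.warm_start and getattr(self, "weights_", None) is not None \
                and self.weights_.shape == (p,):
            w = self.weights_.copy()
        else:
            w = np.zeros(p)
        col_ssq = (Xn**2).sum(axis=0)
        bias = float(np.mean(yn - Xn @ w))
        resid = yn - bias - Xn @ w
        half_lam = self.lam / 2.0
        for sweep in range(self.max_sweeps):
            max_delta = 0.0
            for jj in range(p):
                if col_ssq[jj] == 0.0:
                    continue
                xj = Xn[:, jj]
                rho = xj @ resid + col_ssq[jj] * w[jj]
                w_new = soft_threshold(rho, half_lam) / col_ssq[jj]
                delta = w_new - w[jj]
                if delta != 0.0:
                    resid -= xj * delta
                    w[jj] = w_new
                    max_delta = max(max_delta, abs(delta))
            new_bias = bias + float(resid.mean())
            resid -= new_bias - bias
            bias = new_bias
            if max_delta < self.tol:
                break
        else:
            self.weights_ = w
            self.bias_ = bias
            self.lambda_ = float(self.lam)
            self.n_sweeps_ = self.max_sweeps
            self.n_features_in_ = p
            raise ConvergenceError(
                f"coordinate descent did not converge in {self.max_sweeps} sweeps",
                last_iterate=(w.copy(), bias),
            )
        w[np.abs(w) < self.tol] = 0.0  # weights below the convergence resolution
        self.weights_ = w
        self.bias_ = bias
        self.lambda_ = float(self.lam)
        self.n_sweeps_ = sweep + 1
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X)
        Xn = self.norm_.transform_X(X)
        return self.norm_.inverse_transform_y(self.bias_ + Xn @ self.weights_)

    @property
    def n_nonzero_(self) -> int:
        check_is_fitted(self, "weights_")
        return int(np.count_nonzero(self.weights_))


def kkt_residuals(
    X_norm: np.ndarray, y_norm: np.ndarray, w: np.ndarray, bias: float, lam: float
) -> Tuple[float, float]:
    """Stationarity diagnostics of a LASSO iterate.

    Returns ``(inactive, active)``: the largest amount by which
    ``|∇_j Σ(y−ŷ)²|`` exceeds λ on zero weights, and the largest
    deviation of ``∇_j + λ·sign(w_j)`` from zero on active weights.
    Both ≈ 0 at the optimum.
    """
    resid = y_norm - bias - X_norm @ w
    grad = -2.0 * X_norm.T @ resid
    zero = w == 0
    inactive = float(np.max(np.abs(grad[zero]) - lam, initial=0.0))
    active = float(np.max(np.abs(grad[~zero] + lam * np.sign(w[~zero])), initial=0.0))
    return inactive, active


# ---------------------------------------------------------------------------
# serializable fitted model

@dataclass(frozen=True)
class LinearModel:
    """A fitted linear model in portable, human-readable form.

    Weights and bias live in the normalized space; ``norm`` holds the
    statistics needed to predict directly on raw feature matrices.
    """

    weights: np.ndarray
    bias: float
    lam: float
    norm: NormStats
    target_name: str = "BMC"

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        Xn = self.norm.transform_X(np.asarray(X_raw, dtype=float))
        return self.norm.inverse_transform_y(self.bias + Xn @ self.weights)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "lambda": self.lam,
            "norm": self.norm.to_dict(),
            "target_name": self.target_name,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            lam=float(d["lambda"]),
            norm=NormStats.from_dict(d["norm"]),
            target_name=d["target_name"],
        )

    @classmethod
    def from_estimator(cls, est, target_name: str = "BMC") -> "LinearModel":
        return cls(
            weights=np.asarray(est.weights_, dtype=float).copy(),
            bias=float(est.bias_),
            lam=float(est.lambda_),
            norm=est.norm_,
            target_name=target_name,
        )


@dataclass(frozen=True)
class LassoPath:
    """One model per λ along an ascending grid, with sparsity counts."""

    lambdas: np.ndarray
    models: Tuple[LinearModel, ...]
    nonzero_counts: np.ndarray
    in_sample_cc: np.ndarray
    in_sample_mae: np.ndarray
    in_sample_mse: np.ndarray


# ---------------------------------------------------------------------------
# functional wrappers

def fit_lr(
    X: np.ndarray,
    y: np.ndarray,
    target_name: str = "BMC",
    require_overdetermined: bool = True,
) -> LinearModel:
    """Normal-equation least squares on raw features; see the estimator."""
    est = NormalEquationRegressor(require_overdetermined=require_overdetermined)
    est.fit(X, y)
    return LinearModel.from_estimator(est, target_name)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, target_name: str = "BMC"
) -> LinearModel:
    """L1-penalized fit at a single λ; see :class:`LassoRegressor`."""
    est = LassoRegressor(lam=lam)
    est.fit(X, y)
    return LinearModel.from_estimator(est, target_name)


def default_lambda_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """0, then 20 log-spaced values over [1e-3, λ_max], with 0.04 inserted."""
    Xn, yn, _ = normalize(X, y)
    lmax = max(lambda_max(Xn, yn), 1e-3)
    grid = np.geomspace(1e-3, lmax, 20)
    return np.unique(np.concatenate([[0.0, 0.04], grid]))


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float],
    target_name: str = "BMC",
    tol: float = 1e-8,
    max_sweeps: int = 100_000,
    on_nonconvergence: str = "raise",
) -> LassoPath:
    """Fit the λ grid (ascending, warm-started) and record path summaries.

    The λ = 0 endpoint is the unpenalized least-squares limit and is
    computed in closed form via the pseudoinverse (on rank-deficient
    designs the L1-free objective has no unique minimizer for the
    descent iteration to settle on); every λ > 0 is fitted by coordinate
    descent, warm-started from the previous solution.

    ``on_nonconvergence='warn'`` keeps the budget-exhausted iterate for
    a λ whose descent has not met ``tol`` (with a logged warning)
    instead of aborting the path — on strongly collinear feature sets
    the near-zero-λ fits approach their optimum along near-null
    directions too slowly for any practical budget.
    """
    from .evaluation import mae as _mae, mse as _mse, pearson_cc

    if on_nonconvergence not in ("raise", "warn"):
        raise ConfigurationError("on_nonconvergence must be 'raise' or 'warn'")
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0 or np.any(np.diff(lambdas) < 0):
        raise ConfigurationError("lambda grid must be non-empty and ascending")
    if lambdas[0] != 0.0:
        raise ConfigurationError("lambda grid must include 0")
    est = LassoRegressor(warm_start=True, tol=tol, max_sweeps=max_sweeps)
    models: List[LinearModel] = []
    counts, ccs, maes, mses = [], [], [], []
    y = np.asarray(y, dtype=float)
    for lam in lambdas:
        if lam == 0.0:
            ols = NormalEquationRegressor(require_overdetermined=False)
            ols.fit(X, y)
            model = LinearModel.from_estimator(ols, target_name)
            # seed the warm start for the first penalized fit
            est.weights_ = model.weights.copy()
            est.bias_ = model.bias
        else:
            est.set_params(lam=float(lam))
            try:
                est.fit(X, y)
            except ConvergenceError as exc:
                if on_nonconvergence == "raise":
                    raise
                logger.warning("λ=%g: %s — keeping last iterate", lam, exc)
            model = LinearModel.from_estimator(est, target_name)
        pred = model.predict(X)
        models.append(model)
        counts.append(model.n_nonzero)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # (near-)constant preds at high λ
            try:
                r = pearson_cc(pred, y)
            except ConfigurationError:
                r = 0.0
        ccs.append(r if np.isfinite(r) else 0.0)
        maes.append(_mae(pred, y))
        mses.append(_mse(pred, y))
    return LassoPath(
        lambdas=lambdas,
        models=tuple(models),
        nonzero_counts=np.asarray(counts),
        in_sample_cc=np.asarray(ccs),
        in_sample_mae=np.asarray(maes),
        in_sample_mse=np.asarray(mses),
    )


def predict(model: LinearModel, X_raw: np.ndarray) -> np.ndarray:
    """Apply a fitted model to raw features; output in original units."""
    return model.predict(X_raw)


# ---------------------------------------------------------------------------
# optional small neural network

class ANNRegressor(RegressorMixin, BaseEstimator):
    """Fully connected network with hidden layers (8, 8, 2) and ReLU.

    Trained by seeded full-batch gradient descent on MSE in the z-scored
    space, with a linear scalar output.  Deterministic given ``seed``;
    ``epochs=0`` returns the freshly initialized network (whose training
    MSE is ≈ var(y_norm) = 1).  Divergence (MSE above 10× the initial
    value) raises :class:`ConvergenceError`.
    """

    HIDDEN: Tuple[int, ...] = (8, 8, 2)

    def __init__(
        self, lr: float = 0.005, epochs: int = 2000, seed: int = 0
    ) -> None:
        self.lr = lr
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ANNRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        self.norm_ = _fit_norm_stats(X, y)
        Xn = self.norm_.transform_X(X)
        yn = self.norm_.transform_y(y)
        rng = np.random.default_rng(self.seed)
        sizes = [Xn.shape[1], *self.HIDDEN, 1]
        Ws = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        bs = [np.zeros(s) for s in sizes[1:]]
        n = Xn.shape[0]
        self.loss_history_ = []
        initial_mse = None
        for _ in range(self.epochs):
            acts = [Xn]
            for Wl, bl in zip(Ws[:-1], bs[:-1]):
                acts.append(np.maximum(acts[-1] @ Wl + bl, 0.0))
            out = (acts[-1] @ Ws[-1] + bs[-1]).ravel()
            err = out - yn
            mse_now = float((err**2).mean())
            self.loss_history_.append(mse_now)
            if initial_mse is None:
                initial_mse = mse_now
            elif mse_now > 10.0 * initial_mse:
                raise ConvergenceError(f"training diverged: MSE {mse_now:.3g}")
            delta = (2.0 / n) * err[:, None]
            for layer in range(len(Ws) - 1, -1, -1):
                gW = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ Ws[layer].T) * (acts[layer] > 0)
                Ws[layer] = Ws[layer] - self.lr * gW
                bs[layer] = bs[layer] - self.lr * gb
        self.weights_list_ = Ws
        self.biases_list_ = bs
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_list_")
        X = check_array(X)
        a = self.norm_.transform_X(X)
        for Wl, bl in zip(self.weights_list_[:-1], self.biases_list_[:-1]):
            a = np.maximum(a @ Wl + bl, 0.0)
        out = (a @ self.weights_list_[-1] + self.biases_list_[-1]).ravel()
        return self.norm_.inverse_transform_y(out)
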