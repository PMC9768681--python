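"""Elastic-net penalized logistic regression base learner.

The workhorse of every per-omics model: an L1/L2-penalized logistic fit
along a decreasing regularization path, with the penalty strength lambda
chosen by an internal cross-validation on deviance, an optional
refit-on-support step (unpenalized maximum likelihood restricted to the
selected features, undoing L1 shrinkage), and bookkeeping of which features
enter the support.  The mixing parameter alpha defaults to 0.9 — a nearly
lasso-like penalty that still spreads weight over groups of correlated
features.

The penalized objective is

    (1/N) sum_i [log(1 + e^{eta_i}) - y_i eta_i]
        + lambda (alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2),

eta_i = beta0 + x_i' beta, with features standardized internally using the
training data only.  Coefficients are reported on the original feature
scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._glmnet import binomial_deviance_path, cv_en_deviance, en_logistic_path

__all__ = [
    "ENConfig",
    "ENFit",
    "fit_en",
    "refit_on_support",
    "predict_score",
    "make_lambda_grid",
    "stratified_folds",
]

#: L2 strength used when the unpenalized refit hits complete separation
SEPARATION_RIDGE_LAMBDA = 1e-3


@dataclass(frozen=True)
class ENConfig:
    """Tuning and solver controls for one elastic-net fit."""

    alpha: float = 0.9
    lambda_grid: tuple[float, ...] | str = "auto"
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # glmnet rule: 1e-4 if n > p else 1e-2
    inner_folds: int = 10
    lambda_rule: str = "min"  # or "1se"
    standardize: bool = True
    refit: bool = False
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-7
    dfmax: int | None = None  # glmnet-style cap on support size along the path

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError(f"lambda_rule must be 'min' or '1se', got {self.lambda_rule}")
        if self.inner_folds < 3:
            raise ValueError("inner_folds must be >= 3")
        if not isinstance(self.lambda_grid, str):
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or len(grid) < 1 or np.any(grid <= 0):
                raise ValueError("lambda_grid must be positive reals")
            if np.any(np.diff(grid) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")


@dataclass
class ENFit:
    """A fitted sparse logistic model over named features."""

    feature_ids: list[str]
    beta: np.ndarray  # original-scale coefficients, len == n features
    intercept: float
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    config: ENConfig
    n_obs: int
    refitted: bool = False

    @property
    def support(self) -> list[str]:
        return [f for f, b in zip(self.feature_ids, self.beta) if b != 0.0]

    @property
    def support_mask(self) -> np.ndarray:
        return self.beta != 0.0

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.beta

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "feature_ids": self.feature_ids,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "lambda_selected": self.lambda_selected,
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_deviance_mean": self.cv_deviance_mean.tolist(),
            "cv_deviance_se": self.cv_deviance_se.tolist(),
            "config": _config_to_dict(self.config),
            "n_obs": self.n_obs,
            "refitted": self.refitted,
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ENFit":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        cfg = dict(obj["config"])
        if isinstance(cfg.get("lambda_grid"), list):
            cfg["lambda_grid"] = tuple(cfg["lambda_grid"])
        return cls(
            feature_ids=obj["feature_ids"],
            beta=np.asarray(obj["beta"], dtype=float),
            intercept=float(obj["intercept"]),
            lambda_selected=float(obj["lambda_selected"]),
            lambda_grid=np.asarray(obj["lambda_grid"], dtype=float),
            cv_deviance_mean=np.asarray(obj["cv_deviance_mean"], dtype=float),
            cv_deviance_se=np.asarray(obj["cv_deviance_se"], dtype=float),
            config=ENConfig(**cfg),
            n_obs=int(obj["n_obs"]),
            refitted=bool(obj["refitted"]),
        )


def _config_to_dict(config: ENConfig) -> dict:
    d = asdict(config)
    if not isinstance(d["lambda_grid"], str):
        d["lambda_grid"] = list(d["lambda_grid"])
    return d


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, glmnet convention
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, config: ENConfig
) -> np.ndarray:
    """Decreasing log-spaced grid from the data's lambda_max.

    lambda_max is the smallest lambda with an all-zero solution:
    max_j |<x_j, y - ybar>| / (N * alpha) on standardized columns.
    """
    if not isinstance(config.lambda_grid, str):
        return np.asarray(config.lambda_grid, dtype=float)
    Xs, _, _ = _standardize(X) if config.standardize else (X, None, None)
    n, p = X.shape
    alpha = max(config.alpha, 1e-3)  # ridge limit: finite grid anchor
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * alpha)
    lam_max = max(lam_max, 1e-10) * (1 + 1e-9)  # head is exactly all-zero
    ratio = config.lambda_min_ratio
    if ratio is None:
        ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lam_max, lam_max * ratio, config.n_lambda)


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic class-stratified fold ids in {0..k-1}."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _dfmax(config: ENConfig) -> int:
    return -1 if config.dfmax is None else int(config.dfmax)


def _intercept_only_fit(feature_ids, y, config, grid) -> ENFit:
    ybar = float(np.clip(np.mean(y), 1e-5, 1 - 1e-5))
    return ENFit(
        feature_ids=list(feature_ids),
        beta=np.zeros(len(feature_ids)),
        intercept=float(np.log(ybar / (1 - ybar))),
        lambda_selected=float(grid[0]) if len(grid) else np.inf,
        lambda_grid=np.asarray(grid, dtype=float),
        cv_deviance_mean=np.full(len(grid), np.nan),
        cv_deviance_se=np.full(len(grid), np.nan),
        config=config,
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def fit_en(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: ENConfig = ENConfig(),
    feature_ids: list[str] | None = None,
    groups: np.ndarray | None = None,
) -> ENFit:
    """Fit the elastic-net logistic path and select lambda by inner CV.

    Parameters
    ----------
    X : samples x features design (DataFrame columns name the features).
    y : binary labels in {0, 1}.
    config : ENConfig; ``config.seed`` fixes the inner fold assignment.
    groups : optional per-sample group labels (e.g. patient ids); when
        given, inner folds are assigned at group level so longitudinal
        samples of one patient never straddle an inner train/validation
        split.

    Returns an :class:`ENFit` with coefficients on the original scale.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute or drop first")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y has a single class; cannot fit a classifier")
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    grid = make_lambda_grid(X, y, config)
    k = config.inner_folds
    n_units = n if groups is None else len(np.unique(groups))
    if n_units < k:
        warnings.warn(
            f"inner_folds reduced from {k} to {n_units} (too few units)",
            stacklevel=2,
        )
        k = max(n_units, 2)

    if groups is None:
        fold = stratified_folds(y.astype(int), k, config.seed)
    else:
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        gy = y[first].astype(int)
        gfold = stratified_folds(gy, k, config.seed)
        gmap = {g: f for g, f in zip(uniq, gfold)}
        fold = np.array([gmap[g] for g in groups])

    X = np.ascontiguousarray(X)
    if config.standardize:
        dev = cv_en_deviance(
            X, y, fold, k, config.alpha, grid,
            config.max_iter, config.max_iter, config.tol, _dfmax(config),
        )
    else:
        dev = np.full((k, len(grid)), np.nan)
        for f in range(k):
            tr = fold != f
            va = ~tr
            ytr = y[tr]
            if len(np.unique(ytr)) < 2 or va.sum() == 0:
                continue
            B, b0s = en_logistic_path(
                np.ascontiguousarray(X[tr].T), ytr, config.alpha, grid,
                config.max_iter, config.max_iter, config.tol, _dfmax(config),
            )
            dev[f] = binomial_deviance_path(
                np.ascontiguousarray(X[va]), y[va], B, b0s)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_mean = np.nanmean(dev, axis=0)
        used = np.sum(~np.isnan(dev), axis=0)
        cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.maximum(used, 1))
    if np.all(np.isnan(cv_mean)):
        warnings.warn("all inner folds degenerate; returning intercept-only model",
                      stacklevel=2)
        return _intercept_only_fit(feature_ids, y, config, grid)

    i_min = int(np.nanargmin(cv_mean))
    if config.lambda_rule == "1se":
        thresh = cv_mean[i_min] + cv_se[i_min]
        ok = np.flatnonzero(cv_mean <= thresh)
        i_sel = int(ok[0]) if len(ok) else i_min  # largest lambda within 1 SE
    else:
        i_sel = i_min

    # final path fit on all data
    if config.standardize:
        Xs, mean, sd = _standardize(X)
    else:
        Xs, mean, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    B, b0s = en_logistic_path(
        np.ascontiguousarray(Xs.T), y, config.alpha, grid,
        config.max_iter, config.max_iter, config.tol, _dfmax(config),
    )
    beta_std = B[i_sel]
    beta = beta_std / sd
    intercept = float(b0s[i_sel] - np.dot(beta_std, mean / sd))

    return ENFit(
        feature_ids=list(feature_ids),
        beta=beta,
        intercept=intercept,
        lambda_selected=float(grid[i_sel]),
        lambda_grid=grid,
        cv_deviance_mean=cv_mean,
        cv_deviance_se=cv_se,
        config=config,
        n_obs=n,
    )


def refit_on_support(fit: ENFit, X: np.ndarray | pd.DataFrame, y: np.ndarray) -> ENFit:
    """Unpenalized maximum-likelihood logistic refit on the selected support.

    The support never changes; coefficients outside it stay zero.  An empty
    support yields the intercept-only model (predicted probability = class
    prevalence).  Complete separation triggers a fallback refit with a small
    L2 penalty (:data:`SEPARATION_RIDGE_LAMBDA`) and a warning.
    """
    from sklearn.linear_model import LogisticRegression

    if isinstance(X, pd.DataFrame):
        X = X[fit.feature_ids].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = fit.support_mask
    n = len(y)
    new_beta = np.zeros_like(fit.beta)
    if not mask.any():
        ybar = float(np.clip(y.mean(), 1e-5, 1 - 1e-5))
        out = replace_fit(fit, new_beta, float(np.log(ybar / (1 - ybar))))
        return out

    Xs = X[:, mask]
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    prob = clf.predict_proba(Xs)[:, 1]
    separated = np.all(np.abs(y - prob) < 1e-5)
    if separated:
        warnings.warn(
            "complete separation in refit; falling back to a small ridge "
            f"penalty (lambda={SEPARATION_RIDGE_LAMBDA})",
            stacklevel=2,
        )
        clf = LogisticRegression(
            C=1.0 / (n * SEPARATION_RIDGE_LAMBDA),
            solver="lbfgs", max_iter=5000, tol=1e-10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
    new_beta[mask] = clf.coef_[0]
    return replace_fit(fit, new_beta, float(clf.intercept_[0]))


def replace_fit(fit: ENFit, beta: np.ndarray, intercept: float) -> ENFit:
    return ENFit(
        feature_ids=fit.feature_ids,
        beta=beta,
        intercept=intercept,
        lambda_selected=fit.lambda_selected,
        lambda_grid=fit.lambda_grid,
        cv_deviance_mean=fit.cv_deviance_mean,
        cv_deviance_se=fit.cv_deviance_se,
        config=fit.config,
        n_obs=fit.n_obs,
        refitted=True,
    )


def predict_score(fit: ENFit, X_new: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predicted probabilities logistic(beta0 + x' beta) for new samples.

    A DataFrame is aligned by feature id; every support feature must be
    present.  An ndarray must already have columns in training order.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in fit.support if f not in X_new.columns]
        if missing:
            raise KeyError(f"missing support feature(s): {missing}")
        cols = [f for f in fit.feature_ids if f in X_new.columns]
        idx = [fit.feature_ids.index(c) for c in cols]
        eta = fit.intercept + X_new[cols].to_numpy(dtype=float) @ fit.beta[idx]
    else:
        X_new = np.asarray(X_new, dtype=float)
        eta = fit.linear_predictor(X_new)
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500.0, 500.0)))
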