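"""Elastic-net prediction of mean risk ratings with nested, repeated
cross-validation.

Evaluation protocol
-------------------
Nested 10-fold cross-validation repeated 10 times with a fresh shuffle per
repeat.  Hyperparameters — the penalty magnitude ``alpha`` over eight
log-spaced values in [1e-5, 100] and the L1/L2 mixing ratio over eleven even
steps in [0, 1] (an 88-point grid) — are selected on each outer training set
by inner k-fold CV (scikit-learn's ``ElasticNetCV``); generalization is the
coefficient of determination R^2 on the held-out outer fold.  Predictors are
*not* standardized by default: standardization redistributes variance evenly
across dimensions, which hurts SVD-derived embeddings whose leading
dimensions deliberately carry more variance.

Confidence intervals for comparing several models evaluated on the same
fold partitioning use the within-design adjustment: fold effects are removed
by centering each fold's scores across models, the remaining spread is
inflated by sqrt(m / (m - 1)) for m models, and a normal-theory 95% interval
is taken over the adjusted per-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .ensemble import EnsembleMatrix

__all__ = [
    "CvConfig",
    "CvResult",
    "PredictionModel",
    "OofPredictions",
    "nested_cv_evaluate",
    "fit_final",
    "oof_predictions",
    "adjusted_ci",
]

_SEED_MOD = 2**31 - 1


@dataclass
class CvConfig:
    """Cross-validation and elastic-net configuration.

    ``l1_ratio_grid`` defaults to 11 even steps on [0, 1] and ``alpha_grid``
    to 8 exponential steps on [1e-5, 100] (i.e. 10**linspace(-5, 2, 8)).
    """

    outer_folds: int = 10
    repeats: int = 10
    inner_folds: int = 10
    seed: int = 0
    standardize: bool = False
    l1_ratio_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 11)
    )
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-5.0, 2.0, 8)
    )
    max_iter: int = 1000

    def __post_init__(self) -> None:
        self.l1_ratio_grid = np.asarray(self.l1_ratio_grid, dtype=float)
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CvResult:
    """All outer-fold R^2 scores (folds x repeats of them), their grand mean,
    a 95% CI on the grand mean, and the hyperparameters chosen per fold."""

    per_fold_r2: np.ndarray
    grand_mean_r2: float
    ci_low: float
    ci_high: float
    chosen_hyperparams: list[dict]


@dataclass
class PredictionModel:
    """A fitted elastic net: coefficients, intercept, selected
    hyperparameters, and (optionally) the named feature spans of its design
    matrix."""

    coefficients: np.ndarray
    intercept: float
    alpha: float
    l1_ratio: float
    feature_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X @ self.coefficients + self.intercept


@dataclass
class OofPredictions:
    """Out-of-fold predictions: one prediction per term per repeat, their
    mean, and residuals = observed - mean prediction."""

    predictions: np.ndarray  # (n_terms, repeats)
    mean_prediction: np.ndarray
    residuals: np.ndarray


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, EnsembleMatrix):
        return np.asarray(X.matrix, dtype=float)
    return np.asarray(X, dtype=float)


def _check_xy(X: np.ndarray, y: np.ndarray, config: CvConfig) -> None:
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; R^2 is undefined")
    if X.shape[0] < 2 * config.outer_folds:
        raise ValueError("need at least 2 rows per outer fold")


def _repeat_seeds(config: CvConfig) -> np.ndarray:
    """Deterministic per-repeat shuffling seeds spawned from the master
    seed."""
    rng = np.random.default_rng(config.seed)
    return rng.integers(0, _SEED_MOD, size=config.repeats)


def _fit_enet_cv(
    X_train: np.ndarray, y_train: np.ndarray, config: CvConfig, inner_seed: int
):
    """Inner-CV hyperparameter search + refit on the full training set."""
    if config.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
    else:
        scaler = None
    model = ElasticNetCV(
        l1_ratio=config.l1_ratio_grid,
        alphas=config.alpha_grid,
        cv=KFold(config.inner_folds, shuffle=True, random_state=inner_seed % _SEED_MOD),
        max_iter=config.max_iter,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*l1_ratio.*")
        model.fit(X_train, y_train)
    return model, scaler


def _predict(model, scaler, X: np.ndarray) -> np.ndarray:
    if scaler is not None:
        X = scaler.transform(X)
    return model.predict(X)


def nested_cv_evaluate(X, y, config: CvConfig | None = None) -> CvResult:
    """Evaluate out-of-sample R^2 by nested, repeated k-fold CV.

    Each repeat reshuffles the rows (repeat-specific seed derived from the
    master seed), splits them into ``outer_folds`` folds, selects
    hyperparameters per outer training set by inner CV over the full grid,
    and scores R^2 on the held-out fold.  All ``outer_folds * repeats``
    scores are retained.
    """
    config = config or CvConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, config)
    scores: list[float] = []
    chosen: list[dict] = []
    for rep, rep_seed in enumerate(_repeat_seeds(config)):
        outer = KFold(config.outer_folds, shuffle=True, random_state=int(rep_seed))
        for fold, (tr, te) in enumerate(outer.split(X)):
            model, scaler = _fit_enet_cv(X[tr], y[tr], config, int(rep_seed) + fold)
            r2 = r2_score(y[te], _predict(model, scaler, X[te]))
            scores.append(float(r2))
            chosen.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "alpha": float(model.alpha_),
                    "l1_ratio": float(model.l1_ratio_),
                }
            )
    per_fold = np.array(scores)
    grand = float(per_fold.mean())
    half = 1.959963984540054 * per_fold.std(ddof=1) / np.sqrt(per_fold.size)
    return CvResult(
        per_fold_r2=per_fold,
        grand_mean_r2=grand,
        ci_low=grand - half,
        ci_high=grand + half,
        chosen_hyperparams=chosen,
    )


def fit_final(X, y, config: CvConfig | None = None) -> PredictionModel:
    """Select hyperparameters by (non-nested) CV on all rows, then refit on
    all rows.  Used to generalize predictions beyond the rated vocabulary."""
    config = config or CvConfig()
    spans = X.block_spans if isinstance(X, EnsembleMatrix) else {}
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; R^2 is undefined")
    model, scaler = _fit_enet_cv(X, y, config, config.seed)
    return PredictionModel(
        coefficients=np.asarray(model.coef_, dtype=float),
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        l1_ratio=float(model.l1_ratio_),
        feature_spans=dict(spans),
        scaler_mean=None if scaler is None else scaler.mean_.copy(),
        scaler_scale=None if scaler is None else scaler.scale_.copy(),
    )


def oof_predictions(X, y, config: CvConfig | None = None) -> OofPredictions:
    """Out-of-fold predictions under the same repeated outer-fold protocol.

    Every term lands in exactly one test fold per repeat, so each term
    receives exactly ``repeats`` held-out predictions.  The residual is
    observed minus the mean out-of-fold prediction, which avoids the
    optimistic shrinkage of in-sample residuals.
    """
    config = config or CvConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, config)
    preds = np.empty((X.shape[0], config.repeats))
    for rep, rep_seed in enumerate(_repeat_seeds(config)):
        outer = KFold(config.outer_folds, shuffle=True, random_state=int(rep_seed))
        for fold, (tr, te) in enumerate(outer.split(X)):
            model, scaler = _fit_enet_cv(X[tr], y[tr], config, int(rep_seed) + fold)
            preds[te, rep] = _predict(model, scaler, X[te])
    mean_pred = preds.mean(axis=1)
    return OofPredictions(
        predictions=preds, mean_prediction=mean_pred, residuals=y - mean_pred
    )


def adjusted_ci(
    fold_scores_by_model: np.ndarray, level: float = 0.95
) -> list[tuple[float, float]]:
    """Within-design ("adjusted") confidence intervals for several models
    scored on the same fold partitioning.

    Parameters
    ----------
    fold_scores_by_model
        (n_folds, n_models) array of per-fold scores; column m holds model
        m's scores on the shared folds.

    Notes
    -----
    Each fold's scores are centered across models (removing the shared fold
    effect), the centered spread is inflated by sqrt(m / (m - 1)), and a
    normal-theory interval is computed per model.  Column means are
    unaffected by the centering, so the interval is centered on the raw mean
    score.  With a single model the fold effect cannot be separated and the
    unadjusted interval is returned with a warning.
    """
    scores = np.asarray(fold_scores_by_model, dtype=float)
    if scores.ndim != 2:
        raise ValueError("expected a (n_folds, n_models) array")
    n_folds, n_models = scores.shape
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    if n_models == 1:
        warnings.warn(
            "single model supplied; returning an unadjusted interval",
            stacklevel=2,
        )
        mean = scores.mean()
        half = z * scores.std(ddof=1) / np.sqrt(n_folds)
        return [(float(mean - half), float(mean + half))]
    fold_effect = scores.mean(axis=1, keepdims=True)
    adjusted = scores - fold_effect + scores.mean()
    correction = np.sqrt(n_models / (n_models - 1))
    out: list[tuple[float, float]] = []
    for m in range(n_models):
        mean = adjusted[:, m].mean()
        half = z * correction * adjusted[:, m].std(ddof=1) / np.sqrt(n_folds)
        out.append((float(mean - half), float(mean + half)))
    return out
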