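"""Sparse linear ctDNA-burden model with Lasso stability selection.

Feature selection repeatedly (default 1000x) draws half of the training
samples, standardizes features within the draw, fits an L1-regularized path
with the strength chosen by 10-fold cross-validation (minimum mean CV
error), and records which features carry nonzero coefficients.  Features
selected in at least a frequency threshold (default 0.99) of repeats form
the final feature set; the deployed model is an L1 fit on the full training
set restricted to those features.  Predictions are linear values clamped to
[0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .coverage import FeatureMatrix

logger = logging.getLogger(__name__)

_TRANSFORMS = ("identity", "log", "logit")
_EPS = 1e-4


def _forward(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        return np.log(y + _EPS)
    if transform == "logit":
        yc = np.clip(y, _EPS, 1 - _EPS)
        return np.log(yc / (1 - yc))
    raise ValueError(f"unknown transform {transform!r}")


def _inverse(z: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return z
    if transform == "log":
        return np.exp(z) - _EPS
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown transform {transform!r}")


def _check_complete(values: pd.DataFrame) -> None:
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing cells among candidate features: {bad[:5]}...")


def _lasso_cv(X: np.ndarray, y: np.ndarray, folds: int, seed: int,
              n_alphas: int) -> LassoCV:
    """LassoCV on standardized features, minimum-mean-CV-error strength rule.

    The path floor follows glmnet's lambda.min.ratio convention: 0.01 of the
    largest strength when there are fewer samples than features, 1e-3
    otherwise.  The floor matters: with many correlated informative
    features the CV curve is nearly flat, and an unbounded path drifts into
    dense, unstable fits.
    """
    eps = 0.01 if X.shape[0] < X.shape[1] else 1e-3
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(
        alphas=n_alphas,  # int -> automatic log-spaced path of this length
        eps=eps,
        cv=cv,
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd


@dataclass
class StabilitySelection:
    frequency: pd.Series  # per candidate feature, in [0, 1]
    selected: list[str]
    n_repeats: int
    n_skipped: int
    freq_threshold: float

    def ranking(self, coef_magnitude: Mapping[str, float] | None = None) -> list[str]:
        """Features by descending frequency, then |coefficient|, then id."""
        mags = pd.Series(coef_magnitude or {}, dtype=float).reindex(self.frequency.index).fillna(0.0)
        order = sorted(
            self.frequency.index,
            key=lambda f: (-self.frequency[f], -mags[f], f),
        )
        return order


def stability_select(
    matrix: FeatureMatrix,
    n_repeats: int = 1000,
    subsample: float = 0.5,
    folds: int = 10,
    freq_threshold: float = 0.99,
    seed: int | None = None,
    n_alphas: int = 50,
) -> StabilitySelection:
    """Subsample-and-refit L1 selection frequencies over the candidate features.

    Each repeat draws ceil(subsample * n) samples without replacement,
    standardizes features on the draw, fits an L1 path with ``folds``-fold
    CV, and records the features with nonzero coefficients.  Repeats whose
    response is constant are skipped and logged; more than 5% skipped is an
    error.
    """
    if matrix.response is None:
        raise ValueError("training requires a response")
    _check_complete(matrix.values)
    n = len(matrix.values)
    if n < 2 * folds:
        raise ValueError(f"need >= {2 * folds} samples for {folds}-fold selection")
    X_all = matrix.values.to_numpy(dtype=float)
    y_all = matrix.response.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_draw = int(np.ceil(subsample * n))
    counts = np.zeros(X_all.shape[1], dtype=np.int64)
    coef_mag = np.zeros(X_all.shape[1], dtype=float)
    skipped = 0
    for rep in range(n_repeats):
        idx = rng.choice(n, size=n_draw, replace=False)
        y = y_all[idx]
        if np.all(y == y[0]):
            skipped += 1
            logger.warning("repeat %d skipped: constant response in draw", rep)
            continue
        Xs, _, sd = _standardize(X_all[idx])
        fold_seed = int(rng.integers(0, 2**31 - 1))
        model = _lasso_cv(Xs, y, folds, fold_seed, n_alphas)
        nz = (model.coef_ != 0) & (sd > 0)
        counts += nz
        coef_mag += np.abs(model.coef_)
    n_eff = n_repeats - skipped
    if skipped > 0.05 * n_repeats:
        raise ValueError(f"{skipped}/{n_repeats} repeats skipped (constant response)")
    freq = pd.Series(counts / n_eff, index=matrix.values.columns)
    selected = list(freq.index[freq >= freq_threshold])
    return StabilitySelection(freq, selected, n_eff, skipped, freq_threshold)


@dataclass
class TrainedModel:
    """Selected NDR features, original-scale coefficients, and fit metadata."""

    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    selection_frequency: dict[str, float] = field(default_factory=dict)
    response_transform: str = "identity"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_ids) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")

    def linear_values(self, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
        values = features.values if isinstance(features, FeatureMatrix) else features
        missing = [f for f in self.feature_ids if f not in values.columns]
        if missing:
            raise ValueError(f"model features absent from matrix: {missing}")
        X = values[self.feature_ids]
        bad = X.isna().any(axis=1)
        if bad.any():
            which = {
                sid: X.columns[X.loc[sid].isna()].tolist()
                for sid in X.index[bad][:5]
            }
            raise ValueError(f"missing model feature values for samples: {which}")
        return pd.Series(X.to_numpy() @ self.coefficients + self.intercept, index=values.index)

    def to_json(self, path: str) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "selection_frequency": self.selection_frequency,
            "response_transform": self.response_transform,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_ids=d["feature_ids"],
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=d["intercept"],
            lambda_=d["lambda"],
            selection_frequency=d.get("selection_frequency", {}),
            response_transform=d.get("response_transform", "identity"),
            metadata=d.get("metadata", {}),
        )


def fit(
    matrix: FeatureMatrix,
    folds: int = 10,
    seed: int | None = None,
    n_alphas: int = 100,
    response_transform: str = "identity",
    selection: StabilitySelection | None = None,
) -> TrainedModel:
    """Final L1 fit on the full training set restricted to the given matrix.

    Features are standardized inside the fit; coefficients are reported on
    the original scale.  The regularization strength is chosen by
    ``folds``-fold CV (minimum mean CV error).
    """
    if matrix.response is None:
        raise ValueError("training requires a response")
    if matrix.values.shape[1] == 0:
        raise ValueError("empty feature set: lower freq_threshold to select features")
    if response_transform not in _TRANSFORMS:
        raise ValueError(f"unknown response transform {response_transform!r}")
    _check_complete(matrix.values)
    if len(matrix.values) < folds:
        raise ValueError("need at least `folds` samples")
    X = matrix.values.to_numpy(dtype=float)
    y = _forward(matrix.response.to_numpy(dtype=float), response_transform)
    if np.all(y == y[0]):
        # degenerate: constant response -> intercept-only model
        return TrainedModel(
            feature_ids=list(matrix.values.columns),
            coefficients=np.zeros(X.shape[1]),
            intercept=float(matrix.response.mean()),
            lambda_=float("inf"),
            response_transform="identity",
            metadata={"degenerate": "constant response"},
        )
    Xs, mu, sd = _standardize(X)
    model = _lasso_cv(Xs, y, folds, seed if seed is not None else 0, n_alphas)
    sd_safe = np.where(sd > 0, sd, 1.0)
    coef = model.coef_ / sd_safe
    intercept = float(model.intercept_ - np.sum(coef * mu))
    freq = dict(selection.frequency[matrix.values.columns]) if selection is not None else {}
    return TrainedModel(
        feature_ids=list(matrix.values.columns),
        coefficients=coef,
        intercept=intercept,
        lambda_=float(model.alpha_),
        selection_frequency={k: float(v) for k, v in freq.items()},
        response_transform=response_transform,
        metadata={"folds": folds, "seed": seed, "n_alphas": n_alphas,
                  "n_training_samples": int(len(matrix.values)),
                  "cv_rule": "min-mean-cv-error"},
    )


def predict(model: TrainedModel, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample predicted ctDNA fraction, clamped to [0, 1]."""
    z = model.linear_values(features)
    raw = _inverse(z.to_numpy(), model.response_transform)
    return pd.Series(np.clip(raw, 0.0, 1.0), index=z.index, name="predicted_fraction")


@dataclass
class EvaluationReport:
    mae: float
    pearson_r: float
    spearman_rho: float
    residuals: pd.Series

    @property
    def mae_percent(self) -> float:
        return 100.0 * self.mae


def evaluate(pred: pd.Series | Sequence[float], truth: pd.Series | Sequence[float]) -> EvaluationReport:
    """MAE (fraction units) plus Pearson/Spearman on the raw pairs."""
    p = pd.Series(pred, dtype=float)
    t = pd.Series(truth, dtype=float)
    if isinstance(pred, pd.Series) and isinstance(truth, pd.Series):
        t = t.reindex(p.index)
    if len(p) != len(t) or len(p) < 3:
        raise ValueError("need equal-length prediction/truth with >= 3 pairs")
    resid = pd.Series(p.to_numpy() - t.to_numpy(), index=p.index)
    mae = float(np.abs(resid).mean())
    if p.std() == 0 or t.std() == 0:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(p.to_numpy(), t.to_numpy()).statistic)
        rho = float(stats.spearmanr(p.to_numpy(), t.to_numpy()).statistic)
    return EvaluationReport(mae, r, rho, resid)


@dataclass
class DetectionReport:
    threshold: float
    sensitivity: float
    specificity: float
    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int


def detection_metrics(
    pred_positives: Sequence[float],
    pred_negatives: Sequence[float],
    threshold: float,
) -> DetectionReport:
    """Detected iff predicted fraction >= threshold.

    Positives must be samples whose expected fraction is at or above the
    threshold (caller's responsibility).  An empty class leaves the
    corresponding metric NaN.
    """
    pos = np.asarray(pred_positives, dtype=float)
    neg = np.asarray(pred_negatives, dtype=float)
    tp = int(np.sum(pos >= threshold))
    fn = len(pos) - tp
    tn = int(np.sum(neg < threshold))
    fp = len(neg) - tn
    sens = tp / len(pos) if len(pos) else float("nan")
    spec = tn / len(neg) if len(neg) else float("nan")
    return DetectionReport(threshold, sens, spec, tp, fn, tn, fp)


def complexity_sweep(
    train: FeatureMatrix,
    test: FeatureMatrix,
    ranking: Sequence[str],
    k_values: Sequence[int],
    folds: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Train/test MAE of models restricted to the top-k ranked features.

    k = 0 is the intercept-only baseline (predicts the training mean).
    k values beyond the ranking length are skipped with a warning.
    """
    if train.response is None or test.response is None:
        raise ValueError("both matrices need responses")
    rows = []
    for k in k_values:
        if k > len(ranking):
            logger.warning("k=%d exceeds candidate count %d: skipped", k, len(ranking))
            continue
        if k == 0:
            const = float(train.response.mean())
            tr_mae = float(np.abs(train.response - const).mean())
            te_mae = float(np.abs(test.response - const).mean())
            rows.append({"k": 0, "train_mae": tr_mae, "test_mae": te_mae})
            continue
        feats = list(ranking[:k])
        model = fit(train.restrict(feats), folds=folds, seed=seed)
        tr = evaluate(predict(model, train), train.response)
        te = evaluate(predict(model, test), test.response)
        rows.append({"k": k, "train_mae": tr.mae, "test_mae": te.mae})
    return pd.DataFrame(rows)


def consensus_purity(estimates: Sequence[float]) -> float:
    """Median of tumor-purity estimates (mean of the central pair when even)."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    if np.any((est < 0) | (est > 1)):
        raise ValueError("estimates must lie in [0, 1]")
    return float(np.median(est))
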