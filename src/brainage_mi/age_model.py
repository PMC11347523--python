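"""Kernel-regression brain-age model with age-bias correction.

The model is epsilon-insensitive support vector regression (RBF kernel)
on z-scored regional morphometry features, with the regularization
constant C chosen by exhaustive grid search under 10-fold
cross-validation scored by negative mean absolute error, and the final
model refit on the full training set.

Brain-age models systematically over-predict young subjects and
under-predict old ones (regression toward the mean). The standard
correction fits predicted ~ alpha * age + beta on the training set and
adjusts each prediction by the residual of that line at the subject's
chronological age:

    corrected_i = predicted_i + [age_i - (alpha * age_i + beta)]

By default alpha and beta are fitted on out-of-fold training
predictions, which avoids the slope being dragged toward 1 by in-sample
overfit; an in-sample mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict
from sklearn.svm import SVR

from .schema import FeatureTable, RegionSchema, ValidationError, write_results

__all__ = [
    "BiasCoefficients",
    "PerformanceMetrics",
    "BrainAgeModel",
    "fit_brain_age_model",
    "predict_age",
    "evaluate",
    "fit_bias_correction",
    "apply_bias_correction",
]

DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_EPSILON = 0.1  # on the standardized age target
N_FOLDS = 10


@dataclass(frozen=True)
class BiasCoefficients:
    """OLS fit of predicted age on chronological age (predicted ~ a*age + b)."""

    alpha: float
    beta: float

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "units": {"beta": "years"}}


@dataclass(frozen=True)
class PerformanceMetrics:
    mae: float  # years
    rmse: float  # years
    r2: float | None  # dimensionless; None when actual has zero variance

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "units": {"mae": "years", "rmse": "years"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceMetrics":
        return cls(mae=d["mae"], rmse=d["rmse"], r2=d["r2"])


@dataclass
class BrainAgeModel:
    """Trained SVR state plus standardization and bias-correction coefficients."""

    schema: RegionSchema
    svr: SVR
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    age_mean: float
    age_sd: float
    C: float
    epsilon: float
    dropped_features: list[str] = field(default_factory=list)
    bias: BiasCoefficients | None = None
    oof_train_predictions: np.ndarray | None = None
    oof_train_ages: np.ndarray | None = None

    def _standardize(self, table: FeatureTable) -> np.ndarray:
        mat, names = table.feature_matrix()
        keep = [i for i, n in enumerate(names) if n in set(self.feature_names)]
        mat = mat[:, keep]
        return (mat - self.feature_mean) / self.feature_sd

    # -- persistence ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "schema": self.schema.to_dict(),
            "schema_hash": self.schema.content_hash(),
            "C": self.C,
            "epsilon": self.epsilon,
            "feature_names": self.feature_names,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "dropped_features": self.dropped_features,
            "bias": self.bias.to_dict() if self.bias else None,
        }
        write_results(meta, directory / "model.json")
        joblib.dump(self.svr, directory / "svr.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "BrainAgeModel":
        import json

        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        bias = meta.get("bias")
        return cls(
            schema=RegionSchema.from_dict(meta["schema"]),
            svr=joblib.load(directory / "svr.joblib"),
            feature_names=meta["feature_names"],
            feature_mean=np.asarray(meta["feature_mean"], dtype=float),
            feature_sd=np.asarray(meta["feature_sd"], dtype=float),
            age_mean=meta["age_mean"],
            age_sd=meta["age_sd"],
            C=meta["C"],
            epsilon=meta["epsilon"],
            dropped_features=meta.get("dropped_features", []),
            bias=BiasCoefficients(bias["alpha"], bias["beta"]) if bias else None,
        )


def fit_brain_age_model(
    train: FeatureTable,
    schema: RegionSchema | None = None,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    bias_mode: str = "out_of_fold",
) -> BrainAgeModel:
    """Fit the brain-age SVR with cross-validated C selection.

    Standardization (features and age target) is fitted on the training
    data only. ``bias_mode`` selects whether the age-bias coefficients come
    from out-of-fold predictions (default) or in-sample refit predictions.
    Fold shuffling is reproducible from *seed*.
    """
    schema = schema or train.schema
    if train.n_subjects < n_folds:
        raise ValidationError(
            f"need at least {n_folds} subjects for {n_folds}-fold CV, "
            f"got {train.n_subjects}"
        )
    if bias_mode not in ("out_of_fold", "in_sample"):
        raise ValueError("bias_mode must be 'out_of_fold' or 'in_sample'")

    mat, names = train.feature_matrix()
    ages = train.ages
    if ages.max() - ages.min() < 1e-12 and train.n_subjects > 1:
        age_sd = 1.0  # degenerate constant-age target; keep scaling finite
    else:
        age_sd = float(ages.std(ddof=0)) or 1.0
    age_mean = float(ages.mean())

    sd = mat.std(axis=0, ddof=0)
    dropped = [n for n, s in zip(names, sd) if s == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s): {dropped[:5]}",
            stacklevel=2,
        )
    keep = sd > 0
    kept_names = [n for n, k in zip(names, keep) if k]
    mat = mat[:, keep]
    mean = mat.mean(axis=0)
    sdk = mat.std(axis=0, ddof=0)
    X = (mat - mean) / sdk
    y = (ages - age_mean) / age_sd

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVR(kernel="rbf", epsilon=epsilon, gamma="scale"),
        param_grid={"C": list(c_grid)},
        scoring="neg_mean_absolute_error",
        cv=cv,
        n_jobs=None,
        refit=True,
    )
    search.fit(X, y)
    best_c = float(search.best_params_["C"])
    svr = search.best_estimator_  # refit on all training data

    model = BrainAgeModel(
        schema=schema,
        svr=svr,
        feature_names=kept_names,
        feature_mean=mean,
        feature_sd=sdk,
        age_mean=age_mean,
        age_sd=age_sd,
        C=best_c,
        epsilon=epsilon,
        dropped_features=dropped,
    )

    # bias-correction fit on training predictions
    if bias_mode == "out_of_fold":
        oof_cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        oof_std = cross_val_predict(
            SVR(kernel="rbf", epsilon=epsilon, gamma="scale", C=best_c),
            X,
            y,
            cv=oof_cv,
        )
        train_preds = oof_std * age_sd + age_mean
    else:
        train_preds = svr.predict(X) * age_sd + age_mean
    model.oof_train_predictions = train_preds
    model.oof_train_ages = ages.copy()
    if train.n_subjects >= 3 and ages.std(ddof=0) > 0:
        model.bias = fit_bias_correction(train_preds, ages)
    return model


def predict_age(model: BrainAgeModel, table: FeatureTable) -> np.ndarray:
    """Predict brain age (years) for each subject using the stored
    standardization; never refits on the given table."""
    if table.n_subjects == 0:
        return np.empty(0, dtype=float)
    X = model._standardize(table)
    return model.svr.predict(X) * model.age_sd + model.age_mean


def evaluate(predicted: np.ndarray, actual: np.ndarray) -> PerformanceMetrics:
    """MAE, RMSE and R^2 of predicted vs chronological age."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    err = predicted - actual
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if len(actual) < 2 or ss_tot == 0:
        warnings.warn("R^2 undefined for zero-variance actual ages", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    return PerformanceMetrics(mae=mae, rmse=rmse, r2=r2)


def fit_bias_correction(
    predicted_train: np.ndarray, actual_train: np.ndarray
) -> BiasCoefficients:
    """OLS of predicted on actual age: predicted ~ alpha * age + beta."""
    predicted_train = np.asarray(predicted_train, dtype=float)
    actual_train = np.asarray(actual_train, dtype=float)
    if len(actual_train) < 3:
        raise ValidationError("need at least 3 subjects to fit bias correction")
    if actual_train.std(ddof=0) == 0:
        raise ValidationError("chronological ages are constant; slope undefined")
    res = stats.linregress(actual_train, predicted_train)
    return BiasCoefficients(alpha=float(res.slope), beta=float(res.intercept))


def apply_bias_correction(
    predicted: np.ndarray | float,
    actual: np.ndarray | float,
    coeffs: BiasCoefficients,
) -> np.ndarray | float:
    """corrected = predicted + [age - (alpha * age + beta)].

    Note the correction consumes each subject's chronological age at
    application time — the corrected value is not a pure function of the
    scan (see docs/methods.md for discussion).
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    out = predicted + (actual - (coeffs.alpha * actual + coeffs.beta))
    return float(out) if out.ndim == 0 else out
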