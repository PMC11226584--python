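"""Voxel-wise elastic-net brain-age model, bias correction, and BAG tables.

The estimator is a statsmodels-style Model/Results pair:

>>> model = BrainAgeModel(design, ages, FitConfig(seed=0))   # doctest: +SKIP
>>> res = model.fit()                                        # doctest: +SKIP
>>> res.summary()                                            # doctest: +SKIP

Fitting protocol: features are standardized voxel-wise (constant voxels
dropped), the penalty strength lambda is chosen by k-fold cross-validation
with the one-standard-error rule, the CV is repeated ``n_repeats`` times
with fresh random partitions, the selected lambdas are averaged, and the
final model is refit on all data at the averaged lambda. The elastic-net
objective is the glmnet parameterization

    (1/2n) ||y - b0 - X w||^2 + lambda * (alpha ||w||_1 + (1-alpha)/2 ||w||^2)

with an unpenalized intercept. Coefficients are returned on the original
feature scale.

Raw predictions in a target cohort are bias-corrected by removing the
training-set linear trend of (predicted - age) on age, the standard remedy
for regression-to-the-mean in age prediction; the corrected gap is the BAG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .config import FitConfig
from .volumes import DesignMatrix, Mask, save_volume, unvectorize

__all__ = [
    "BrainAgeModel",
    "BrainAgeResults",
    "BiasCorrection",
    "FitMetrics",
    "select_lambda_1se",
    "auto_lambda_grid",
    "fit_bias_correction",
    "apply_bias_correction",
    "evaluate",
    "elastic_net_objective",
    "kkt_violation",
]


# ---------------------------------------------------------------------------
# metrics

@dataclass
class FitMetrics:
    """Age-prediction accuracy: MAE and RMSE in years, Pearson correlation."""

    mae: float
    rmse: float
    pearson_r: float
    r_defined: bool = True

    def __post_init__(self) -> None:
        if self.r_defined and not (self.mae <= self.rmse + 1e-12):
            raise ValueError("MAE cannot exceed RMSE")


def evaluate(predicted: np.ndarray, ages: np.ndarray) -> FitMetrics:
    """MAE, RMSE and Pearson r of predicted vs chronological age.

    If either vector has zero variance the correlation is undefined and
    flagged (``r_defined=False``, ``pearson_r=nan``) rather than set to 1.
    """
    predicted = np.asarray(predicted, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if predicted.shape != ages.shape or predicted.size < 2:
        raise ValueError("predicted and ages must be equal-length with n >= 2")
    delta = predicted - ages
    mae = float(np.mean(np.abs(delta)))
    rmse = float(np.sqrt(np.mean(delta**2)))
    if np.std(predicted) == 0 or np.std(ages) == 0:
        return FitMetrics(mae=mae, rmse=rmse, pearson_r=float("nan"),
                          r_defined=False)
    r = float(np.corrcoef(predicted, ages)[0, 1])
    return FitMetrics(mae=mae, rmse=rmse, pearson_r=r)


# ---------------------------------------------------------------------------
# elastic-net internals (glmnet parameterization)

def elastic_net_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                          lam: float, alpha: float) -> float:
    """(1/2n)||y - Xw||^2 + lam*(alpha*||w||_1 + (1-alpha)/2*||w||^2).

    ``y`` is assumed centered (intercept handled outside).
    """
    n = X.shape[0]
    resid = y - X @ w
    return float(
        resid @ resid / (2 * n)
        + lam * (alpha * np.abs(w).sum() + 0.5 * (1 - alpha) * (w @ w))
    )


def kkt_violation(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  lam: float, alpha: float) -> float:
    """Max stationarity violation of the elastic-net subgradient conditions."""
    n = X.shape[0]
    grad = -X.T @ (y - X @ w) / n + lam * (1 - alpha) * w
    active = w != 0
    viol = 0.0
    if active.any():
        viol = float(np.max(np.abs(grad[active] + lam * alpha * np.sign(w[active]))))
    if (~active).any():
        viol = max(viol, float(np.max(np.maximum(np.abs(grad[~active]) - lam * alpha, 0.0))))
    return viol


def auto_lambda_grid(X_std: np.ndarray, y_centered: np.ndarray, alpha: float,
                     n_lambda: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from the data-driven lambda_max.

    lambda_max = max |X~' y~| / (n * alpha) is the smallest penalty at which
    every coefficient is zero; alpha is floored at 0.001 when ridge-like so
    the grid stays finite.
    """
    n = X_std.shape[0]
    a = max(alpha, 1e-3)
    lam_max = float(np.max(np.abs(X_std.T @ y_centered)) / (n * a))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def select_lambda_1se(cv_curve: pd.DataFrame) -> float:
    """The one-standard-error rule on a CV curve.

    ``cv_curve`` has columns ``lambda``, ``mean_error``, ``se``. Returns the
    maximum lambda whose mean CV error is within one standard error of the
    minimum mean CV error.
    """
    lam = np.asarray(cv_curve["lambda"], dtype=float)
    err = np.asarray(cv_curve["mean_error"], dtype=float)
    se = np.asarray(cv_curve["se"], dtype=float)
    ok = np.isfinite(err)
    if not ok.any():
        raise ValueError("CV curve has no finite errors")
    lam, err, se = lam[ok], err[ok], se[ok]
    i_min = int(np.argmin(err))
    threshold = err[i_min] + se[i_min]
    eligible = lam[err <= threshold]
    return float(eligible.max())


def _select_lambda_min(cv_curve: pd.DataFrame) -> float:
    lam = np.asarray(cv_curve["lambda"], dtype=float)
    err = np.asarray(cv_curve["mean_error"], dtype=float)
    ok = np.isfinite(err)
    if not ok.any():
        raise ValueError("CV curve has no finite errors")
    return float(lam[ok][np.argmin(err[ok])])


def _standardize(X: np.ndarray):
    """Column means/SDs; constant columns flagged (SD set to 1, coef will be 0)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    return mean, sd_safe, constant


def _enet_solve(X_std: np.ndarray, y_centered: np.ndarray, lam: float,
                alpha: float, tol: float, max_iter: int) -> np.ndarray:
    """One elastic-net solve at fixed lambda on standardized data (no intercept)."""
    if alpha == 0:
        # pure ridge: closed form is available and exact
        n, p = X_std.shape
        A = X_std.T @ X_std / n + lam * np.eye(p)
        return np.linalg.solve(A, X_std.T @ y_centered / n)
    est = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                     tol=tol, max_iter=max_iter)
    est.fit(X_std, y_centered)
    return est.coef_.copy()


# ---------------------------------------------------------------------------
# Model / Results

class BrainAgeModel:
    """Elastic-net regression of chronological age on voxel-wise GM values.

    Parameters
    ----------
    design : DesignMatrix or ndarray
        Subjects x voxels feature matrix (the vectorized GM maps).
    ages : array-like
        Chronological ages (years), one per design row. May be omitted when
        the design matrix carries ages.
    config : FitConfig
        Fitting protocol (alpha, folds, repeats, grid, selection rule, seed).
    """

    def __init__(self, design: DesignMatrix | np.ndarray,
                 ages: np.ndarray | None = None,
                 config: FitConfig | None = None):
        if isinstance(design, DesignMatrix):
            self.design = design
            X = design.values
            if ages is None:
                ages = design.ages
            self._voxel_index = np.asarray(design.voxel_index)
            self._grid_shape = tuple(design.grid_shape)
            self._affine = design.affine
        else:
            self.design = None
            X = np.asarray(design, dtype=float)
            self._voxel_index = np.arange(X.shape[1])
            self._grid_shape = None
            self._affine = None
        if ages is None:
            raise ValueError("ages are required")
        self.X = np.asarray(X, dtype=float)
        self.ages = np.asarray(ages, dtype=float)
        if self.X.shape[0] != self.ages.size:
            raise ValueError("design rows and ages length differ")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError("ages must be finite")
        if np.var(self.ages) == 0:
            raise ValueError("ages are constant; the outcome has no variance")
        self.config = config or FitConfig()

    def fit(self, verbose: bool = False) -> "BrainAgeResults":
        cfg = self.config
        n, p = self.X.shape
        if n < 2 * cfg.n_folds:
            raise ValueError(
                f"need at least {2 * cfg.n_folds} subjects for {cfg.n_folds}-fold CV; "
                f"got {n}. Reduce n_folds (e.g. to {max(2, n // 2)})."
            )
        mean, sd, constant = _standardize(self.X)
        if not cfg.standardize:
            mean = np.zeros(p)
            sd = np.ones(p)
        X_std = (self.X - mean) / sd
        X_std[:, constant] = 0.0
        y_mean = self.ages.mean()
        y_c = self.ages - y_mean

        if isinstance(cfg.lambda_grid, str):
            grid = auto_lambda_grid(X_std, y_c, cfg.alpha, cfg.n_lambda,
                                    cfg.lambda_min_ratio)
        else:
            grid = np.asarray(cfg.lambda_grid, dtype=float)

        cv_curves: list[pd.DataFrame] = []
        lambda_per_repeat: list[float] = []
        for rep in range(cfg.n_repeats):
            curve = self._cv_one_repeat(X_std, grid, rep)
            cv_curves.append(curve)
            if cfg.selection_rule == "1se":
                lambda_per_repeat.append(select_lambda_1se(curve))
            else:
                lambda_per_repeat.append(_select_lambda_min(curve))
        if cfg.lambda_average == "log":
            lam_final = float(np.exp(np.mean(np.log(lambda_per_repeat))))
        else:
            lam_final = float(np.mean(lambda_per_repeat))

        w_std = _enet_solve(X_std, y_c, lam_final, cfg.alpha, cfg.tol,
                            cfg.max_iter)
        w_std[constant] = 0.0
        weights = w_std / sd
        weights[constant] = 0.0
        intercept = float(y_mean - weights @ mean)
        n_dropped = int(constant.sum())
        if verbose and n_dropped:
            print(f"dropped {n_dropped} constant voxels from penalization")

        return BrainAgeResults(
            model=self,
            weights=weights,
            intercept=intercept,
            lambda_selected=lam_final,
            lambda_per_repeat=lambda_per_repeat,
            cv_curves=cv_curves,
            feature_mean=mean,
            feature_scale=sd,
            constant_features=constant,
            voxel_index=self._voxel_index,
            grid_shape=self._grid_shape,
        )

    def _cv_one_repeat(self, X_std: np.ndarray, grid: np.ndarray,
                       rep: int) -> pd.DataFrame:
        """One k-fold CV pass over the lambda grid; fresh partition per repeat.

        Features are re-standardized within each training fold so validation
        errors do not leak fold-level statistics.
        """
        cfg = self.config
        n = X_std.shape[0]
        kf = KFold(n_splits=cfg.n_folds, shuffle=True,
                   random_state=(cfg.seed + 1000 * rep) % (2**31))
        fold_err = np.empty((cfg.n_folds, grid.size))
        for k, (tr, va) in enumerate(kf.split(np.arange(n))):
            Xtr, Xva = X_std[tr], X_std[va]
            ytr, yva = self.ages[tr], self.ages[va]
            mu = Xtr.mean(axis=0)
            s = Xtr.std(axis=0)
            s[s == 0] = 1.0
            Xtr_s = (Xtr - mu) / s
            Xva_s = (Xva - mu) / s
            ytr_mean = ytr.mean()
            # warm-started path over the whole (descending) grid; the loose
            # cv_tol only affects fold-error estimates, not the final solution
            _, coefs, _ = enet_path(Xtr_s, ytr - ytr_mean, l1_ratio=cfg.alpha,
                                    alphas=grid, tol=cfg.cv_tol,
                                    max_iter=cfg.max_iter)
            pred = Xva_s @ coefs + ytr_mean
            fold_err[k] = np.mean((pred - yva[:, None]) ** 2, axis=0)
        mean_err = fold_err.mean(axis=0)
        se = fold_err.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)
        return pd.DataFrame({"lambda": grid, "mean_error": mean_err, "se": se})


@dataclass
class BrainAgeResults:
    """Fitted brain-age model: coefficients, CV diagnostics, prediction."""

    model: BrainAgeModel
    weights: np.ndarray               # original feature scale
    intercept: float                  # years
    lambda_selected: float
    lambda_per_repeat: list[float]
    cv_curves: list[pd.DataFrame]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    constant_features: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def predict(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        """Raw predicted age: intercept + design @ weights.

        When a DesignMatrix is given its voxel index must match the one the
        model was trained on — no silent reindexing.
        """
        if isinstance(design, DesignMatrix):
            if (design.n_voxels != self.voxel_index.size
                    or not np.array_equal(design.voxel_index, self.voxel_index)):
                raise ValueError(
                    "design voxel_index does not match the model's mask; "
                    "re-vectorize the target volumes with the training mask"
                )
            X = design.values
        else:
            X = np.asarray(design, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != self.weights.size:
                raise ValueError("feature count mismatch")
        return self.intercept + X @ self.weights

    def fitted_values(self) -> np.ndarray:
        return self.predict(self.model.X)

    def training_metrics(self) -> FitMetrics:
        return evaluate(self.fitted_values(), self.model.ages)

    def weight_volume(self, mask: Mask) -> np.ndarray:
        return unvectorize(self.weights, mask)

    def summary(self) -> str:
        m = self.training_metrics()
        lines = [
            "Brain age elastic-net model",
            "===========================",
            f"subjects: {self.model.X.shape[0]}   voxels: {self.model.X.shape[1]}",
            f"alpha: {self.model.config.alpha}   selection: {self.model.config.selection_rule}",
            f"lambda per repeat: {[round(l, 6) for l in self.lambda_per_repeat]}",
            f"lambda selected (mean): {self.lambda_selected:.6f}",
            f"nonzero voxel weights: {self.n_nonzero}",
            f"training MAE: {m.mae:.3f} y   RMSE: {m.rmse:.3f} y   r: {m.pearson_r:.3f}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path, mask: Mask | None = None) -> None:
        """Serialize: JSON metadata + weight arrays (+ weight NIfTI with a mask)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "alpha": self.model.config.alpha,
            "selection_rule": self.model.config.selection_rule,
            "lambda_selected": self.lambda_selected,
            "lambda_per_repeat": self.lambda_per_repeat,
            "intercept": self.intercept,
            "seed": self.model.config.seed,
            "n_nonzero": self.n_nonzero,
            "linearization": "C-order ascending linear voxel index",
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))
        np.savetxt(out / "weights.csv",
                   np.column_stack([self.voxel_index, self.weights]),
                   delimiter=",", header="voxel_index,weight", comments="")
        if mask is not None:
            save_volume(self.weight_volume(mask), out / "weights.nii.gz")


# ---------------------------------------------------------------------------
# bias correction and the BAG table

@dataclass
class BiasCorrection:
    """Training-set linear trend of the raw gap on age: gap ~ a*age + b."""

    slope_a: float
    intercept_b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope_a) and np.isfinite(self.intercept_b)):
            raise ValueError("bias coefficients must be finite")


def fit_bias_correction(predicted_raw: np.ndarray,
                        ages: np.ndarray) -> BiasCorrection:
    """OLS of (predicted_raw - age) on age; the fitted trend is later removed."""
    predicted_raw = np.asarray(predicted_raw, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if predicted_raw.size != ages.size or ages.size < 3:
        raise ValueError("need >= 3 (prediction, age) pairs")
    if np.var(ages) == 0:
        raise ValueError("age variance is zero; bias trend is unidentified")
    gap = predicted_raw - ages
    slope, intercept = np.polyfit(ages, gap, 1)
    return BiasCorrection(slope_a=float(slope), intercept_b=float(intercept))


def apply_bias_correction(predicted_raw: np.ndarray, ages: np.ndarray,
                          bias: BiasCorrection,
                          subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Corrected gap and predicted age.

    bag = (predicted_raw - age) - (a*age + b);  pred_corrected = age + bag.
    Returns the per-subject BAG table (without tertiles, which depend on the
    cohort-wide distribution; see :func:`braingap.outcomes.assign_tertiles`).
    """
    predicted_raw = np.asarray(predicted_raw, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if predicted_raw.size != ages.size:
        raise ValueError("length mismatch")
    bag = (predicted_raw - ages) - (bias.slope_a * ages + bias.intercept_b)
    if subject_ids is None:
        subject_ids = [f"s{i:05d}" for i in range(ages.size)]
    return pd.DataFrame({
        "subject_id": list(subject_ids),
        "age": ages,
        "pred_raw": predicted_raw,
        "pred_corrected": ages + bag,
        "bag": bag,
    })
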