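"""Stage 3 — per-ROI epsilon-insensitive support vector regression.

Each ROI phenotype is predicted from the selected feature SNPs by its own SVR
f(x) = sum_i beta_i K(x_i, x) + b, with beta_i = alpha_i* - alpha_i the dual
coefficients of the support vectors, subject to sum_i beta_i = 0 and
|beta_i| <= C. The dual quadratic program is delegated to scikit-learn's
libsvm-backed SVR; this module's contract is the dual solution's KKT
properties, not the optimizer. Features are standardized inside the stage
(statistics fitted on the training samples only) so the kernel scale is
comparable across SNP panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y, check_is_fitted

from .io import PhenotypeMatrix

logger = logging.getLogger("snproi")

KERNELS = ("linear", "poly", "rbf")


@dataclass
class SVRModel:
    """One fitted per-ROI regression: kernel spec, dual solution and scaling record."""

    svr: SVR
    scaler: StandardScaler | None
    kernel: str
    C: float
    eps_tube: float
    n_features: int
    constant_value: float | None = None  # degenerate constant-target model
    y_mean: float = 0.0                  # target scaling record
    y_scale: float = 1.0

    @property
    def beta(self) -> np.ndarray:
        """Dual coefficients alpha* - alpha of the support vectors."""
        if self.constant_value is not None:
            return np.zeros(0)
        return self.svr.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        if self.constant_value is not None:
            return self.constant_value
        return float(self.svr.intercept_[0])

    @property
    def support_vectors(self) -> np.ndarray:
        if self.constant_value is not None:
            return np.zeros((0, self.n_features))
        return self.svr.support_vectors_


def fit_svr(X_sel: np.ndarray, y: np.ndarray, kernel: str = "rbf", C: float = 1.0,
            eps_tube: float = 0.1, degree: int = 3, coef0: float = 0.0,
            gamma="scale", standardize: bool = True, scale_y: bool = True,
            tol: float = 1e-4) -> SVRModel:
    """Fit one epsilon-insensitive SVR on the selected-SNP feature matrix.

    ``gamma='scale'`` uses 1 / (k * Var(X_sel)) for the rbf/poly kernel width.
    With ``scale_y`` the target is centered/unit-scaled before the dual solve
    (so C and the tube width eps_tube act on a standardized target; predictions
    are mapped back to the original units). A constant target short-circuits
    to a mean predictor (with a warning).
    """
    X_sel, y = check_X_y(np.asarray(X_sel, dtype=float), np.asarray(y, dtype=float))
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    if C <= 0:
        raise ValueError("C must be > 0")
    if eps_tube < 0:
        raise ValueError("eps_tube must be >= 0")
    if np.ptp(y) == 0:
        warnings.warn("constant target: SVR degenerates to a mean predictor",
                      UserWarning, stacklevel=2)
        return SVRModel(SVR(), None, kernel, C, eps_tube, X_sel.shape[1],
                        constant_value=float(y[0]))
    scaler = None
    Xt = X_sel
    if standardize:
        scaler = StandardScaler().fit(X_sel)
        Xt = scaler.transform(X_sel)
    y_mean, y_scale = 0.0, 1.0
    yt = y
    if scale_y:
        y_mean = float(y.mean())
        y_scale = float(y.std(ddof=0))
        yt = (y - y_mean) / y_scale
    svr = SVR(kernel=kernel, C=C, epsilon=eps_tube, degree=degree, coef0=coef0,
              gamma=gamma, tol=tol)
    svr.fit(Xt, yt)
    return SVRModel(svr, scaler, kernel, C, eps_tube, X_sel.shape[1],
                    y_mean=y_mean, y_scale=y_scale)


def predict_svr(m: SVRModel, X_new: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i beta_i K(x_i, x) + b on new feature rows."""
    X_new = check_array(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.n_features:
        raise ValueError(f"expected {m.n_features} features, got {X_new.shape[1]}")
    if m.constant_value is not None:
        return np.full(X_new.shape[0], m.constant_value)
    Xt = m.scaler.transform(X_new) if m.scaler is not None else X_new
    return m.svr.predict(Xt) * m.y_scale + m.y_mean


def fit_all_rois(X_sel: np.ndarray, ph, kernel: str = "rbf", C: float = 1.0,
                 eps_tube: float = 0.1, gamma="scale", scale_y: bool = True,
                 cv_grid: dict | None = None,
                 cv_folds: int = 5, random_state: int = 0) -> dict[str, SVRModel]:
    """One independent SVR per ROI column.

    ``cv_grid`` (e.g. ``{"C": [0.1, 1, 10]}``) triggers a per-ROI grid search
    with ``cv_folds``-fold CV on negative RMSE; otherwise the shared
    hyperparameters are used for every ROI.
    """
    if isinstance(ph, PhenotypeMatrix):
        Y, roi_ids = ph.values, ph.roi_ids
    else:
        Y = np.asarray(ph, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        roi_ids = [f"ROI{j}" for j in range(Y.shape[1])]
    models: dict[str, SVRModel] = {}
    for j, roi in enumerate(roi_ids):
        y = Y[:, j]
        params = {"kernel": kernel, "C": C, "eps_tube": eps_tube, "gamma": gamma}
        if cv_grid and np.ptp(y) > 0:
            y_cv = (y - y.mean()) / y.std(ddof=0) if scale_y else y
            params.update(_grid_select(X_sel, y_cv, params, cv_grid, cv_folds,
                                       random_state))
        models[roi] = fit_svr(X_sel, y, scale_y=scale_y, **params)
    return models


def _grid_select(X, y, base: dict, cv_grid: dict, folds: int, seed: int) -> dict:
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(kernel=base["kernel"], C=base["C"], epsilon=base["eps_tube"],
                    gamma=base["gamma"])),
    ])
    param_grid = {}
    rename = {"C": "svr__C", "eps_tube": "svr__epsilon", "gamma": "svr__gamma",
              "kernel": "svr__kernel"}
    for key, vals in cv_grid.items():
        param_grid[rename.get(key, key)] = vals
    gs = GridSearchCV(pipe, param_grid,
                      scoring="neg_root_mean_squared_error",
                      cv=KFold(folds, shuffle=True, random_state=seed))
    gs.fit(X, y)
    inv = {v: k for k, v in rename.items()}
    return {inv[k]: v for k, v in gs.best_params_.items() if k in inv}


def predict_all_rois(models: dict[str, SVRModel], X_new: np.ndarray) -> np.ndarray:
    """Stack per-ROI predictions into an n x q matrix (column order = dict order)."""
    return np.column_stack([predict_svr(m, X_new) for m in models.values()])


class MultiROISVR(BaseEstimator, RegressorMixin):
    """Independent per-target SVR bank with internal feature standardization."""

    def __init__(self, kernel: str = "rbf", C: float = 1.0, epsilon: float = 0.1,
                 gamma="scale", scale_y: bool = True, cv_grid: dict | None = None,
                 cv_folds: int = 5, random_state: int = 0):
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma
        self.scale_y = scale_y
        self.cv_grid = cv_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True)
        self._y_1d = y.ndim == 1
        Y = y if y.ndim == 2 else y[:, None]
        self.models_ = fit_all_rois(
            X, Y, kernel=self.kernel, C=self.C, eps_tube=self.epsilon,
            gamma=self.gamma, scale_y=self.scale_y, cv_grid=self.cv_grid,
            cv_folds=self.cv_folds, random_state=self.random_state)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "models_")
        X = check_array(X)
        out = predict_all_rois(self.models_, X)
        return out.ravel() if self._y_1d else out
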