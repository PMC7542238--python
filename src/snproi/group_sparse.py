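"""Stage 2 — group-sparse multi-task regression for feature-SNP selection.

Model
-----
With d SNPs, c ROIs and n subjects arranged as X (d x n, column = subject) and
Y (c x n), the weight matrix W (d x c) minimizes

    ||W^T X - Y||_F^2 + gamma1 * sum_k ||W_k||_F + gamma2 * sum_i ||w^i||_2

where W_k stacks the rows of SNP group pi_k (the G_{2,1} penalty, zeroing whole
groups) and w^i is row i (the l_{2,1} penalty, zeroing single SNPs across all
ROIs jointly). The objective is convex; setting the gradient to zero gives the
stationarity condition

    (X X^T + gamma1 * D + gamma2 * Dt) W = X Y^T

with D block-diagonal, k-th block (1 / (2 ||W_k||_F)) I, and Dt diagonal with
i-th entry 1 / (2 ||w^i||_2). Since D and Dt depend on W, the solver alternates
the SPD linear solve with reweighting (IRLS). Norms are floored at
``epsilon_smooth`` so the weights stay finite when a row or block collapses to
zero; under that flooring each iteration is a majorize-minimize step on the
Huber-smoothed objective, which therefore decreases monotonically.

A SNP's importance is the l2 norm of its weight row across ROIs; the top-k rows
are the selected feature SNPs passed to the stage-3 regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .clustering import SNPGroups

logger = logging.getLogger("snproi")


@dataclass
class DesignPair:
    """Feature-major design: X is d x n (SNPs x subjects), Y is c x n (ROIs x subjects).

    ``from_samples`` builds one from the usual samples-major layout, optionally
    centering and unit-scaling each SNP row and centering each ROI row; the
    applied shifts/scales are recorded so predictions can be mapped back.
    """

    X: np.ndarray
    Y: np.ndarray
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError(
                f"X has {self.X.shape[1]} subjects but Y has {self.Y.shape[1]}")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("design contains non-finite values")

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def c(self) -> int:
        return self.Y.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_samples(cls, X_samples: np.ndarray, Y_samples: np.ndarray,
                     standardize: bool = True) -> "DesignPair":
        Xs = np.asarray(X_samples, dtype=float)
        Ys = np.asarray(Y_samples, dtype=float)
        if Ys.ndim == 1:
            Ys = Ys[:, None]
        X = Xs.T.copy()
        Y = Ys.T.copy()
        if not standardize:
            return cls(X, Y)
        x_mean = X.mean(axis=1)
        X -= x_mean[:, None]
        sd = X.std(axis=1, ddof=0)
        x_scale = np.where(sd > 0, sd, 1.0)  # constant SNPs left at zero
        X /= x_scale[:, None]
        y_mean = Y.mean(axis=1)
        Y -= y_mean[:, None]
        return cls(X, Y, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean)


@dataclass
class SolverResult:
    W: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    gamma1: float
    gamma2: float
    epsilon_smooth: float


def _group_row_norms(W: np.ndarray, groups: SNPGroups) -> tuple[np.ndarray, np.ndarray]:
    """(per-group Frobenius norms, per-row l2 norms)."""
    row = np.linalg.norm(W, axis=1)
    grp = np.sqrt(np.bincount(groups.assignment, weights=row**2,
                              minlength=groups.n_groups))
    return grp, row


def objective(W: np.ndarray, dp: DesignPair, groups: SNPGroups,
              gamma1: float, gamma2: float) -> float:
    """Exact (non-smoothed) objective value."""
    W = np.asarray(W, dtype=float)
    if W.shape != (dp.d, dp.c):
        raise ValueError(f"W shape {W.shape} incompatible with design ({dp.d}, {dp.c})")
    if groups.assignment.size != dp.d:
        raise ValueError("group assignment length does not match d")
    resid = W.T @ dp.X - dp.Y
    grp, row = _group_row_norms(W, groups)
    return float(np.sum(resid**2) + gamma1 * grp.sum() + gamma2 * row.sum())


def _huber_norm(t: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed |t|: t for t >= eps, (t^2 + eps^2) / (2 eps) below (C1 at eps)."""
    return np.where(t >= eps, t, (t**2 + eps**2) / (2.0 * eps))


def smoothed_objective(W: np.ndarray, dp: DesignPair, groups: SNPGroups,
                       gamma1: float, gamma2: float, eps: float) -> float:
    """Objective with eps-Huberized norms; what the IRLS provably decreases."""
    resid = W.T @ dp.X - dp.Y
    grp, row = _group_row_norms(W, groups)
    return float(np.sum(resid**2)
                 + gamma1 * _huber_norm(grp, eps).sum()
                 + gamma2 * _huber_norm(row, eps).sum())


def fit_ridge(dp: DesignPair, gamma: float = 1.0) -> np.ndarray:
    """Closed-form ridge weights W = (X X^T + gamma I)^(-1) X Y^T."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    A = dp.X @ dp.X.T
    A[np.diag_indices_from(A)] += gamma
    B = dp.X @ dp.Y.T
    try:
        return linalg.solve(A, B, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "ridge system is singular; use gamma > 0 (X X^T is rank deficient)"
        ) from exc


def fit_gsmurfs(dp: DesignPair, groups: SNPGroups, gamma1: float = 1.0,
                gamma2: float = 1.0, tol: float = 1e-6, max_iter: int = 100,
                epsilon_smooth: float = 1e-8) -> SolverResult:
    """IRLS solver for the G_{2,1} + l_{2,1} group-sparse multi-task objective.

    Alternates (i) the SPD solve (X X^T + gamma1 D + gamma2 Dt) W = X Y^T with
    (ii) rebuilding the diagonal weights from the current row/group norms,
    floored at ``epsilon_smooth``. D and Dt start at the identity, so the first
    iterate is a ridge solution with penalty (gamma1 + gamma2) I. Stops when
    the relative change of the smoothed objective drops below ``tol``.
    """
    if gamma1 < 0 or gamma2 < 0:
        raise ValueError("gamma1 and gamma2 must be >= 0")
    if groups.assignment.size != dp.d:
        raise ValueError("group assignment length does not match d")
    G = dp.X @ dp.X.T
    B = dp.X @ dp.Y.T
    d = dp.d
    assign = groups.assignment
    d_diag = np.ones(d)   # gamma1 * D weights (per row, shared within group)
    dt_diag = np.ones(d)  # gamma2 * Dt weights (per row)
    trace: list[float] = []
    W = np.zeros((d, dp.c))
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        A = G.copy()
        A[np.diag_indices_from(A)] += gamma1 * d_diag + gamma2 * dt_diag
        if it == 1:
            cond = np.linalg.cond(A)
            if cond > 1e12:
                warnings.warn(
                    f"IRLS linear system is ill-conditioned (cond~{cond:.2e}); "
                    "consider larger gamma1/gamma2", UserWarning, stacklevel=2)
        try:
            c_factor = linalg.cho_factor(A, lower=True)
            W = linalg.cho_solve(c_factor, B)
        except linalg.LinAlgError:
            W = linalg.solve(A, B, assume_a="sym")
        obj = smoothed_objective(W, dp, groups, gamma1, gamma2, epsilon_smooth)
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective diverged at IRLS iteration {it}")
        trace.append(obj)
        n_iter = it
        if len(trace) >= 2:
            prev = trace[-2]
            rel = abs(prev - obj) / max(abs(prev), 1e-300)
            if rel < tol:
                converged = True
                break
        grp, row = _group_row_norms(W, groups)
        grp_w = 1.0 / (2.0 * np.maximum(grp, epsilon_smooth))
        d_diag = grp_w[assign]
        dt_diag = 1.0 / (2.0 * np.maximum(row, epsilon_smooth))
    if not converged and tol > 0:
        logger.warning("fit_gsmurfs hit max_iter=%d without converging", max_iter)
    return SolverResult(W, trace, n_iter, converged, gamma1, gamma2, epsilon_smooth)


def snp_importance(W: np.ndarray) -> np.ndarray:
    """Per-SNP importance: l2 norm of the weight row across ROIs."""
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite entries")
    return np.linalg.norm(np.atleast_2d(W), axis=1)


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending; ties -> smaller index first."""
    scores = np.asarray(scores, dtype=float)
    d = scores.size
    if not 1 <= k <= d:
        raise ValueError(f"k={k} out of range [1, {d}]")
    order = np.argsort(-scores, kind="stable")  # stable: ties keep index order
    return order[:k]


class GroupSparseMultiTaskRegressor(BaseEstimator, RegressorMixin):
    """Multi-task linear regression with group (G_{2,1}) and row (l_{2,1}) sparsity.

    Fits all ROI columns jointly so that a SNP is kept or dropped across every
    task at once, and whole LD/gene groups of SNPs can be dropped together.

    Parameters
    ----------
    gamma1 : float, default 1.0
        Weight of the group penalty sum_k ||W_k||_F.
    gamma2 : float, default 1.0
        Weight of the row penalty sum_i ||w^i||_2.
    groups : array-like of int, length n_features, or None
        Group label per SNP; ``None`` makes every SNP its own group (then the
        two penalties coincide).
    standardize : bool, default True
        Center/scale SNP columns and center ROI columns before the solve;
        coefficients are reported on the standardized scale, predictions on
        the original scale.
    tol, max_iter, epsilon_smooth :
        IRLS stopping rule (relative smoothed-objective change), iteration cap
        and norm floor.

    Attributes
    ----------
    coef_ : ndarray (n_features, n_targets)
        Weight matrix W on the (standardized) design scale.
    importance_ : ndarray (n_features,)
        Row l2 norms of ``coef_``.
    objective_trace_ : list of float
        Smoothed objective per IRLS iteration (non-increasing).
    n_iter_, converged_ :
        Solver diagnostics.
    """

    def __init__(self, gamma1: float = 1.0, gamma2: float = 1.0, groups=None,
                 standardize: bool = True, tol: float = 1e-6,
                 max_iter: int = 100, epsilon_smooth: float = 1e-8):
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.groups = groups
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.epsilon_smooth = epsilon_smooth

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True)
        Y = y if y.ndim == 2 else y[:, None]
        dp = DesignPair.from_samples(X, Y, standardize=self.standardize)
        if self.groups is None:
            groups = SNPGroups.singletons(dp.d)
        elif isinstance(self.groups, SNPGroups):
            groups = self.groups
        else:
            groups = SNPGroups(np.asarray(self.groups))
        res = fit_gsmurfs(dp, groups, gamma1=self.gamma1, gamma2=self.gamma2,
                          tol=self.tol, max_iter=self.max_iter,
                          epsilon_smooth=self.epsilon_smooth)
        self.coef_ = res.W
        self.importance_ = snp_importance(res.W)
        self.objective_trace_ = res.objective_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.design_ = dp
        self.groups_ = groups
        self.n_features_in_ = X.shape[1]
        self._y_1d = y.ndim == 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        dp = self.design_
        Xt = X.T.astype(float)
        if dp.x_mean is not None:
            Xt = (Xt - dp.x_mean[:, None]) / dp.x_scale[:, None]
        pred = self.coef_.T @ Xt
        if dp.y_mean is not None:
            pred = pred + dp.y_mean[:, None]
        out = pred.T
        return out.ravel() if self._y_1d else out

    def select(self, k: int) -> np.ndarray:
        """Indices of the top-k SNPs by row-norm importance."""
        check_is_fitted(self, "importance_")
        return select_top_k(self.importance_, k)
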