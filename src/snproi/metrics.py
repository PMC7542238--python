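"""Six regression error measures, per ROI and aggregated.

With predictions f and truths y over n samples:

    MAE   = mean |f - y|
    RMSE  = sqrt(mean (f - y)^2)
    MeAE  = median |f - y|
    MAPE  = 100 * mean |(y - f) / y|
    R2    = 1 - sum (y - f)^2 / sum (y - ybar)^2
    RMSPE = sqrt(mean ((y - f) / y)^2)

MeAE is the median of the *absolute* residuals, per the metric's name; it is
robust to outlying residuals. Percentage metrics (MAPE, RMSPE) require truths
bounded away from zero — ROI volumes and thicknesses are strictly positive in
practice — and raise (naming the offending indices) rather than silently
skipping, which would bias method comparisons. R2 requires a non-constant
truth and can be negative (worse than the mean predictor); it is not clamped.

Aggregation across ROIs is the unweighted arithmetic mean.
"""

from __future__ import annotations

import numpy as np

from .io import MetricsReport, PhenotypeMatrix, METRIC_NAMES

_ZERO_TOL = 1e-12


def _as_pair(f, y) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if f.size != y.size:
        raise ValueError(f"length mismatch: {f.size} predictions vs {y.size} truths")
    if f.size == 0:
        raise ValueError("empty input")
    return f, y


def _check_nonzero(y: np.ndarray, name: str) -> None:
    bad = np.flatnonzero(np.abs(y) <= _ZERO_TOL)
    if bad.size:
        raise ValueError(f"{name} undefined: |y| <= {_ZERO_TOL} at indices {bad.tolist()}")


def mae(f, y) -> float:
    f, y = _as_pair(f, y)
    return float(np.mean(np.abs(f - y)))


def rmse(f, y) -> float:
    f, y = _as_pair(f, y)
    return float(np.sqrt(np.mean((f - y) ** 2)))


def meae(f, y) -> float:
    f, y = _as_pair(f, y)
    return float(np.median(np.abs(f - y)))


def mape(f, y) -> float:
    f, y = _as_pair(f, y)
    _check_nonzero(y, "MAPE")
    return float(100.0 * np.mean(np.abs((y - f) / y)))


def r2(f, y) -> float:
    f, y = _as_pair(f, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("R2 undefined for a constant truth vector")
    return float(1.0 - np.sum((y - f) ** 2) / ss_tot)


def rmspe(f, y) -> float:
    f, y = _as_pair(f, y)
    _check_nonzero(y, "RMSPE")
    return float(np.sqrt(np.mean(((y - f) / y) ** 2)))


_METRICS = {"MAE": mae, "RMSE": rmse, "MeAE": meae, "MAPE": mape,
            "R2": r2, "RMSPE": rmspe}


def compute_metric(name: str, f, y) -> float:
    """Evaluate one named measure; names are the canonical upper-case keys."""
    try:
        fn = _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {list(_METRICS)}") from None
    return fn(f, y)


def evaluate(pred, actual, n_features_used: int = 0) -> MetricsReport:
    """All six measures per ROI plus their unweighted mean across ROIs."""
    if isinstance(pred, PhenotypeMatrix) and isinstance(actual, PhenotypeMatrix):
        if pred.roi_ids != actual.roi_ids:
            raise ValueError("ROI ids of prediction and truth disagree")
        F, Y, roi_ids = pred.values, actual.values, actual.roi_ids
    else:
        F = np.asarray(pred, dtype=float)
        Y = np.asarray(actual, dtype=float)
        if F.ndim == 1:
            F, Y = F[:, None], Y[:, None]
        roi_ids = [f"ROI{j}" for j in range(Y.shape[1])]
    if F.shape != Y.shape:
        raise ValueError(f"shape mismatch: predictions {F.shape} vs truths {Y.shape}")
    per_roi = {
        roi: {name: compute_metric(name, F[:, j], Y[:, j]) for name in METRIC_NAMES}
        for j, roi in enumerate(roi_ids)
    }
    aggregate = {
        name: float(np.mean([per_roi[roi][name] for roi in roi_ids]))
        for name in METRIC_NAMES
    }
    return MetricsReport(per_roi, aggregate, n_features_used)
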