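"""End-to-end three-stage pipeline and the multi-method comparison protocol.

Stage order: redundancy filtering (hierarchical clustering, medoid per flat
cluster) -> SNP grouping (LD connected components or genes) -> group-sparse
multi-task fit and top-k selection -> per-ROI SVR readout. Baselines for the
comparison: per-ROI ordinary least squares on all SNPs, multi-task ridge, and
the group-sparse fit with a refitted linear readout on its selected SNPs.
All methods in a comparison share the same cross-validation fold splits.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_X_y, check_is_fitted

from . import io as sio
from .clustering import LDHierarchicalFilter, SNPGroups, build_groups, ld_r2
from .group_sparse import DesignPair, GroupSparseMultiTaskRegressor, fit_ridge, select_top_k
from .io import GenotypeMatrix, MetricsReport, PhenotypeMatrix, METRIC_NAMES
from .metrics import evaluate
from .svr import MultiROISVR

logger = logging.getLogger("snproi")

COMPARISON_METHODS = ("linear_regression", "ridge", "gsmurfs_linear",
                      "three_stage_gene", "three_stage_cluster")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable record of every stage parameter."""

    distance: str = "euclidean"
    minkowski_r: float = 0.23
    linkage: str = "average"
    n_clusters: int | None = None          # None -> p // 2
    group_mode: str = "ld"                 # 'ld' or 'gene'
    r2_threshold: float = 0.2
    gamma1: float = 10.0                   # CV-selected on the default synthetic scale
    gamma2: float = 10.0
    top_k: int = 50
    kernel: str = "rbf"
    svr_c: float = 1.0
    svr_eps: float = 0.1
    svr_cv: bool = False
    ridge_gamma: float = 1.0
    cv_folds: int = 5
    seed: int = 0
    output_dir: str | None = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class ThreeStageRegressor(BaseEstimator, RegressorMixin):
    """Filter -> group-sparse select -> per-ROI SVR, as one sklearn estimator.

    Parameters mirror :class:`PipelineConfig`; ``gene_labels`` (group label per
    SNP column) is required for ``group_mode='gene'``. ``top_k`` feature SNPs
    are chosen by the row-norm importance of the group-sparse weight matrix.

    Attributes
    ----------
    filter_ : fitted LDHierarchicalFilter (stage 1)
    groups_ : SNPGroups on the filtered panel
    sparse_ : fitted GroupSparseMultiTaskRegressor (stage 2)
    selected_idx_ : top-k indices into the filtered panel
    support_ : top-k indices into the *original* SNP columns
    svr_ : fitted MultiROISVR (stage 3)
    """

    def __init__(self, distance: str = "euclidean", minkowski_r: float = 0.23,
                 linkage: str = "average", n_clusters: int | None = None,
                 group_mode: str = "ld", r2_threshold: float = 0.2,
                 gene_labels=None, gamma1: float = 10.0, gamma2: float = 10.0,
                 top_k: int = 50, kernel: str = "rbf", C: float = 1.0,
                 epsilon: float = 0.1, svr_cv_grid: dict | None = None,
                 random_state: int = 0):
        self.distance = distance
        self.minkowski_r = minkowski_r
        self.linkage = linkage
        self.n_clusters = n_clusters
        self.group_mode = group_mode
        self.r2_threshold = r2_threshold
        self.gene_labels = gene_labels
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.top_k = top_k
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.svr_cv_grid = svr_cv_grid
        self.random_state = random_state

    # -- stages 1 and 2 (shared across top-k sweeps) --------------------------

    def _fit_stages(self, X: np.ndarray, Y: np.ndarray) -> None:
        self.filter_ = LDHierarchicalFilter(
            distance=self.distance, minkowski_r=self.minkowski_r,
            linkage=self.linkage, n_clusters=self.n_clusters).fit(X)
        Xf = self.filter_.transform(X)
        if self.group_mode == "ld":
            self.groups_ = build_groups(Xf, mode="ld", ld=ld_r2(Xf),
                                        threshold=self.r2_threshold)
        elif self.group_mode == "gene":
            if self.gene_labels is None:
                raise ValueError("group_mode='gene' requires gene_labels")
            labels = np.asarray(self.gene_labels)
            self.groups_ = SNPGroups(
                pd.factorize(labels[self.filter_.support_])[0])
        else:
            raise ValueError(f"unknown group_mode {self.group_mode!r}")
        self.sparse_ = GroupSparseMultiTaskRegressor(
            gamma1=self.gamma1, gamma2=self.gamma2,
            groups=self.groups_).fit(Xf, Y)
        self.importance_ = self.sparse_.importance_
        self._Xf = Xf

    def _fit_readout(self, Y: np.ndarray, k: int) -> None:
        if k > self._Xf.shape[1]:
            raise ValueError(
                f"top_k={k} exceeds the {self._Xf.shape[1]} SNPs surviving stage 1")
        self.selected_idx_ = self.sparse_.select(k)
        self.support_ = self.filter_.support_[self.selected_idx_]
        self.svr_ = MultiROISVR(
            kernel=self.kernel, C=self.C, epsilon=self.epsilon,
            cv_grid=self.svr_cv_grid,
            random_state=self.random_state).fit(self._Xf[:, self.selected_idx_], Y)

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True)
        self._y_1d = y.ndim == 1
        Y = y if y.ndim == 2 else y[:, None]
        self._fit_stages(X, Y)
        self._fit_readout(Y, self.top_k)
        self.n_features_in_ = X.shape[1]
        return self

    def refit_top_k(self, y, k: int) -> "ThreeStageRegressor":
        """Refit only the SVR readout for a new k, reusing stages 1-2."""
        check_is_fitted(self, "sparse_")
        Y = np.asarray(y, dtype=float)
        Y = Y if Y.ndim == 2 else Y[:, None]
        self._fit_readout(Y, k)
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = check_array(X)
        out = self.svr_.predict(X[:, self.support_])
        return out.ravel() if getattr(self, "_y_1d", False) else out


# -- linear baselines ----------------------------------------------------------


def _fit_ols_weights(dp: DesignPair) -> np.ndarray:
    """Per-task least squares on the (standardized) design; pseudoinverse if d > n."""
    W, *_ = np.linalg.lstsq(dp.X.T, dp.Y.T, rcond=None)
    return W


def _linear_predict(dp: DesignPair, W: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    Xt = np.asarray(X_new, dtype=float).T
    if dp.x_mean is not None:
        Xt = (Xt - dp.x_mean[:, None]) / dp.x_scale[:, None]
    pred = W.T @ Xt
    if dp.y_mean is not None:
        pred = pred + dp.y_mean[:, None]
    return pred.T


# -- orchestration -------------------------------------------------------------


def _average_reports(reports: list[MetricsReport]) -> MetricsReport:
    rois = list(reports[0].per_roi)
    per_roi = {
        roi: {name: float(np.mean([r.per_roi[roi][name] for r in reports]))
              for name in METRIC_NAMES}
        for roi in rois
    }
    aggregate = {name: float(np.mean([per_roi[roi][name] for roi in rois]))
                 for name in METRIC_NAMES}
    return MetricsReport(per_roi, aggregate, reports[0].n_features_used)


def _make_estimator(cfg: PipelineConfig, g: GenotypeMatrix,
                    group_mode: str) -> ThreeStageRegressor:
    gene_labels = None
    if group_mode == "gene":
        if not g.gene_of:
            raise ValueError("gene grouping requested but genotype matrix has no gene map")
        gene_labels = np.array([g.gene_of.get(s, f"__{s}") for s in g.snp_ids])
    return ThreeStageRegressor(
        distance=cfg.distance, minkowski_r=cfg.minkowski_r, linkage=cfg.linkage,
        n_clusters=cfg.n_clusters, group_mode=group_mode,
        r2_threshold=cfg.r2_threshold, gene_labels=gene_labels,
        gamma1=cfg.gamma1, gamma2=cfg.gamma2, top_k=cfg.top_k,
        kernel=cfg.kernel, C=cfg.svr_c, epsilon=cfg.svr_eps,
        svr_cv_grid={"C": [0.1, 1.0, 10.0]} if cfg.svr_cv else None,
        random_state=cfg.seed)


def run_three_stage(g: GenotypeMatrix, ph: PhenotypeMatrix, cfg: PipelineConfig):
    """Cross-validated three-stage run plus a final fit on all samples.

    Returns ``(selected_snp_ids, roi -> SVRModel, MetricsReport)`` where the
    report averages held-out-fold metrics and the selected ids / models come
    from the final all-sample fit. Artifacts are written to ``cfg.output_dir``
    when set (selected SNPs, weights, metrics, dendrogram, config snapshot).
    """
    g, ph = sio.align_samples(g, ph)
    X, Y = g.values.astype(float), ph.values
    est = _make_estimator(cfg, g, cfg.group_mode)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    reports = []
    for tr, te in kf.split(X):
        fold_est = _make_estimator(cfg, g, cfg.group_mode)
        fold_est.fit(X[tr], Y[tr])
        pred = fold_est.predict(X[te])
        reports.append(evaluate(pred, Y[te], n_features_used=len(fold_est.support_)))
    report = _average_reports(reports)
    report.per_roi = {ph.roi_ids[j]: report.per_roi[f"ROI{j}"]
                      for j in range(ph.q_rois)}
    est.fit(X, Y)
    selected_ids = [g.snp_ids[j] for j in est.support_]
    models = dict(zip(ph.roi_ids, est.svr_.models_.values()))
    if cfg.output_dir:
        _write_artifacts(cfg, g, ph, est, report, selected_ids)
    return selected_ids, models, report


def _write_artifacts(cfg: PipelineConfig, g, ph, est, report, selected_ids) -> None:
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    pd.Series(selected_ids, name="snp_id").to_csv(
        os.path.join(out, "selected_snps.tsv"), sep="\t", index=False)
    kept_ids = [g.snp_ids[j] for j in est.filter_.support_]
    sio.write_weights(est.sparse_.coef_, kept_ids, ph.roi_ids,
                      os.path.join(out, "weights.tsv"))
    sio.write_metrics(report, os.path.join(out, "metrics.tsv"))
    with open(os.path.join(out, "metrics.json"), "w", encoding="utf-8") as fh:
        json.dump({"per_roi": report.per_roi, "aggregate": report.aggregate,
                   "n_features_used": report.n_features_used}, fh, indent=2)
    with open(os.path.join(out, "dendrogram.nwk"), "w", encoding="utf-8") as fh:
        fh.write(est.filter_.dendrogram_.to_newick(list(g.snp_ids)))
    cfg.to_yaml(os.path.join(out, "run-config.yaml"))


@dataclass
class ComparisonResult:
    """CV-averaged metrics per (method, k) plus a per-ROI breakdown."""

    table: pd.DataFrame       # columns: method, k, six metrics, folds, seed
    per_roi: pd.DataFrame     # columns: method, k, roi, six metrics
    fold_hash: str            # identical fold splits across methods


def compare_methods(g: GenotypeMatrix, ph: PhenotypeMatrix, cfg: PipelineConfig,
                    k_list: list[int],
                    methods: tuple[str, ...] = COMPARISON_METHODS) -> ComparisonResult:
    """Evaluate every method at every k on identical CV fold splits.

    ``linear_regression`` and ``ridge`` use all SNPs (k is reported for table
    symmetry but does not affect them); ``gsmurfs_linear`` refits ordinary
    least squares on its top-k selected SNPs; the two three-stage variants
    differ only in stage-2 grouping (LD clusters vs genes).
    """
    g, ph = sio.align_samples(g, ph)
    X, Y = g.values.astype(float), ph.values
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(kf.split(X))
    fold_hash = str(hash(tuple(tuple(te.tolist()) for _, te in splits)))
    rows, roi_rows = [], []
    collect: dict[tuple[str, int], list[MetricsReport]] = {
        (m, k): [] for m in methods for k in k_list}

    for tr, te in splits:
        Xtr, Xte, Ytr, Yte = X[tr], X[te], Y[tr], Y[te]
        if "linear_regression" in methods or "ridge" in methods:
            dp = DesignPair.from_samples(Xtr, Ytr)
        if "linear_regression" in methods:
            W = _fit_ols_weights(dp)
            rep = evaluate(_linear_predict(dp, W, Xte), Yte, X.shape[1])
            for k in k_list:
                collect[("linear_regression", k)].append(rep)
        if "ridge" in methods:
            W = fit_ridge(dp, gamma=cfg.ridge_gamma)
            rep = evaluate(_linear_predict(dp, W, Xte), Yte, X.shape[1])
            for k in k_list:
                collect[("ridge", k)].append(rep)
        if "gsmurfs_linear" in methods:
            # embedded selection: the group-sparse model predicts with its own
            # weight rows restricted to the top-k SNPs
            groups = build_groups(Xtr, mode="ld", ld=ld_r2(Xtr),
                                  threshold=cfg.r2_threshold)
            gs = GroupSparseMultiTaskRegressor(
                gamma1=cfg.gamma1, gamma2=cfg.gamma2, groups=groups).fit(Xtr, Ytr)
            for k in k_list:
                sel = gs.select(min(k, X.shape[1]))
                Wk = np.zeros_like(gs.coef_)
                Wk[sel] = gs.coef_[sel]
                collect[("gsmurfs_linear", k)].append(
                    evaluate(_linear_predict(gs.design_, Wk, Xte), Yte, len(sel)))
        for method, mode in (("three_stage_cluster", "ld"), ("three_stage_gene", "gene")):
            if method not in methods:
                continue
            est = _make_estimator(cfg, g, mode)
            est._y_1d = False
            est._fit_stages(Xtr, Ytr)
            for k in k_list:
                est._fit_readout(Ytr, min(k, est._Xf.shape[1]))
                collect[(method, k)].append(
                    evaluate(est.predict(Xte), Yte, len(est.support_)))

    for (method, k), reports in collect.items():
        if not reports:
            continue
        rep = _average_reports(reports)
        rows.append({"method": method, "k": k, **rep.aggregate,
                     "folds": cfg.cv_folds, "seed": cfg.seed})
        for j, roi in enumerate(ph.roi_ids):
            roi_rows.append({"method": method, "k": k, "roi": roi,
                             **rep.per_roi[f"ROI{j}"]})
    table = pd.DataFrame(rows).sort_values(["method", "k"]).reset_index(drop=True)
    per_roi = pd.DataFrame(roi_rows)
    return ComparisonResult(table, per_roi, fold_hash)
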