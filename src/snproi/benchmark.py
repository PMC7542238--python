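"""Holdout benchmark of the three-stage pipeline against its baselines.

A lighter-weight variant of :func:`snproi.pipeline.compare_methods`: one 80/20
train/test split per replicate instead of full cross-validation, with stages 1
and 2 fitted once per replicate and the SVR readout refitted across the top-k
grid. Used for repeated-seed comparisons of prediction error and of error
stability across the number of selected SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import build_groups, ld_r2
from .group_sparse import DesignPair, GroupSparseMultiTaskRegressor, fit_ridge
from .metrics import evaluate
from .pipeline import PipelineConfig, ThreeStageRegressor, _linear_predict, _make_estimator
from .simulate import SimulationConfig, simulate_dataset


@dataclass
class HeadlineResult:
    """Per-replicate aggregate RMSEs for the headline comparison."""

    seed: int
    ridge_rmse: float
    three_stage_rmse: dict[int, float]     # k -> aggregate RMSE
    gsmurfs_rmse: dict[int, float]         # k -> aggregate RMSE (own truncated weights)

    @property
    def three_stage_mean(self) -> float:
        return float(np.mean(list(self.three_stage_rmse.values())))

    @property
    def beats_ridge(self) -> bool:
        return self.three_stage_mean < self.ridge_rmse

    @property
    def more_stable_than_gsmurfs(self) -> bool:
        return (np.std(list(self.three_stage_rmse.values()))
                < np.std(list(self.gsmurfs_rmse.values())))


def headline_comparison(seed: int, sim_cfg: SimulationConfig | None = None,
                        pipe_cfg: PipelineConfig | None = None,
                        k_grid: tuple[int, ...] = (20, 40, 60, 80, 100),
                        train_frac: float = 0.8) -> HeadlineResult:
    """One replicate: simulate, split, fit ridge / group-sparse / three-stage.

    The simulation defaults to the quadratic-link study-scale configuration,
    where a nonlinear readout has genuine signal to gain over linear baselines.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig(link="quadratic", seed=seed)
    if pipe_cfg is None:
        pipe_cfg = PipelineConfig(seed=seed)
    ds = simulate_dataset(sim_cfg)
    X = ds.genotypes.values.astype(float)
    Y = ds.phenotypes.values
    rng = np.random.default_rng(seed + 1_000_003)
    idx = rng.permutation(X.shape[0])
    ntr = int(train_frac * len(idx))
    tr, te = idx[:ntr], idx[ntr:]

    dp = DesignPair.from_samples(X[tr], Y[tr])
    ridge_rmse = evaluate(
        _linear_predict(dp, fit_ridge(dp, pipe_cfg.ridge_gamma), X[te]),
        Y[te]).aggregate["RMSE"]

    groups = build_groups(X[tr], mode="ld", ld=ld_r2(X[tr]),
                          threshold=pipe_cfg.r2_threshold)
    gs = GroupSparseMultiTaskRegressor(gamma1=pipe_cfg.gamma1,
                                       gamma2=pipe_cfg.gamma2,
                                       groups=groups).fit(X[tr], Y[tr])
    gsmurfs_rmse = {}
    for k in k_grid:
        sel = gs.select(min(k, X.shape[1]))
        Wk = np.zeros_like(gs.coef_)
        Wk[sel] = gs.coef_[sel]
        gsmurfs_rmse[k] = evaluate(
            _linear_predict(gs.design_, Wk, X[te]), Y[te]).aggregate["RMSE"]

    est = _make_estimator(pipe_cfg, ds.genotypes, "ld")
    est._y_1d = False
    est._fit_stages(X[tr], Y[tr])
    three_stage_rmse = {}
    for k in k_grid:
        est._fit_readout(Y[tr], min(k, est._Xf.shape[1]))
        three_stage_rmse[k] = evaluate(est.predict(X[te]), Y[te]).aggregate["RMSE"]

    return HeadlineResult(seed, float(ridge_rmse), three_stage_rmse, gsmurfs_rmse)


def support_recovery(seed: int, k: int | None = None,
                     sim_cfg: SimulationConfig | None = None,
                     gamma1: float = 1.0, gamma2: float = 1.0) -> float:
    """Fraction of truly active SNPs among the top-k selected, one replicate.

    Defaults to the recovery study conditions: n=500, p=200, 20 LD blocks,
    3 active, SNR=5, k = true support size, grouping from the generating blocks.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig(n_samples=500, p_snps=200, q_rois=10,
                                   n_blocks=20, n_active_groups=3, snr=5.0,
                                   seed=seed)
    ds = simulate_dataset(sim_cfg)
    gs = GroupSparseMultiTaskRegressor(gamma1=gamma1, gamma2=gamma2,
                                       groups=ds.true_groups).fit(
        ds.genotypes.values, ds.phenotypes.values)
    truth = ds.true_support
    sel = gs.select(k if k is not None else truth.size)
    return float(np.isin(sel, truth).mean())
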