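# snproi

Three-stage association analysis between SNPs and brain-imaging phenotypes.

Imaging genetics asks which genetic variants drive structural differences in
the brain. Given an additive genotype matrix `X ∈ {0,1,2}^{n×p}` (n subjects,
p candidate SNPs; 0/1/2 = minor-allele count) and a matrix `Y ∈ ℝ^{n×q}` of
region-of-interest (ROI) phenotypes (volumes, thicknesses, densities), the
goal is a small feature-SNP set whose values predict the ROI phenotypes well.
This package implements that analysis as three composable stages, each also
exposed as a scikit-learn estimator:

1. **Redundancy filtering** (`LDHierarchicalFilter`) — SNPs in strong linkage
   disequilibrium (LD) are near-duplicates. Pairwise SNP dissimilarities
   (Euclidean, absolute, Minkowski with any exponent r > 0, or
   variance-weighted) feed agglomerative hierarchical clustering (single /
   complete / centroid / average / Ward linkage); the dendrogram is cut into
   flat clusters and each cluster is represented by its medoid SNP. The
   cophenetic correlation between tree and distances diagnoses which
   distance × linkage combination fits the panel best
   (`linkage_distance_screen`).

2. **Group-sparse feature selection** (`GroupSparseMultiTaskRegressor`) —
   a multi-task regression of all ROIs on all surviving SNPs with two coupled
   penalties over the weight matrix `W ∈ ℝ^{d×c}`:

       min_W ‖WᵀX − Y‖²_F + γ₁ Σ_k ‖W_k‖_F + γ₂ Σ_i ‖wⁱ‖₂

   The G₂,₁ term sums Frobenius norms over SNP *groups* (LD components with
   r² ≥ 0.2, or genes), dropping whole groups; the ℓ₂,₁ term sums row norms,
   dropping single SNPs across all ROIs jointly. The convex objective is
   solved by iteratively reweighted least squares: a symmetric
   positive-definite solve `(XXᵀ + γ₁D + γ₂D̃)W = XYᵀ` alternating with
   diagonal reweighting `D_ii = 1/(2‖W_{k(i)}‖_F)`, `D̃_ii = 1/(2‖wⁱ‖₂)`.
   SNP importance is the row norm `‖wⁱ‖₂`; the top-k rows are the feature SNPs.

3. **SVR readout** (`MultiROISVR`) — one ε-insensitive support vector
   regression per ROI on the selected SNPs,
   `f(x) = Σᵢ (αᵢ* − αᵢ) K(xᵢ, x) + b`, with linear, polynomial or RBF
   kernel, capturing nonlinear SNP→phenotype relationships the linear stages
   cannot.

`ThreeStageRegressor` chains the stages as one estimator; predictions are
scored by six error measures (MAE, RMSE, MeAE, MAPE, R², RMSPE) per ROI and
aggregated. A block-LD synthetic-data generator (`simulate_dataset`)
reproduces the study geometry (632 samples × 486 SNPs × 56 ROIs, 40 LD
blocks) with group-sparse true effects and controllable signal-to-noise, so
the whole pipeline is testable without restricted clinical data.

## Worked example

```python
import numpy as np
from snproi import SimulationConfig, simulate_dataset, ThreeStageRegressor, evaluate

ds = simulate_dataset(SimulationConfig(link="quadratic", seed=1))
X, Y = ds.genotypes.values.astype(float), ds.phenotypes.values
tr, te = np.arange(500), np.arange(500, 632)

est = ThreeStageRegressor(top_k=60).fit(X[tr], Y[tr])
report = evaluate(est.predict(X[te]), Y[te])
print(f"selected {len(est.support_)} SNPs, "
      f"{np.isin(est.support_, ds.true_support).sum()} truly active")
print(f"held-out aggregate RMSE {report.aggregate['RMSE']:.3f}  "
      f"R2 {report.aggregate['R2']:.3f}")
```

prints

```
selected 60 SNPs, 16 truly active
held-out aggregate RMSE 3.255  R2 0.306
```

60 feature SNPs survive the filter → group-sparse ranking; 16 of them carry
true nonzero effects (the generator's three active blocks hold 36 SNPs, many
of which the stage-1 medoid pruning replaces with correlated LD proxies, so
the selected set mixes causal SNPs with their proxies). The held-out
aggregate RMSE of 3.26 is less than half of what ridge regression on all 486
SNPs achieves on the same split (7.59), because the RBF-kernel readout
captures the quadratic component of the simulated SNP→ROI link that any
linear model must leave in the residual.

The same analysis is available from the shell:

```bash
snproi simulate --link quadratic --seed 1 --out run/data
snproi cluster-screen --genotypes run/data/genotypes.tsv
snproi fit --genotypes run/data/genotypes.tsv --phenotypes run/data/phenotypes.tsv \
           --top-k 60 --out run/fit
snproi compare --genotypes run/data/genotypes.tsv --phenotypes run/data/phenotypes.tsv \
           --gene-map run/data/gene_map.tsv --out run/cmp
```

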