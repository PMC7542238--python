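# Methods

## Problem and model

The package relates an additive genotype matrix `X ∈ {0,1,2}^{n×p}` (0 = wild
homozygote, 1 = heterozygote, 2 = mutant homozygote by minor-allele count) to
a continuous ROI-phenotype matrix `Y ∈ ℝ^{n×q}`: find a small feature-SNP set
whose values predict the ROI phenotypes with low error. Each ROI is one
regression task; all tasks are coupled, because SNPs act on multiple brain
regions and LD couples SNPs to one another. The analysis has three stages.

### Stage 1 — LD-aware redundancy filtering

Pairwise dissimilarities between SNP columns over n subjects:

| kind | definition |
|---|---|
| euclidean | (Σᵢ (uᵢ−vᵢ)²)^½ |
| absolute | Σᵢ \|uᵢ−vᵢ\| |
| minkowski(r) | (Σᵢ \|uᵢ−vᵢ\|^r)^{1/r}, any r > 0 |
| variance_weighted | (Σᵢ (uᵢ−vᵢ)²/sᵢ²)^½, sᵢ² = variance of subject i's codes across SNPs |

Minkowski exponents below 1 violate the triangle inequality; they are
accepted as *power dissimilarities* with a warning, since agglomerative
clustering needs only dissimilarities. The variance-weighted form is the
standard per-coordinate inverse-variance weighting; a subject with identical
codes at every SNP makes it undefined and is reported as an error rather than
silently skipped. Exponents this small (e.g. r = 0.23) compress large code
differences toward counts of disagreeing subjects, which can track LD better
than squared differences.

Agglomerative clustering (single, complete, centroid, average, Ward linkage)
is delegated to `scipy.cluster.hierarchy`; merge heights are monotone for all
linkages except centroid, whose known inversions are logged and tolerated.
The cophenetic correlation — Pearson correlation between original pairwise
distances and the heights at which pairs first merge — scores how faithfully
each distance × linkage combination represents the panel;
`linkage_distance_screen` tabulates the full 4 × 5 grid and its argmax.

The dendrogram is cut into `n_clusters` flat clusters (default p/2, a
halving of the panel; the cut count is a free parameter because no principled
universal choice exists) and each cluster is represented by its **medoid**,
the member minimizing summed within-cluster distance, with ties broken toward
the smaller SNP index. Medoids are actual SNPs (unlike centroids), which
keeps downstream results interpretable.

### Stage 2 — group-sparse multi-task selection

With the design arranged feature-major (X is d×n, Y is c×n), the weight
matrix W (d×c) minimizes

    ‖WᵀX − Y‖²_F + γ₁ Σ_k ‖W_k‖_F + γ₂ Σᵢ ‖wⁱ‖₂

where the groups π_k partition the SNPs. Two grouping rules are provided:
connected components of the graph with an edge wherever r² ≥ 0.2 (the
pairwise rule is not transitive, so the component closure is taken to obtain
a true partition), or one group per annotated gene with unannotated SNPs as
singletons. The G₂,₁ penalty zeroes whole groups; the ℓ₂,₁ penalty zeroes
single SNP rows across every ROI jointly, so selection is consistent across
tasks.

Setting the gradient to zero gives `(XXᵀ + γ₁D + γ₂D̃)W = XYᵀ` with
`D = diag(1/(2‖W_{k(i)}‖_F))` and `D̃ = diag(1/(2‖wⁱ‖₂))`. Because D and D̃
depend on W, the solver alternates the SPD linear solve (Cholesky) with
reweighting — iteratively reweighted least squares. Numerical choices:

* **ε-flooring.** The weights are undefined at zero norms; norms are floored
  at ε = 1e−8 in the reweighting. Under that floor each iteration is a
  majorize–minimize step on the objective with ε-Huberized norms
  (h(t) = t for t ≥ ε, (t²+ε²)/(2ε) below), so the smoothed objective is
  provably non-increasing; the solver records it per iteration.
* **Initialization.** D = D̃ = I, so the first iterate is a ridge solution
  with penalty (γ₁+γ₂)I — cheap and stable.
* **Stopping.** Relative change of the smoothed objective < 1e−6, capped at
  100 iterations (both configurable). When a row collapses toward zero the
  objective flattens before the row fully settles; analyses that need
  machine-precision stationarity (the oracle comparisons) disable the
  tolerance and run a fixed iteration budget instead.
* **Conditioning.** The system's condition number is estimated once at the
  first iteration and a warning is emitted above 1e12; the reweighting only
  adds positive diagonal mass afterwards.
* **Standardization.** SNP rows are centered and unit-scaled and ROI rows
  centered before the solve (fitted on training data only), making γ values
  comparable across SNPs; coefficients are reported on the standardized
  scale and predictions mapped back.

SNP importance is the row norm ‖wⁱ‖₂ — invariant to rotations of the ROI
axes — and the top-k rows are the feature SNPs, ties broken toward the
smaller index. IRLS never produces exact zeros; rows below 1e−6 of the
maximum row norm are reported as zero in summaries.

The pipeline defaults γ₁ = γ₂ = 10 were selected once by 5-fold
cross-validation on aggregate RMSE over the grid 10^{−3..3} on the default
synthetic configuration and then frozen; the bare estimator keeps a neutral
default of 1 and composes with scikit-learn model selection for
dataset-specific tuning.

### Stage 3 — per-ROI support vector regression

Each ROI gets an independent ε-insensitive SVR on the selected SNPs,
`f(x) = Σᵢ βᵢ K(xᵢ,x) + b` with βᵢ = αᵢ* − αᵢ, Σβᵢ = 0 and |βᵢ| ≤ C. The
dual quadratic program is delegated to scikit-learn's libsvm backend; the
module's contract is the dual solution's feasibility and KKT properties, not
the optimizer. Kernels: linear, polynomial, RBF (default, width
1/(k·Var(X_sel)), i.e. sklearn's `scale`). Features **and the target** are
standardized inside the stage on training data only: C and the tube width
ε = 0.1 then act on a unit-variance target, which keeps the defaults
meaningful for phenotypes of any scale (ROI volumes sit around 10–20 in the
synthetic data). The scaling record is stored on the model and inverted at
prediction. An exactly constant training target degenerates to a mean
predictor with a warning. Optional per-ROI grid search over C (5-fold CV on
RMSE) is available but off by default.

## Evaluation measures

Six measures per ROI, aggregated by unweighted mean: MAE, RMSE,
MeAE = median |f−y| (the median of the *absolute* residuals — the signed
median would not be an "absolute error" and could cancel), MAPE (in percent),
R² (not clamped; negative means worse than the mean predictor), and RMSPE
(on the raw ratio scale, not percent). Percentage measures require truths
bounded away from zero and raise otherwise, naming the offending indices —
ROI volumes and thicknesses are strictly positive in practice, and silent
skipping would bias method comparisons.

## Synthetic data

The generator emulates a candidate-SNP imaging-genetics panel at the study
scale (defaults: 632 subjects, 486 SNPs, 56 ROIs, 40 LD blocks):

* **Genotypes.** Latent-Gaussian threshold model: within each block, latent
  normals share an exchangeable correlation ρ (default 0.7); each coordinate
  is cut at the Hardy–Weinberg quantiles of a per-SNP MAF drawn uniformly
  from [0.05, 0.5]. Marginals follow Hardy–Weinberg proportions exactly;
  within-block r² is tunable through ρ and between-block r² is ~0.
* **Effects.** 3 active blocks (default); their weight rows are i.i.d.
  normal, all other rows exactly zero — the group-row-sparse structure the
  stage-2 penalty assumes.
* **Phenotypes.** Signal W*ᵀ(X−mean), optionally plus a standardized
  quadratic term (`link="quadratic"`, equal to z + 0.5(z²−mean z²) on the
  per-ROI standardized linear score, putting ~⅓ of signal variance in the
  nonlinear component) so a kernel readout has genuine signal to gain over
  linear baselines. Per-ROI Gaussian noise is scaled to a target
  signal-to-noise ratio (default 5); a positive baseline offset uniform on
  [10, 20] mimics strictly positive ROI volumes and keeps percentage metrics
  well defined.

What the generator does **not** emulate: population stratification,
covariates (age, sex), genotyping missingness patterns, spatially correlated
imaging noise across ROIs, and realistic decaying-with-distance LD (blocks
are exchangeable inside and independent between). Passing tests therefore
demonstrate correctness of the machinery and qualitative behavior under
block-LD group-sparse conditions, not clinical performance.

## Comparison protocol

`compare_methods` evaluates, on identical cross-validation fold splits
(5-fold by default, sample-level, seeded): per-ROI least squares on all SNPs
("multivariate regression"; pseudoinverse when p > n), multi-task ridge, the
group-sparse model predicting with its own weight rows restricted to the
top-k SNPs (embedded selection — each method is evaluated with its own
coefficients at a given number of selected SNPs), and the two three-stage
variants, which differ only in the stage-2 grouping (LD components vs
genes). The repeated-seed benchmark (`snproi.benchmark`) uses a single 80/20
holdout per replicate and re-fits only the SVR readout across the top-k grid,
which keeps 20 study-scale replicates within a few CPU-minutes; with the
quadratic link, the three-stage pipeline consistently halves the ridge error
and its error varies far less across k ∈ {20..100} than the truncated-weight
linear readout's.

## Known limitations

* The training protocol of the original analyses (folds, repetitions, the
  exact k values) is not recoverable, so comparisons are reproduced
  qualitatively on synthetic data, not numerically.
* Covariate adjustment is out of scope; real analyses would regress out age,
  sex and scanner effects first.
* Cophenetic screening at p SNPs costs O(p²) memory; the implementation is
  intended for candidate panels (hundreds to thousands of SNPs), not
  genome-wide screening.
* For r < 1 the Minkowski exponent yields a non-metric dissimilarity;
  centroid/Ward linkage interpret distances as Euclidean and are reported
  for completeness, as in standard practice.
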