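# Methods

## Model and estimator

Each condition k ∈ {1, 2} is a zero-mean Gaussian graphical model on the
same p features: X⁽ᵏ⁾ ~ N(0, Σₖ) with precision Ωₖ = Σₖ⁻¹, and
Ωₖ,ᵢⱼ = 0 exactly when features i and j are conditionally independent
given the rest. Structure is estimated by neighborhood selection: for every
node i, a sparse regression of column i on the other p − 1 columns,
coupled across the two conditions by a fused-lasso penalty,

    f(β⁽¹⁾, β⁽²⁾) = Σₖ wₖ/2 ‖y⁽ᵏ⁾ − X⁽ᵏ⁾β⁽ᵏ⁾‖²
                    + λ₁ Σⱼ (|βⱼ⁽¹⁾| + |βⱼ⁽²⁾|) + λ₂ Σⱼ |βⱼ⁽¹⁾ − βⱼ⁽²⁾|.

A nonzero βⱼ in node i's regression corresponds (up to a positive factor)
to the partial correlation between i and j, so the support of the fitted
coefficients is the estimated edge set. The ℓ₁ term on the coefficient sum
yields sparse per-condition networks; the ℓ₁ term on the difference sets
βⱼ⁽¹⁾ = βⱼ⁽²⁾ *exactly* for edges without cross-condition evidence.
Consequences used throughout: common edges carry bitwise-equal
coefficients, condition-specific edges are exact zeros on the other side,
and edge classification never needs a tolerance.

### Error weighting

wₖ = 1/Nₖ (each group contributes its mean squared error) is the default.
With raw squared error (wₖ = 1, the legacy mode) the loss scales with Nₖ
while the penalties do not, so the effective penalty per sample differs
between groups: with 20 vs 200 samples the smaller group's coefficients
face a 10× stronger effective penalty and its estimated network is largely
stripped, with nearly every false differential edge appearing as
"present only in the larger group". The MSE weighting removes this scale
asymmetry: the fused estimate weighs both groups' evidence equally and the
false-positive count drops by an order of magnitude (see the study below).
The weighted objective is invariant under duplicating all samples of one
group; the legacy objective is not.

A caveat the imbalance study makes explicit: equal *objective*
contributions do not imply equal per-group false-detection *rates*. The
sample correlation noise of group k scales as 1/√Nₖ while both groups face
one common threshold (≈ λ₁ + λ₂ on the correlation scale), so the few
remaining condition-specific false edges concentrate in the smaller group.
A 50/50 split of condition-specific false edges under the null is not
achievable by any common (λ₁, λ₂); balancing per-group false-detection
rates would require group-specific thresholds ∝ 1/√Nₖ, which is outside
this model family.

### Standardization

Columns are centered and scaled to unit *population* variance within each
condition. This puts the weighted Gram diagonal exactly at 1, so inner
products coincide with sample correlations and λ values live on the
correlation scale (λ₁ above max |cor| zeroes everything). Standardization
is per-condition, not pooled; missing values are rejected at ingestion.
Condition-2 columns are matched to the condition-1 feature order by name.

## Solver

The penalty is separable over per-predictor pairs (βⱼ⁽¹⁾, βⱼ⁽²⁾), so
cyclic block coordinate descent over these 2-D blocks converges to the
global optimum of the convex objective. The block subproblem

    a₁/2 (b₁−c₁)² + a₂/2 (b₂−c₂)² + λ₁(|b₁|+|b₂|) + λ₂|b₁−b₂|

is solved exactly by enumerating the stationary points of every smooth
sign region together with the minimizers restricted to the kink lines
b₁ = 0, b₂ = 0, b₁ = b₂ (at most 11 candidates); the fused and zero
branches return bitwise-equal pairs and exact zeros. Blocks are visited in
ascending index order; convergence is declared when the largest absolute
coefficient change over a sweep falls below `tol` (default 1e-6;
`max_sweeps` 10 000). Because every block update is an exact minimization,
the objective is non-increasing sweep by sweep.

Three equivalent update strategies:

* **naive** — inner products recomputed from data vectors each update;
* **resi_upd** — residuals maintained by two axpy updates per coefficient
  change and fully recomputed every 100 sweeps to bound floating drift;
* **corr_mtx** — all inner products read from precomputed weighted Gram
  (correlation) tables; implemented as a compiled (numba) kernel and used
  by the cross-validation and study code. Per-node tables are slices of
  one p × p table per condition.

The sequential strong rule screens predictors on the λ₁ penalty per
condition (keep j when maxₖ |wₖ Xⱼ⁽ᵏ⁾ᵀy⁽ᵏ⁾| ≥ 2λ₁ − λ_max); the fusion
penalty is ignored at screening time. Every screened solve ends with a KKT
check that re-solves the 2-D subproblem for each discarded predictor at the
current residuals and re-admits violators, so screening is
solution-equivalent (verified to 1e-10 in the tests). Node problems are
independent and parallelized over threads (the kernel releases the GIL);
results are identical for any worker count.

## Penalty selection

* **FPR control.** λ₁ = (2/√N)·Φ⁻¹(1 − α₁/(2p²)) with N the *total*
  sample count — the neighborhood-selection threshold with a
  per-comparison correction over the p² candidate coefficients; strictly
  decreasing in α₁, increasing in p, ∝ 1/√N.
  λ₂ = ½·tanh((2/√(N−3))·Φ⁻¹(1 − α₂/2))·(1 − mean(ρ⁽¹⁾ρ⁽²⁾)) — a
  Fisher-z threshold on cross-condition correlation differences, shrunk by
  how correlated the two conditions already are. The mediating statistic
  mean(ρ⁽¹⁾ρ⁽²⁾) is estimated as the average over unordered feature pairs
  of the product of the two conditions' sample correlations; it is isolated
  in one function (`estimate_rho_product_mean`) so the estimator can be
  swapped. Both formulas assume standardized variables.
* **Cross-validation.** K ∈ {5, 10} folds drawn within each condition;
  each training split is standardized on its own and held-out samples are
  mapped with the training statistics. The score is the per-group mean
  squared prediction error summed over conditions and nodes, averaged over
  folds; ties break toward the larger (λ₁, λ₂) pair (sparser model). The
  default grid is 10 log-spaced λ₁ in [0.02, λ_max] × 6 linear λ₂ in
  [0, λ₁/2].

## Network assembly

Neighborhood selection produces two directed opinions per feature pair;
symmetrization makes one undirected edge. Under the default `or_rule` an
edge exists in condition k when either direction is nonzero and the
reported weight is the maximum-magnitude direction's coefficient
(|β| ties broken toward the lower-index response row); under `and_rule`
both directions must agree and the weight is their mean. The `or_rule`
maximizes sensitivity for differential edges (the method's target);
`and_rule` trades recall for specificity. Weights are reported as
regression coefficients, not converted to partial correlations (the
precision diagonal is not estimated). Swapping the input conditions
exactly swaps the condition-specific edge classes.

## Simulator

`SimulationSpec` builds a sparse support (random: Erdős–Rényi with mean
degree 3 unless `edge_prob` is given; cluster: within-module
Erdős–Rényi blocks at density 0.25; hub: p/20 hubs of degree p/4 over a
matched background; scale_free: per-module preferential attachment, one
module per component), assigns off-diagonal weights uniform in
`edge_weight_range` (default (0.2, 0.6)) with random sign, and sets the
diagonal to the row-wise absolute sum + 0.1 — strict diagonal dominance,
so positive definiteness holds by construction (and is still checked).
Rewiring removes round(fraction·|E|) edges and adds the same number
elsewhere, keeping density constant; kept edges retain their weights, so
the ground-truth common/differential labels are exact support algebra.
Data are Cholesky samples from N(0, Ω⁻¹); a multivariate-t option
(`t_dof`) provides heavy-tailed draws for robustness checks.

What the generator does *not* emulate: non-Gaussian marginals beyond the
t option, mean shifts between conditions, batch structure, missingness,
or measurement noise correlated across features. Passing tests therefore
demonstrate correctness of the estimator under its own model assumptions,
not robustness to real-data pathologies.

## Evaluation

Scores are computed over all p(p−1)/2 unordered pairs. For the `common`
target, positives are the truth's support intersection and a pair counts
as predicted when both condition coefficients are nonzero; for
`differential`, positives are the support symmetric difference and
predictions are pairs nonzero in exactly one condition (weight-only
changes are reported as their own class but are not support differences).
Partial ROC ranks pairs by min(|β₁|, |β₂|) (common) or |β₁ − β₂|
(differential) and reports the area over FPR ∈ [0, cap] divided by the
cap (default cap 0.1): perfect ranking → 1, reversed → 0, chance → cap/2,
and cap = 1 recovers the full AUC. The separate-lasso baseline is the
λ₂ = 0 path of the same solver — the "estimate each condition
independently and subtract" approach the fusion is designed to beat.

## Study designs and problem sizes

* **Imbalanced-null study** — one generating network (null), 20 vs 200
  samples, p = 50, both group orders per seed, penalties from the FPR
  formulas at α₁ = α₂ = 0.05; legacy-mode penalties are multiplied by
  N/2 so the two modes coincide exactly for balanced groups and any
  contrast isolates the weighting. Reported: condition-specific false
  differential edge counts and the fraction present only in the smaller
  group.
* **Joint-vs-separate study** — p = 100, 100 samples per group, 10% of
  edges rewired, penalties by 5-fold CV, 10 seeds per topology (random
  and hub); differential-edge F1 of the fused fit vs the separate-lasso
  baseline at the same λ₁.

The test suite runs these at the sizes above; the acceptance script uses
reduced seed counts (3 CV seeds, 25 null seeds) to keep a single run in a
few minutes.

## Numerical choices and degenerate inputs

Zero-variance columns are rejected with the feature named. The 2-D block
solver requires positive curvatures (guaranteed by standardization).
λ₁ ≥ λ_max yields the all-zero solution; α values must lie in (0, 1);
the λ₂ formula needs N > 3. Ties in CV error prefer larger penalties;
ties in |β| during or-rule assembly prefer the lower-index direction.
Incremental residuals are refreshed every 100 sweeps. Solver tolerances of
1e-10..1e-12 are used in tests that assert cross-strategy agreement to
1e-10, so the compared runs sit at the same fixed point.

## Known limitations

Two conditions only; no latent-variable or nonparanormal extensions; edge
weights are regression coefficients, not partial correlations; the strong
rule screens only the λ₁ penalty (safe via the KKT backstop but possibly
conservative); the closed-form λ formulas assume balanced groups in their
noise calibration (see the weighting caveat above); CV cost grows as
grid × folds × p node solves, mitigated by the compiled kernel, screening
and warm active sets.
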