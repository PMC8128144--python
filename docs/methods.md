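# Methods

## Model overview and assumptions

The package treats drug repositioning as bipartite link prediction on a
binary association matrix Y (m drugs × n diseases), guided by two external
similarity matrices S_r (drugs) and S_d (diseases) with values in [0, 1],
symmetric, unit diagonal. The core assumption is the standard
guilt-by-association one: similar drugs treat similar diseases, and the
similarity matrices are informative about the association pattern. Three
base predictors exploit that assumption through different mechanisms
(diffusion, low-rank factorization, geometric projection); because their
errors are only partially correlated, a noisy-OR fusion of their
probabilities tends to dominate each component.

## Stages, parameters, defaults

### WKNKN completion

Zeros in Y are a mixture of true negatives and unobserved positives, and new
entities have all-zero profiles, which starves every downstream method. The
completion replaces each zero with a decay-weighted average of the profiles
of the K nearest *known* neighbors. Parameters: `K = 5` neighbors and decay
`T = 0.5` (dimensionless; the i-th ranked neighbor's similarity is
discounted by `T^(i-1)`, so ranks beyond ~5 are negligible anyway).
Conventions chosen where the formulas are silent:

* "known" = at least one association in the (training) matrix — required
  for the de-novo scenario to be meaningful;
* the entity itself is always excluded (its own empty profile must not leak
  back in);
* fewer than K known neighbors: use all available; none: leave the
  contribution at zero rather than fail;
* completion uses the *input* similarities, not the learned ones, because it
  precedes similarity learning in the pipeline;
* the merge is the elementwise `max(Y, Y_rd)`; since every likelihood
  profile is a sub-convex combination of [0, 1] vectors, the output stays in
  [0, 1] and recorded positives are preserved exactly.

### Linear neighborhood similarity

Feature vectors are the rows (drugs) / columns (diseases) of the *completed*
matrix. This keeps the pipeline self-contained: the learned graph reflects
interaction-profile geometry rather than raw chemistry, and profiles are
non-degenerate after completion. Per entity the package solves
`min ωᵀ(G + λI)ω` on the probability simplex, where G is the Gram matrix of
displacements to the K nearest neighbors (Euclidean metric, distance ties
broken toward the lower index, self excluded). Defaults `K = 100` (capped at
p − 1 so small problems remain solvable) and ridge `λ = 1`, which makes the
problem strongly convex and the minimizer unique.

Solver: FISTA with Euclidean projection onto the simplex (step `1/L`,
`L = 2·λ_max(G + λI)` from a dense symmetric eigensolve; monotone restart on
objective increase; stop when the iterate moves < 1e-12 and the objective is
stationary, cap 20 000 iterations). With λ = 0 and a singular Gram matrix
any feasible minimizer is accepted. Floating-point negatives are clipped at
0 and the row renormalized, preserving the simplex invariant. The stacked
weight matrix is used exactly as produced — row-stochastic and asymmetric.

### Label propagation (LPRIA)

Scores diffuse over the directed learned graph with absorption probability
`α = 0.5`: the default path solves the linear system
`(I − αS*)Y = (1 − α)Y⁰` directly (never forming an inverse), which is the
exact fixed point of the iteration; the iterative mode is retained and used
as an internal consistency oracle. Because S* is row-stochastic and Y⁰ in
[0, 1], every iterate is a convex combination and the output stays in
[0, 1]. The drug-side and disease-side propagations are averaged.

### Graph-regularized NMF (NMFRIA)

Objective: squared Frobenius reconstruction error plus Tikhonov penalties
(`λ_l = 2`) on both factors and Laplacian smoothness terms (`λ_r = λ_d =
1e-4`) tying factor rows to the learned similarity graphs. The learned
graphs are asymmetric, and `Tr(WᵀLW) ≥ 0` is only guaranteed for symmetric
graphs, so the graph terms use `S_sym = (S + Sᵀ)/2` with degrees
`D = rowsum(S_sym)` — the standard graph-regularization construction.
Latent rank `k = 100`, capped at `min(m, n) − 1`. Factors are initialized
uniformly on `[0, sqrt(mean(Y)/k)]` from a documented seed, so `WHᵀ` starts
at the data's scale. Multiplicative updates run until the relative objective
change drops below 1e-6 or 2000 sweeps, with denominators floored at 1e-12
to avoid 0/0 and factors floored at 0; the objective trace is recorded and
checked non-increasing in the tests. The reconstruction `WHᵀ` can exceed 1;
it is clipped at the fusion boundary, not rescaled, because clipping is
local and parameter-free and only affects scores already expressing
near-certainty.

### Network consistency projection (NCPRIA)

Exact zeros of the (completed) matrix are replaced by 1e-30 before
projecting, so no column or row is the zero vector; for genuinely empty
profiles this turns an undefined score into a similarity-mean value, which
is the intended semantics for unobserved-not-refuted pairs. All norms are
Euclidean. With non-negative entries each projection is bounded by
Cauchy–Schwarz, so the fused score lies in [0, 1]; a pair whose similarity
row *and* column are both entirely zero has no defined projection and is
reported as an error rather than silently scored.

### Fusion

`Rt = 1 − (1 − Y*)(1 − Y**)(1 − Y***)`. Properties relied on downstream and
asserted in tests: dominance (`Rt ≥ max` of the inputs), monotonicity in
each argument, permutation invariance, and range preservation.

## Evaluation protocol

* **Repeated K-fold CV** (default 10 × 10): known pairs are partitioned into
  near-equal folds per repeat. Each fold's training matrix is rebuilt *from
  the fold plan alone* (training pairs set to 1, everything else 0), so the
  harness is structurally incapable of reading held-out cell values — the
  leakage audit poisons held-out cells with sentinels and checks bit-equal
  reports. Completion and similarity learning are recomputed per fold from
  training data only. Positives = held-out pairs; negatives = all pairs
  unknown in the complete matrix; per-fold AUCs are averaged within repeats,
  then across repeats.
* **De-novo test**: each drug with ≥ 1 association has its entire row
  removed, the pipeline is re-run, and its removed associations are ranked
  against its unknown diseases. The headline AUC pools all drugs' positive
  and negative scores (a per-drug breakdown is returned alongside), since a
  single pooled number is the convention this harness reports.
* **AUC** is the trapezoidal area under the threshold-swept ROC, which
  equals the Mann–Whitney pairwise count with half credit for ties; the two
  routes are cross-checked to 1e-12, and against scikit-learn's
  `roc_auc_score` in the tests.

## Synthetic data generator

The generator emulates the structure of curated repositioning gold standards
(hundreds × hundreds, ~1–6 % density) without mimicking any real dataset's
degree sequence or chemistry. Each entity gets one dominant latent
"therapeutic theme" out of r, an exponentially distributed activity level,
and a 5 % uniform cross-theme background; association probabilities are
proportional to UVᵀ, rescaled by bisection (with clipping at 1) so the mean
equals the target density, and Y is sampled Bernoulli. Similarities are
cosines of the latent loadings plus symmetric Gaussian noise (sd σ), clipped
to [0, 1] with unit diagonal. Structure and noise use independent seeded
substreams, so σ can vary with the planted network held fixed.

The block-plus-activity design makes the planted probabilities graded and
heavy-tailed, the way annotation counts are in real data, and — unlike an
iid-factor design — leaves enough headroom between the Bayes-optimal scorer
and chance for recovery tests to be meaningful: at the reference conditions
(m = 150, n = 100, r = 6, density 0.06, σ = 0.1, 10 % of positives masked)
the truth-probability scorer reaches a hold-out AUC around 0.93 and the
fused pipeline around 0.85–0.90. What passing these tests shows is that the
pipeline recovers planted block structure from correlated similarities; it
does not certify performance on real pharmacological data, whose similarity
matrices are noisier and whose associations are not low-rank Bernoulli.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: equation-level oracle
checks on 5–8-entity instances, recovery at 150 × 100 (three seeded
replicates), cross-validation at 60 × 40 (5 folds × 2 repeats), de-novo at
30 × 20. These sizes exercise every code path — neighborhood caps, rank
caps, empty-profile branches — while keeping a full run in minutes on one
core; the method itself is dense-matrix bound and handles the
thousands-scale regime the defaults (K = 100, k = 100) were chosen for.

Degenerate inputs are handled deliberately: entities with no known neighbors
keep zero completion contributions; a single-entity similarity learning
problem is an error (no neighborhood exists); an empty matrix cannot be
written; association input must be strictly binary — completed matrices are
a distinct artifact, which prevents accidentally re-completing a completed
matrix.

## Known limitations

* Single drug similarity and single disease similarity; no multi-view
  fusion of heterogeneous similarity sources.
* The fusion rule is fixed noisy-OR; no learned ensemble weights.
* AUC is the only headline metric (no AUPR / precision@k).
* Chemical and phenotype similarity computation is out of scope: the tool
  consumes similarity matrices, it does not build them from SMILES or
  disease descriptions.
* The de-novo and CV aggregation conventions (pooled negatives from the full
  matrix; pooled de-novo AUC) are one defensible choice among several;
  absolute AUC values are not comparable across harnesses using different
  conventions.
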