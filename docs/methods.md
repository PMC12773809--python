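# Methods

## Model

The core model is sparse partial least squares discriminant analysis
(sPLS-DA) and its multiblock extension. For one block X (n samples ×
p features, column-centered) and the centered one-hot class indicator
Y, each component solves

    max_{u,v}  cov(X u, Y v)   s.t.  ‖u‖₂ = 1, ‖v‖₂ = 1, ‖u‖₀ = keepX,

by alternating u ∝ S(Xᵀ Y v), v ∝ Yᵀ X u, where S soft-thresholds at
the (keepX+1)-th largest magnitude: the keepX largest entries survive,
shrunk toward zero by that threshold, then the vector is renormalized.
This is the exact-cardinality operator the mixOmics family uses, and on
shared fixtures our loadings agree with mixOmics::splsda to machine
precision (asserted in the test suite through an Rscript oracle). With
keepX = p the threshold is zero and the iteration is the power method
on XᵀY YᵀX, so component 1 equals the dense PLS-DA singular vector.

After each component the block is deflated by regression on its score
t = X u (X ← X − t pᵀ, p = Xᵀt/tᵀt) and Y is deflated likewise, so
scores of successive components are orthogonal.

The multiblock model couples blocks through a symmetric design matrix
C with zero diagonal: block coordinate ascent maximizes
Σ_{i<j} c_ij t_iᵀ t_j + Σ_i c_iY t_iᵀ t_Y, updating
u_i ∝ S(X⁽ⁱ⁾ᵀ Σ_{j≠i} c_ij t_j) per sweep and the outcome loading
densely. Each block deflates on its own score; the outcome deflates
once per component on the mean block score, which makes the one-block
model reduce exactly to single-block sPLS-DA.

Two numerical points. First, the soft-threshold update maximizes an
L1-penalized surrogate, not the raw covariance objective, so a sweep
can (rarely, near convergence) decrease the monitored objective; the
fitter then reverts to the previous iterate and stops, so the recorded
objective history is non-decreasing by construction. Second,
convergence is declared when the largest loading change falls below
1e-6 (at most 100 iterations, after which a convergence error carrying
the iteration count is raised); for two-class problems the centered
indicator is rank one and the iteration converges in a handful of
steps.

Prediction is by the accumulated regression map (``max_dist``:
Ŷ = X_c W(PᵀW)⁻¹Cᵀ + ȳ, argmax over classes) or by nearest class
centroid in score space (``centroid_dist``); multiblock predictions
combine per-block class scores by averaging or per-block plurality
vote with an average fallback on ties. The combination scheme and
distance are options because neither is canonical.

## Tuning

The balanced error rate — the mean of per-class misclassification
fractions — drives all selection, making the minority class count
fully. Cross-validation is stratified k-fold (k = 5) with R freshly
seeded repartitions; per-fold class proportions deviate from the
global proportions by at most one sample.

The component count is searched over 1..6 (dense fits) and chosen by
a one-standard-error rule: the smallest H whose mean BER is within one
pooled standard error of the minimum. Note that for two classes the
class-mean contrast is one-dimensional, so a linear discriminant model
rarely needs more than one component on data whose classes differ only
in mean; multi-class problems genuinely drive H up, and the test suite
exercises that with a three-class fixture.

keepX is tuned greedily per component over either the single-omics
grid (3–300 with steps 3/6/15/30) or the nine-value integrative grid
(10–50 step 5). Because the BER surface is typically flat near its
optimum, the raw minimizer wanders over near-tied grid values; we
therefore apply the same one-standard-error parsimony rule per
component (smallest keepX within one SE of that component's minimum).
This concentrates the choice near the true signature size on synthetic
data and matches the parsimony intent of the workflow's tie-breaking
toward smaller keepX.

Selection stability is the per-feature frequency of nonzero loadings
over B stratified bootstrap refits at fixed (ncomp, keepX); stratified
resampling (within-class, with replacement) removes the possibility of
single-class resamples at small n.

## Network stage

Hidden Nodes scores each non-seed candidate v by the upper-tail
hypergeometric probability of drawing at least x_v seeds in k_v draws
(k_v = degree, population N = |nodes| − 1, successes K = |seeds|); the
population excludes the candidate itself for exchangeability. p-values
are BH-adjusted over all evaluated candidates (Bonferroni behind a
flag), scores are −log10(adjusted p), and adjusted p < 0.05 marks
significance. Seeds themselves are not scored by default.

Network propagation iterates F ← (1−r)WF + rF₀ with W the
column-stochastic adjacency (mass is conserved — a tested invariant),
restart r = 0.5, and F₀ uniform on the seeds. Significance comes from
permuted seed sets drawn within ten degree-quantile bins matching the
real seeds' bin composition, which controls hub bias; empirical
p = (1 + #{F_null ≥ F_obs})/(n_perm + 1), so p ≥ 1/(n_perm+1). The
top ⌈1% of nodes⌉ by score among non-seed candidates is retained.
The permutation null reuses the closed-form stationary solution
F = r(I − (1−r)W)⁻¹F₀, which matches the iteration to 1e−8.

The stability suite reports: the LCC-ratio robustness curve over
removal fractions 0.05–0.50 (20 replicates per fraction; the overall
score is the unweighted mean over fractions, exactly 1 − mean(f) for
complete graphs with integral removals); node criticality
(E(G) − E(G∖v))/E(G) with global efficiency E the mean inverse
shortest-path length (on large networks the sweep can be restricted to
the top-degree hubs, since each deletion costs an all-pairs BFS);
average path length on the LCC; mean local clustering (degree-<2 nodes
contribute 0); modularity Q from deterministic greedy (CNM)
agglomeration so Q is reproducible (seeded Louvain behind a flag);
Freeman degree and betweenness centralization; and the regulator
degree ratio plus mean normalized betweenness for regulators vs the
rest. Networks are undirected by default (interaction evidence is
bidirectional).

## Classification

Stratified 80/20 split with per-class largest-remainder rounding so the
totals hit round(n·0.2) (a 213/92 cohort gives 244/61). XGBoost
hyperparameters are grid-searched by mean stratified 5-fold CV AUC on
training data only (default grid: 100/300 trees, depth 2–4, learning
rate 0.05/0.1, subsample 0.8/1.0; ties prefer fewer trees, then
shallower trees). Final metrics on the held-out set are AUC (rank
statistic), and accuracy/sensitivity/specificity/F1 at threshold 0.5
(configurable), each with a 95% percentile-bootstrap CI over
class-stratified test resamples (B = 2000 by default). z-scoring is
fitted on training samples only; a poisoning test asserts that
held-out rows cannot influence the scaler or grid choice. External
validation intersects features by exact ID, refits on the training
data restricted to the intersection, and reports the per-modality
intersection inventory; missing features are dropped, not imputed.

## Synthetic data

The generator emulates the structure the analysis assumes: n samples
(default 300, 70/30 case/control to echo cohort imbalance) share
n_latent standard-normal latent components; the first n_disc_latent
columns are shifted by delta (default 1.5) for cases, so one latent
dimension separates classes with oracle AUC Φ(delta/√2) ≈ 0.86.
Signature features (default 20 per block) load on the components
round-robin with loadings uniform in ±[0.5, 1.5] (detectable but
heterogeneous); remaining features are pure noise. The methylation
block is Gaussian on the M-value scale directly (beta-valued input is
exercised separately through the beta→M transform); expression counts
are negative-binomial (gamma-Poisson, dispersion 0.4) around
exp(linear predictor) times log-normal library factors (σ = 0.3,
which the median-of-ratios step must remove); proteomics is Gaussian
on the log2 scale. The interaction network is preferential attachment
(800 nodes, 3 edges per arrival) over gene IDs shared with the
expression block; each planted regulator (default 15, chosen among
non-signature nodes) gains extra edges to signature nodes with
probability (bias−1)·attachment/n_signature per pair, so bias 1 is
exactly plain preferential attachment and the expected surplus of seed
neighbours per regulator is ≈ (bias−1)·attachment.

What the generator does **not** emulate: batch/plate structure,
clinical covariates, annotation-based identifier mapping, inter-block
correlation beyond the shared latent components (its magnitude is a
parameter, not a fixed value), or realistic interactome topology
beyond the scale-free degree law. Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions, not
performance on any real cohort.

## Problem sizes and determinism

Tests and the acceptance script run the study at desk scale chosen
once: 300 samples × three blocks (300/300/200 features), an 800-node
network, 20-seed medians for recovery experiments, 100–200
permutations/bootstraps where a null distribution is needed. All
randomness flows from a single seed through per-stage CRC32-derived
seeds, so any stage re-run in isolation reproduces its in-pipeline
stream and a full re-run is byte-identical in every report.

## Known limitations

- Identifier matching is exact string equality; no symbol↔probe
  mapping.
- The greedy per-component keepX search is not a full factorial
  search; interactions between components' budgets are ignored.
- The percentile bootstrap can be anti-conservative for AUC at very
  small test sizes.
- Networks are undirected throughout; interaction evidence from
  STRING-style exports is bidirectional, and a directed mode is out of
  scope.
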