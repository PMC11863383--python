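# Methods

## Model

### Two-class OPLS(-DA)

For a preprocessed predictor matrix **X** (n × p) and a centered response
vector **y**, the model is

    X = t_pred p_pred' + T_orth P_orth' + E
    y = q t_pred + f

with one predictive component and A_orth ≥ 0 orthogonal components. One
predictive component is a structural choice, not a tuning knob: a single
dummy response spans a one-dimensional predictive subspace, so nothing
beyond the first component can correlate with it.

With a single y the PLS weight has the closed form w = X'y/‖X'y‖, so no
NIPALS iteration is needed and fitting is bitwise deterministic. Each
orthogonal component is extracted classically: compute the loading p of the
current weight's score, remove the part of p along w, normalize to get
w_orth, score and deflate **X** by that component, repeat; the single
predictive component is extracted last from the deflated matrix. Deflating
by y-orthogonal components leaves X'y unchanged, which is why w_pred is
exactly orthogonal to every w_orth and the predictive weight never needs
recomputing.

Predictions of a model with a orthogonal components are identical to those
of an (a+1)-component PLS regression — the orthogonal split relocates
variation between parts without changing the fitted subspace. The test
suite asserts this identity to 1e-8 against scikit-learn's PLS over random
matrices, and the acceptance script against a self-contained textbook
NIPALS recursion; in practice agreement is at machine precision.

Predictions are returned on the original 0/1 dummy scale by adding back the
training response mean, so the 0.5-centered geometry of balanced problems
is literal.

### Cross-validation and component selection

Folds are stratified per class: a seeded within-class shuffle followed by
round-robin dealing from a seeded starting fold, so within-class fold
sizes differ by at most one and classes smaller than k still land in
distinct folds. Preprocessing (centering/scaling) and the response mean
are refit inside every fold; nothing about a held-out sample reaches the
model that predicts it. The per-sample held-out predictions ŷ_cv give
PRESS = Σ(y − ŷ_cv)² and Q² = 1 − PRESS/SS_y.

Orthogonal components are added sequentially and A+1 replaces A only when
Q²(A+1) − Q²(A) exceeds a gain threshold (default 0.01, `max_orth` 5), a
declared small-gain rule in the spirit of common chemometrics practice;
the search also stops when the data cannot support another component.
Selection is rerun independently for every pairwise model and every tree
node, because each sees a different class pooling and reusing a count
would bias PRESS.

### Cohen's d distances

For each unordered class pair, a one-vs-one model is fit on the pair's
samples only and d = |m₁ − m₀|/s_p is computed from the chosen model's
ŷ_cv, with s_p the pooled SD (denominator n₀ + n₁ − 2). The absolute
value makes d a dissimilarity; s_p = 0 (perfect noiseless separation) is
capped at 1e6 — any cap above realistic d values yields the same tree.
Pairs are visited lexicographically, so the distance matrix and the pair
log are reproducible artifacts.

### Clustering and the decision tree

The class-distance matrix is clustered agglomeratively with Lance–Williams
updates (single/complete/average/Ward; default average/UPGMA, the
least-assumption choice for a non-Euclidean dissimilarity — Ward is
offered but is nonstandard for such input). Merge-height ties are broken
by the lexicographically smallest member class, and the child whose
smallest member sorts first becomes the left child, so the tree and its
Newick export are deterministic. Heights are raw Cohen's d values, no
rescaling. Newick branch lengths are parent height minus child height.

Each internal node then gets a fresh OPLS-DA model over the pooled classes
of its two subtrees (left = dummy 0, right = dummy 1), with its own
component selection. Split models are refit on the pooled groups rather
than reusing pairwise models, because a split discriminates
groups-of-classes that no pairwise model represents. The decision
threshold is the midpoint of the two training-group mean fitted responses
— not a fixed 0.5, which is only principled for balanced groups, and
pooled nodes are typically unbalanced. A prediction exactly at the
threshold routes right (the dummy-1 side); any fixed rule works, this one
is declared for determinism. Splits are numbered 1..N−1 by decreasing
dendrogram height, so split #1 is the top split. Every split always
classifies; per-node Q² is surfaced in logs rather than used to refuse
predictions.

### Interpretation surfaces

Volcano tables use Welch's unequal-variance two-sided t-test and a ratio
fold change on the original (unscaled) data reported as log2; the
significance gate is the conjunction p < 0.01 and >2-fold (both
configurable), on raw p-values. A Benjamini–Hochberg q-value column is
emitted for users who want FDR control, but it does not enter the default
gate. Variables with a nonpositive group mean cannot carry a ratio fold
change; they are flagged and excluded from the gate rather than silently
dropped. Score tables report per-sample cross-validated predictive scores
(plus the first orthogonal cv-score when one exists) and per-class 95%
Hotelling's T² regions: radius² c = p(n−1)/(n−p)·F_{p,n−p}(0.95), ellipse
semi-axes √(λᵢc) along the score-covariance eigenvectors, degenerating to
the interval ±s√(F_{1,n−1}(0.95)) when only one score dimension exists.

## Preprocessing

Default unit-variance scaling with mean centering (the de facto
chemometrics default), configurable to center-only, Pareto, or none.
Scales are sample SDs floored at 1e-12, so constant columns survive as
(effectively) all-zero columns instead of being dropped and
desynchronizing variable names. Missing values are rejected at load time
with a cell-addressed error; an opt-in flag imputes column means.
Spectral pretreatments (SNV, derivatives, baseline correction) are out of
scope.

## Synthetic data generators

`make_iris_like` draws three isotropic Gaussian classes in 2-D with
exactly collinear means (petal-like centroids at (1.46, 0.25),
(4.24, 1.46), (5.55, 2.03); SDs 0.15/0.35/0.40): one compact outlying
class and two adjacent overlapping ones, separated along the same
direction at different scales. This is the geometry where one-vs-rest
boundaries with a common center fail while two hierarchical cuts succeed.

`make_hierarchical` generates class means by walking a declared binary
grouping tree: each split displaces its two subtrees by ±(between_scale ·
level_decay^depth) along a seeded unit direction, successive directions
orthogonalized against all earlier ones while dimensions remain. Opposed
offsets and orthogonal level subspaces are deliberate: they make sibling
separation at depth k exactly 2·between_scale·level_decay^k (in within-SD
units) instead of a random quantity that collapses when two directions
happen to align, so recovery tests score the method, not the luck of the
draw. Samples add isotropic Gaussian noise (within_sd); appended
standard-normal noise columns exercise scaling and component selection.
The 12-class convenience spec (4 groups × 3 subclasses, n = 28 per class,
12 informative + 4 noise variables, between_scale 5, within_sd 1, decay
0.5) mirrors a two-level design where one source of variation (e.g.
sample state) dominates another (species), scaled down from its
real-world analogue of roughly a hundred samples per class to keep test
runtimes in seconds.

What the generators do not emulate: correlated or heteroscedastic noise,
heavy tails, batch effects, and realistic spectral line shapes. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the intended class geometries, not robustness to every artifact of
real instrument data.

## Numerical choices and degenerate inputs

- NIPALS is replaced by closed forms throughout (single response), making
  fits bitwise reproducible; model JSON round-trips preserve predictions
  exactly.
- Component extraction raises a rank error naming the bound when the
  requested count exceeds min(n − 2, p − 1) or when the remaining
  orthogonal variation is numerically zero (relative norm < 1e-10);
  selection treats that as "stop", a direct fit propagates it.
- A constant response or a response with no covariance in X raises a
  degenerate-response error.
- Cohen's d with equal means and zero pooled SD is 0; distinct means with
  zero pooled SD return the cap.
- Welch p-values are floored at 1e-300 to stay in (0, 1]; two constant
  equal groups give p = 1 by convention.
- All randomness flows through named integer seeds (cv_seed, generator
  seeds); there is no hidden global state.

## Known limitations

- Cohen's d estimated from a few dozen cv-predictions is noisy; with
  small classes the dendrogram's fine structure (the lowest merges) can
  vary between seeds even when the coarse structure is stable. More
  samples per class tightens it.
- The linkage choice can change tree topology on real data with ambiguous
  structure; it is a first-class config option for that reason.
- No rejection option: a sample from a class never seen in training is
  still routed to some leaf. Path records (per-node ŷ and direction) are
  emitted so such cases can be audited.
- Multi-response OPLS, O2PLS, kernel variants, probability calibration,
  and nested cross-validation for unbiased accuracy estimation are out of
  scope.
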