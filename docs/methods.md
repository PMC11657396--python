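# Methods

## The gamma-metric

Given observations `X_i ∈ R^p` with class labels `Y_i ∈ {1..K}`, each class
`k` is summarized by an ellipsoid: its centroid is the class mean `μ_k` and
its shape is the class covariance `W_k` (unbiased denominator `n_k − 1`),
whose eigenvectors give the axis directions and whose eigenvalues the squared
semi-axis lengths.  For one pair of classes the score is

```
γ(k, l) = ‖μ_l − μ_k‖ − r_k(u) − r_l(−u),      u = (μ_l − μ_k) / ‖μ_l − μ_k‖,
```

the centroid distance minus each ellipsoid's centroid-to-border distance along
the inter-centroid direction.  For `K > 2` the pairwise values are summed.
A negative value signals that the two (scaled) ellipsoids overlap along the
joining line; well-separated classes give positive values.  The metric is
symmetric in the pair, invariant to translating all observations, equivariant
under a common rotation, and invariant to observation order.

**Border-distance convention.**  The centroid-to-border distance is the
support radius of the covariance ellipsoid,

```
r(u) = scale · sqrt(uᵀ W u) = scale · sqrt(Σ_j λ_j (uᵀ u_j)²),
```

with `scale = 1` by default: one standard deviation of the class distribution
projected on `u`.  Several geometric readings of "border distance" exist
(the true boundary intersection `(uᵀW⁻¹u)^(−1/2)`, eigenvalue-as-length
variants, quantile-scaled ellipsoids); the support radius is adopted because
it is the unique choice among them that is simultaneously cheap (no eigen-
decomposition or solve in the inner search loop), exactly even in `u`, and
reproduces every qualitative property the metric is designed for (sign
encodes overlap, the listed invariances).  The `gamma_scale` knob rescales
every semi-axis (`semi-axis = scale · sqrt(λ)`) for users who prefer, e.g., a
two-sigma ellipsoid; changing it changes which borderline features a search
accepts.

Degenerate cases are pinned down explicitly: coincident centroids return
minus the sum of both radii along the first ellipsoid's principal axis (full
overlap, hence negative); eigenvalues in `[−1e−10, 0)` from rank-deficient
empirical covariances are clipped to zero so radii stay real; anything more
negative raises.

**Covariance estimation.**  With `estimator="auto"` (default) the empirical
estimate is used unless *any* class has fewer observations than the subset
size, in which case the Schäfer–Strimmer shrinkage estimate is used for
*every* class: sample correlations are shrunk toward zero and variances
toward their median, each with the analytic intensity
`λ* = Σ Var(r_ij) / Σ r_ij²` clipped to `[0, 1]`.  Shrinkage keeps all
ellipsoids positive definite in the `p > n_k` regime.  The trigger is global
(one undersized class switches all classes) so that the two ellipsoids of a
pair are always estimated the same way.

**Fast evaluation.**  Subset search needs thousands of evaluations, so
`GammaEvaluator` precomputes per-class means, full empirical covariances and
the shrinkage pair statistics once; any subset's score is then a slice plus
one quadratic form per class pair, numerically identical to the reference
path (the shrinkage intensity of a subset depends only on pairwise statistics
of its own columns, so slicing is exact).

## Subset search

Three greedy strategies maximize an arbitrary subset score under a *strict*
improvement rule (exact float `>`, no tolerance):

* **forward** — start from the best singleton, add the best single feature
  while it strictly improves the score;
* **backward** — start from the full set, remove the best single feature
  while it strictly improves; never evaluates the empty set;
* **best-first** — forward expansion plus a priority queue of every
  evaluated-but-unexpanded subset; on a dead end it resumes from the best
  queued subset, up to `max_backtracks` times (default 5, the convention of
  the R feature-selection ecosystem), and returns the best subset found.

Ties are broken toward the lowest added (or removed) feature index, making
all searches fully deterministic.  With `max_backtracks = 0` best-first
coincides with forward; its score can never be lower than forward's.

## Synthetic study conditions

Labels follow a logistic model `ρ_i = expit(β₀ + x_iᵀβ)`, `Y_i ~
Bernoulli(ρ_i)`; features are unit-variance Gaussians.  Three regimes:

| condition | n | features | effects |
|---|---|---|---|
| `s1` | 2000 | 3 informative + 22 independent null | β = (3, −2, 0.5), β₀ = 0 |
| `s2_{bal,unbal}_{strong,weak}` | 100 | 3 informative + 197 null | strong: (3.6, −2.2, −1.0) / (3.6, −4, −1); weak: (0.6, −2.5, −1); β₀ ∈ {0, 0.5, −2.65, −2.75} |
| `s3_{const,decay}_{09,06,03}` | 2000 | 10 groups of 10, first of groups 1–5 and 10 informative | β = 1.5, β₀ = 0 |

In the third regime the feature covariance is block diagonal: constant
blocks have off-diagonal `α_max ∈ {0.9, 0.6, 0.3}`; decaying blocks have
`α_ij = α_max exp(−w(|i − j| − 1))` with `w = log(α_max / c)/(s_g − 2)` so the
first-to-last in-group correlation equals the floor `c ∈ {0.35, 0.25, 0.1}`
exactly (the construction only bounds it; equality fixes `w` uniquely).
Group 10 is left at the identity.  Each condition yields an independent
train/validation pair of equal size; a draw landing every observation in one
class (possible under strong imbalance at n = 100) is redrawn, at most 100
times.  Feature variance in the first two regimes is set to 1, consistent
with the third regime's construction.

What the generator does *not* emulate: non-Gaussian margins, heteroscedastic
classes, label noise beyond the Bernoulli link, and missing data — passing
tests therefore speak to the selectors' behavior under a clean logistic-
Gaussian world, not to robustness on messy real data.

## Evaluation indicators

A selected subset is judged by an unpenalized binomial logistic regression
fit on the training half and applied to the validation half: trapezoidal ROC
AUC; sensitivity and specificity at the cutoff maximizing Youden's
`Se + Spe − 1` (thresholds scanned at midpoints between consecutive distinct
scores plus ±∞ sentinels; ties resolved toward the lowest cutoff, i.e. the
most sensitive operating point — with constant scores this yields (1, 0));
counts of selected informative (NSIF) and non-informative (NSNIF) features
against the generator's truth; the mean pairwise Jaccard similarity of the
selected sets across repetitions (empty-vs-empty counts as 1); and the
selection wall-time alone (model fitting excluded).  Perfect separation in
the logistic fit is accepted — probabilities saturate.

## Baseline selectors

Filter scores are computed from their formulas on equal-frequency
discretized features (`max(2, ceil(log₂ n) + 1)` bins by default — a
simpler, configurable stand-in for MDL-based discretization): Cramér's V
from the χ² statistic (`V = sqrt(χ²/(n · min(r−1, c−1)))`), symmetrical
uncertainty (`2·IG/(H(X)+H(Y))`, entropies in bits, zero cells contributing
nothing), and the CFS merit `k·r̄_cf / sqrt(k + k(k−1) r̄_ff)` maximized by
best-first search.  Ranking filters keep the head of the ranking up to the
largest drop between consecutive sorted scores, so the selected count is
data-driven.  Note the merit of a set of equally class-correlated features is
non-decreasing in `k` whenever their mutual redundancy is below 1; a
perfectly redundant copy leaves it exactly unchanged (and strict improvement
then refuses it).

Model-based baselines are contracts over standard fits: L1-logistic
regression with the penalty chosen by stratified cross-validated deviance
under the one-standard-error rule; random-forest permutation importance
(mean accuracy decrease) with the gap cutoff; bidirectional stepwise AIC
(`AIC = −2 logLik + 2(k+1)`) from the intercept-only model; linear-SVM
recursive feature elimination removing one smallest-|weight| feature per
round and keeping the smallest subset maximizing cross-validated accuracy.

## Method ranking

The per-method indicator vectors (AUC, Se, Spe, NSIF, NSNIF, stability,
runtime) are ranked by TOPSIS with vector (Euclidean) normalization — the
standard variant, adopted as the package's convention — weights
`(8 − rank)/28` for ranks 1..7 (0.2500 … 0.0357) and NSNIF/runtime treated
as costs.  An alternative coinciding with the ideal point scores 1;
identical alternatives score 0.5 by convention; zero-norm criterion columns
are dropped with a warning.  Runtime is hardware-dependent, so reproduced
ranks can differ from any published ones on runtime-dominated margins.  The
no-selection reference (`full`) is reported but excluded from ranking.

## HRV application

60-second RR segments yield sixteen standard HRV features (definitions in
`gammafs.hrv`).  Conventions the literature leaves open are fixed as:
histogram bin width 1/128 s for TINN and the HRV index (TINN's triangular
fit is optimized exactly — the squared error separates into a left part
depending only on the base start and a right part only on the base end);
derivative features use forward differences with the unbiased SD; 5-second
sub-windows are defined by cumulative time with trailing partials dropped
and are undefined (NaN) when fewer than two complete windows exist;
difference-based features never cross segment boundaries.

The synthetic rhythm generator stands in for non-redistributable clinical
Holter data.  NSR is an AR(1)-correlated interval (φ = 0.9, stationary SD
50 ms) around a subject-level baseline near 0.89 s; AF is an i.i.d.
two-component Gaussian mixture (0.75·N(0.67, 0.09²) + 0.25·N(0.91, 0.12²),
clipped at 0.25 s) with mean 0.73 s, segment SDNN near 145 ms and pNN50 near
75%.  These targets mirror the reported AF/NSR group contrast of real Holter
segments; the generator does not emulate ectopic beats, artifacts, or
intermediate rhythms, so results on it bound what the pipeline can do on
clean rhythms only.

## Problem sizes and numerical choices

The bundled study runs use 50 repetitions for the classical regime and 20–25
for the high-dimensional and block-correlated regimes (5 for the backward
search in the 200-feature regime, whose cost is two orders of magnitude
above the forward search there); these sizes keep each full run in the
minutes range on a single core while leaving Monte-Carlo standard errors
well below the effect sizes of interest.  Repetition `r` owns seed
`base_seed + r`, so parallelism cannot change results.  All tolerances used
in comparisons of Monte-Carlo means combine the re-run's standard error with
a lower bound on the source value's (for integer-valued indicators, the
minimal variance consistent with the printed mean).

## Known limitations

* The border-distance convention is a documented choice among several
  geometrically defensible readings; selection counts — especially how many
  borderline or correlated null features a search accepts before stopping —
  are sensitive to it, and `gamma_scale` only rescales radii, which does not
  change the per-dimension behavior.  Under strong class separation (γ > 0)
  the strict-improvement rule accepts many weakly contributing features,
  because adding a feature that duplicates existing signal scales the
  centroid distance and the radii nearly proportionally.
* The gamma-metric requires numeric features; categorical features are out
  of scope.
* Backward search from a large feature set is the slowest path
  (O(p) shrinkage evaluations per removal) and can terminate far from the
  forward solution — it removes features only while single removals strictly
  improve, which stalls early when individual null features barely move the
  score.
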