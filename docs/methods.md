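# Methods

## The selection problem

Given an M x N expression matrix with binary sample labels y_m in {-1, +1}
and a partition of the N features into G groups (correlation clusters,
pathways, GO terms, ...), the goal is to pick exactly one *representative*
feature per group such that the selected features are *jointly*
discriminative.  Selecting the best feature of each group separately ignores
interactions across groups and can be strictly worse — the packaged 8x4 toy
dataset is a minimal demonstration (see the README).

Formally the problem is a binary program: minimize a convex data-fit loss
L1(w) subject to w_i^g in {0,1} and sum_i w_i^g = 1 per group.  The
relaxation used here keeps w >= 0 and replaces the combinatorial constraints
by two coupled conditions per group — the weights sum to one (an l1-type
condition) and the maximum weight equals one (an l-infinity-type condition);
their intersection forces a one-hot pattern.  Both are moved into the
objective with multipliers:

    F(w) = L1(w) + lambda1 * sum_g (sum_i w_i^g - 1)^2
                 + lambda2 * sum_g (1 - max_i w_i^g),    w >= 0.

The max is bounded below by the smooth log-sum-exp,
max_i w_i^g >= log sum_i exp(w_i^g) - log N_g, giving the convex function
L3(w) = -sum_g (1 - logsumexp(w^g) + log N_g) and the difference-of-convex
objective F = L1 + lambda1*L2 - lambda2*L3.

## CCCP outer loop

The convex-concave procedure linearizes the concave part -lambda2*L3 at the
current iterate w^t.  The gradient of L3 is the group-wise softmax of w, so
each outer iteration minimizes the convex surrogate

    J(w) = L1(w) + lambda1*L2(w) - lambda2 * w . softmax_groups(w^t),  w >= 0,

which upper-bounds F up to a constant; minimizing it cannot increase F
(majorize-minimize).  Convergence is monitored on F itself: the loop stops
when the relative decrease of F falls below `tol_outer` (1e-6) or after
`max_outer` (50) iterations.  Initialization is w_i = 1/N_g, which satisfies
the sum condition exactly and is symmetric, so the data alone determine the
first move.  The softmax term creates a rich-get-richer feedback across
outer iterations: whichever feature leads a group is rewarded, which is what
eventually drives every group toward a one-hot pattern.

## Losses

Two convex data-fit terms are provided; both expose value, gradient and a
diagonal Hessian approximation, which is all the inner solver uses.

* **logistic** (default): L1 = sum_m log(1 + exp(-y_m s_m)) with
  s_m = sum_i w_i x_mi.  No intercept: the weights act as a soft selector,
  not a classifier.  Overflow-safe via logaddexp/expit.  Diagonal curvature
  sum_m x_mi^2 sigma(s_m)(1 - sigma(s_m)).
* **class_separation**: L1 = -c'w, linear in per-feature Fisher-like
  relevance scores c_i = |mean_+ - mean_-| / (sd_+ + sd_- + 1e-8), rescaled
  to [0, 1].  Its curvature is identically zero, so the diagonal is floored
  at eps_H = 1e-6.

## BCGD inner solver

The surrogate is minimized by block coordinate gradient descent over the
nonnegative orthant.  One iteration is one *sweep*: the solver identifies
the groups to process (all of them on the first sweep and on every T-th
sweep, T = 5; otherwise only the non-frozen ones), then for each group in
turn repeats up to `max_block_steps` (10) model steps:

1. Build the quadratic model of J restricted to the group at the current
   point.  The loss curvature is the diagonal approximation; the sum
   penalty's curvature is the exact rank-one matrix 2*lambda1*ones*ones'.
   The model Hessian is diag(h) + 2*lambda1*ones*ones' with h the full
   diagonal of J — deliberately an upper bound of the penalty curvature, so
   steps are damped rather than Newton-exact and a group moves at a rate
   proportional to its gradient signal.  A purely diagonal model is not
   usable here: it underestimates the curvature of any sum-changing move by
   a factor ~N_g, the line search then collapses the step, and iterates
   oscillate around the sum constraint.
2. Solve the model subject to w + d >= 0 by the Sherman-Morrison identity
   with *pinning*: coordinates whose model step would cross zero are fixed
   at the bound and the reduced rank-one system is re-solved (up to 4
   passes).  Plain clipping instead of pinning inflates the group sum and
   stalls the search.
3. Backtracking Armijo line search (c = 1e-4, shrink 0.5) on the true J
   along the block direction; accepted steps never increase J.
4. Commit the block update; cached sample scores and group sums make a
   whole sweep cost about one gradient evaluation, O(M*N).

Sequential (Gauss-Seidel) processing matters: each group's line search sees
the score shifts committed by the groups before it, which a simultaneous
full-vector step cannot (the representatives all correlate with the label,
so the loss has strong cross-group curvature along that direction that a
diagonal model misses).  Re-building the model after every block step also
lets thin chance advantages of background features fade while a genuinely
discriminative feature keeps climbing.

The sweep loop stops when the relative decrease of J falls below
`tol_inner` (1e-6), when no block can move on a full sweep, or at
`max_inner` (500) sweeps.

### Active sets

After each sweep every group is checked for *stability*: the leading weight
at least tau_max = 0.7, every other weight at most tau_rest = 0.3, and the
leading feature unchanged for `stability_patience` = 2 consecutive checks
(the first qualifying check opens the streak).  A stable group is frozen —
excluded from subsequent sweeps except the every-T-th full sweeps — because
continuing to optimize it only polishes the leading weight toward 1 without
changing which feature leads.  Frozen state persists across outer
iterations.  The thresholds are deliberately permissive (a 0.8/0.2 split
counts as settled); they are configurable in `SolverConfig`.

Diagnostics record, per group, the outer iteration during which it froze
("stabilization iteration"; groups that never froze report the total number
of outer iterations) plus the sweep index within that solve.  Outer-
iteration granularity is used for reporting because each outer iteration
solves one convex subproblem to tolerance — it is the natural unit of
"how long the optimizer needed this group".

### Projected-gradient reference

`projected_gradient_minimize` is a deliberately plain full-vector projected
gradient method with the same Armijo rule and stopping criteria, no
quadratic model and no active sets (its accepted step warms up from the
previous iteration).  It is slower but structurally independent, and the
test suite requires both solvers to produce identical selections on planted
data.

## Synthetic data

The generator plants one representative feature per group: the indicator of
the positive class (1 where y = +1, 0 where y = -1), with exactly
round(fraction*M) samples flipped (x -> 1-x), chosen uniformly without
replacement, so a stated noise level of 10 % is literally true per group.
All other features are fair 0/1 coin flips independent of the label.
Labels are balanced (M/2 per class).  The graded-noise design splits the G
groups into ten consecutive blocks with flip fractions 0, 0.10, 0.15, ...,
0.50.  A continuous mode (standard-normal background, representative =
label + Gaussian noise matched to a flip-equivalent sign-error rate) is
available for experiments with continuous data.

Binary indicator data is consumed *raw* (standardize=False) in the
simulation studies.  This is a deliberate modeling choice: with
nonnegative weights and no intercept, raw indicators keep the negative
class at low scores, so the logistic loss keeps discriminating within
groups no matter how many groups have already concentrated.  Centering the
columns (or coding the features as +/-1) makes both classes' margins grow
with the number of concentrated groups, and on wide problems the loss
saturates before late groups have resolved — an artifact of the coding, not
of the method.  For continuous expression data the model's default
standardization (per-feature z-scoring, population variance, zero-variance
columns mapped to zero with a warning) remains appropriate, and the toy
worked example also runs standardized: on raw 0/1 values a nonnegative
score cannot express "absence of evidence", and the jointly optimal pair is
only optimal for the logistic loss after centering.

What the generator does not emulate: probe-level noise, batch effects,
correlated background features, unbalanced classes, continuous expression
distributions.  Passing tests therefore show that the optimizer solves the
selection problem it was posed, not that the method is robust to real
microarray artifacts.

## Grouping by correlation

When no prior grouping is supplied, features are clustered by agglomerative
hierarchical clustering with average linkage on the distance 1 - |r|
(Pearson), cut to exactly G clusters (`scipy.cluster.hierarchy.cut_tree`).
|r| makes the grouping invariant to feature sign flips; zero-variance
features sit at distance 1 from everything.  The N x N distance matrix
limits this path to a few thousand features; known partitions are loaded
from a two-column TSV instead.

## Numerical choices and degenerate inputs

- lambda1 = lambda2 = 100 (defaults): large enough that the one-per-group
  structure dominates the data-fit term without erasing it.
- Overflow-safe log-sum-exp (group-max subtraction) everywhere.
- Ties in per-group argmax break to the lowest feature index; brute-force
  enumeration ties break to the lexicographically smallest index tuple.
- Final weights commonly overshoot 1 slightly (~1 + lambda2*s/(2*lambda1));
  the selection is the per-group argmax, which is unaffected.
- Labels: any two-class labeling is remapped, lexically smaller class to
  -1; constant labels, missing values and ragged rows are rejected.
- The discrete misclassification criterion rejects continuous features.
- The brute-force oracle enumerates at most 10^6 combinations.

## Problem sizes used in the checks

The shipped test suite runs the graded-noise design at its full width
(M=100, G=200, N_g=100 -> 20,000 features; about 5 s), a recovery grid over
N in {10^3, 10^4} x G in {10, 50, 100} x 5 seeds with both inner solvers
(about 40 s), and 100 small instances against exhaustive enumeration.
Million-feature runs and wall-clock comparisons between solvers are out of
scope: timing claims are hardware-bound, so speed is observed but never
asserted.

## Known limitations

- CCCP converges to a local solution of the DC program; on noisy groups the
  selected feature can depend on the iteration path.  The oracle-agreement
  test bounds this effect on small instances (>= 95 % agreement).
- The correlation-clustering path materializes an N x N matrix.
- The class-separation loss is a per-feature filter inside the joint
  machinery: it carries no cross-feature information, so joint and separate
  selection coincide under it (used as a test oracle precisely for that).
- Stability thresholds are heuristics; pathological weight patterns (two
  near-equal leaders) are deliberately never marked stable and such groups
  run to the iteration cap.
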