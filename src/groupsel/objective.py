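"""The penalized difference-of-convex objective and its CCCP outer loop.

The one-per-group selection problem is the combinatorial program

    minimize L1(w)  s.t.  w_i^g in {0,1},  sum_i w_i^g = 1  for every group g.

Relaxing to w >= 0 with the two coupled conditions "group weights sum to 1"
(an l1-type condition) and "group max equals 1" (an l-infinity-type
condition) and moving both into the objective with multipliers lambda1,
lambda2 gives

    F(w) = L1(w) + lambda1 * L2(w) - lambda2 * L3(w),      w >= 0,

where L2 = sum_g (sum_i w_i^g - 1)^2 penalizes the sum condition and the max
is bounded below by the smooth log-sum-exp,
max_i w_i^g >= logsumexp(w^g) - log N_g, so that

    L3(w) = - sum_g (1 - logsumexp(w^g) + log N_g)

is convex and F is a difference of convex functions.  The convex-concave
procedure (CCCP) linearizes -lambda2*L3 at the current iterate w^t (the
gradient of L3 is the group-wise softmax of w) and minimizes the convex
surrogate

    J(w) = L1(w) + lambda1*L2(w) - lambda2 * w . softmax_groups(w^t)

subject to w >= 0, yielding monotone descent on F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GroupStructure, LabeledMatrix
from .losses import EPS_HESSIAN, LogisticLoss, LossEval, get_loss
from . import solver as _solver


@dataclass
class PenaltyParams:
    """Multipliers for the two relaxed constraints.

    lambda1 weights the squared sum-to-one deviation, lambda2 the max-equals-
    one reward.  Both default to 100, large enough relative to the data-fit
    term that the one-per-group structure dominates without being so large
    that the loss stops mattering.
    """
    lambda1: float = 100.0
    lambda2: float = 100.0

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")


@dataclass
class CccpState:
    """One outer iterate: weights w^t and the linearization vector
    s^t = dL3/dw at w^t (a probability vector within each group)."""
    t: int
    w: np.ndarray
    s_t: np.ndarray
    objective: float
    converged: bool = False


def l2_penalty(w: np.ndarray, groups: GroupStructure):
    """L2 = sum_g (sum_i w_i^g - 1)^2 and its gradient."""
    r = groups.sums(np.asarray(w, dtype=float)) - 1.0
    return float(r @ r), 2.0 * groups.expand(r)


def l3_value(w: np.ndarray, groups: GroupStructure) -> float:
    """L3 = -sum_g (1 - logsumexp(w^g) + log N_g), overflow-safe."""
    lse = groups.logsumexp(np.asarray(w, dtype=float))
    return float(-np.sum(1.0 - lse + np.log(groups.sizes)))


def l3_gradient(w: np.ndarray, groups: GroupStructure) -> np.ndarray:
    """dL3/dw: the group-wise softmax of w (positive, sums to 1 per group)."""
    return groups.softmax(np.asarray(w, dtype=float))


def maxbound_check(w: np.ndarray, groups: GroupStructure,
                   slack: float = 1e-12) -> bool:
    """Test oracle: max_i w_i^g >= logsumexp(w^g) - log N_g in every group."""
    w = np.asarray(w, dtype=float)
    return bool(np.all(groups.maxima(w)
                       >= groups.logsumexp(w) - np.log(groups.sizes) - slack))


class CccpSubproblem:
    """The convex surrogate J for a fixed linearization vector s_t.

    Exposes ``value(w)`` (cheap, for line searches) and ``eval(w)`` returning
    (J, gradient, hessian_diag).  The linear term -lambda2 * w.s_t contributes
    -lambda2*s_t to the gradient and nothing to the curvature; the L2 term
    contributes the constant 2*lambda1 to every diagonal entry.
    """

    def __init__(self, loss, groups: GroupStructure, params: PenaltyParams,
                 s_t: np.ndarray):
        self.loss = loss
        self.groups = groups
        self.params = params
        self.s_t = np.asarray(s_t, dtype=float)
        # exact per-group rank-one curvature of the L2 penalty, used by the
        # BCGD direction model (the loss curvature stays diagonal)
        self.rank1_coeff = 2.0 * params.lambda1

    def value(self, w: np.ndarray) -> float:
        l2v, _ = l2_penalty(w, self.groups)
        return (self.loss.value(w) + self.params.lambda1 * l2v
                - self.params.lambda2 * float(w @ self.s_t))

    def block_context(self, w: np.ndarray) -> "BlockContext | None":
        """Start a Gauss-Seidel sweep at w (mutates w in place via commits);
        None when the loss has no efficient block form."""
        if isinstance(self.loss, LogisticLoss) or hasattr(self.loss, "c"):
            return BlockContext(self, w)
        return None

    def eval(self, w: np.ndarray):
        le: LossEval = self.loss(w)
        l2v, l2g = l2_penalty(w, self.groups)
        J = (le.value + self.params.lambda1 * l2v
             - self.params.lambda2 * float(w @ self.s_t))
        grad = (le.gradient + self.params.lambda1 * l2g
                - self.params.lambda2 * self.s_t)
        hess = le.hessian_diag + 2.0 * self.params.lambda1
        return J, grad, hess


class BlockContext:
    """Incremental state for Gauss-Seidel block updates over one sweep.

    Caches the sample scores (for the logistic loss), the per-group weight
    sums and the running subproblem value so that updating one group costs
    O(M * N_g) and a full sweep over all groups costs no more than one
    global gradient evaluation.  Scores are recomputed from scratch at the
    start of every sweep so incremental float error cannot accumulate.
    """

    def __init__(self, sub: "CccpSubproblem", w: np.ndarray):
        self.sub = sub
        self.w = w                                   # mutated in place
        self.groups = sub.groups
        loss = sub.loss
        self.score_based = isinstance(loss, LogisticLoss)
        if self.score_based:
            self.scores = loss.X @ w
            self.loss_value = float(np.logaddexp(0.0, -loss.y * self.scores).sum())
        else:
            self.loss_value = loss.value(w)
        self.S = self.groups.sums(w)
        r = self.S - 1.0
        self.J = (self.loss_value + sub.params.lambda1 * float(r @ r)
                  - sub.params.lambda2 * float(w @ sub.s_t))

    def group_model(self, g: int):
        """Gradient and loss-curvature diagonal restricted to group g's
        coordinates, at the current (already partially updated) point."""
        sub = self.sub
        cols = self.groups.indices(g)
        if self.score_based:
            loss = sub.loss
            Xg = loss.X[:, cols]
            from scipy.special import expit
            p = expit(-loss.y * self.scores)
            grad_loss = Xg.T @ (-loss.y * p)
            q = expit(self.scores)
            curv = np.maximum((Xg ** 2).T @ (q * (1.0 - q)), EPS_HESSIAN)
        else:
            grad_loss = -sub.loss.c[cols]
            curv = np.full(cols.size, EPS_HESSIAN)
        grad = (grad_loss + 2.0 * sub.params.lambda1 * (self.S[g] - 1.0)
                - sub.params.lambda2 * sub.s_t[cols])
        return cols, grad, curv

    def phi(self, g: int, cols: np.ndarray, d_g: np.ndarray):
        """J along the block direction: a callable alpha -> J(w + alpha*d_g
        on group g), evaluated in O(M)."""
        sub = self.sub
        delta_sum = float(d_g.sum())
        lin = float(sub.s_t[cols] @ d_g)
        r_g = self.S[g] - 1.0
        if self.score_based:
            u = sub.loss.X[:, cols] @ d_g
            y = sub.loss.y

            def phi(alpha: float) -> float:
                lv = float(np.logaddexp(0.0, -y * (self.scores + alpha * u)).sum())
                rg = r_g + alpha * delta_sum
                return (self.J - self.loss_value + lv
                        + sub.params.lambda1 * (rg * rg - r_g * r_g)
                        - sub.params.lambda2 * alpha * lin)
            phi.u = u
        else:
            c_g = sub.loss.c[cols]
            dl = float(-(c_g @ d_g))

            def phi(alpha: float) -> float:
                rg = r_g + alpha * delta_sum
                return (self.J + alpha * dl
                        + sub.params.lambda1 * (rg * rg - r_g * r_g)
                        - sub.params.lambda2 * alpha * lin)
            phi.u = None
        phi.delta_sum = delta_sum
        return phi

    def commit(self, g: int, cols: np.ndarray, d_g: np.ndarray,
               alpha: float, phi, J_new: float) -> None:
        self.w[cols] = np.maximum(self.w[cols] + alpha * d_g, 0.0)
        self.S[g] += alpha * phi.delta_sum
        if self.score_based:
            self.scores += alpha * phi.u
            y = self.sub.loss.y
            self.loss_value = float(np.logaddexp(0.0, -y * self.scores).sum())
        else:
            self.loss_value = self.sub.loss.value(self.w)
        self.J = J_new


def surrogate_objective(w, state: CccpState, loss, X: LabeledMatrix,
                        groups: GroupStructure, params: PenaltyParams):
    """Functional form of the CCCP surrogate at linearization ``state``;
    returns (J, gradient, hessian_diag)."""
    loss_obj = get_loss(loss, X) if isinstance(loss, str) else loss
    return CccpSubproblem(loss_obj, groups, params, state.s_t).eval(
        np.asarray(w, dtype=float))


def full_objective(w, loss, X: LabeledMatrix | None, groups: GroupStructure,
                   params: PenaltyParams) -> float:
    """The true DC objective F = L1 + lambda1*L2 - lambda2*L3, the quantity
    with guaranteed descent across CCCP iterations."""
    loss_obj = get_loss(loss, X) if isinstance(loss, str) else loss
    w = np.asarray(w, dtype=float)
    l2v, _ = l2_penalty(w, groups)
    return (loss_obj.value(w) + params.lambda1 * l2v
            - params.lambda2 * l3_value(w, groups))


@dataclass
class CccpDiagnostics:
    """Per-run record: DC-objective trace, per-group stabilization bookkeeping
    (at outer-iteration granularity, matching how group settling is usually
    visualized), and solver effort counters."""
    objective_trace: list = field(default_factory=list)
    n_outer: int = 0
    converged: bool = False
    inner_iterations: list = field(default_factory=list)
    active_groups_per_outer: list = field(default_factory=list)
    stable: np.ndarray | None = None
    stabilization_outer: np.ndarray | None = None
    stabilization_inner: np.ndarray | None = None
    final_argmax: np.ndarray | None = None
    frozen_argmax_ok: bool = True

    def monotone(self, slack: float = 1e-8) -> bool:
        t = np.asarray(self.objective_trace)
        return bool(np.all(np.diff(t) <= slack))


def uniform_init(groups: GroupStructure) -> np.ndarray:
    """w0_i = 1/N_g within each group: satisfies the sum condition exactly and
    is symmetric, so the data alone decides the initial descent direction."""
    return groups.expand(1.0 / groups.sizes.astype(float))


def cccp_solve(X: LabeledMatrix, groups: GroupStructure, loss="logistic",
               params: PenaltyParams | None = None, inner: str = "bcgd",
               config: "_solver.SolverConfig | None" = None,
               tol_outer: float = 1e-6, max_outer: int = 50,
               w0: np.ndarray | None = None):
    """Outer CCCP loop: linearize L3 at w^t, minimize the convex surrogate
    with the inner solver, repeat until the relative decrease of the DC
    objective falls below ``tol_outer``.

    Returns ``(w, CccpDiagnostics)``.  With the BCGD inner solver, active-set
    state (which groups have settled into a near one-hot pattern and are
    frozen) persists across outer iterations; a group's stabilization
    iteration is the outer iteration during which it froze.
    """
    params = params or PenaltyParams()
    config = config or _solver.SolverConfig()
    loss_obj = get_loss(loss, X) if isinstance(loss, str) else loss
    if inner not in ("bcgd", "pg"):
        raise ValueError(f"unknown inner solver {inner!r}; expected bcgd|pg")

    w = uniform_init(groups) if w0 is None else np.asarray(w0, dtype=float).copy()
    if np.any(w < 0):
        raise ValueError("initial weights must be nonnegative")

    diag = CccpDiagnostics()
    f_prev = full_objective(w, loss_obj, None, groups, params)
    diag.objective_trace.append(f_prev)
    active_state = _solver.ActiveSetState(groups) if inner == "bcgd" else None

    for t in range(1, max_outer + 1):
        s_t = l3_gradient(w, groups)
        sub = CccpSubproblem(loss_obj, groups, params, s_t)
        if inner == "bcgd":
            w, info = _solver.bcgd_minimize(sub, w, groups, config,
                                            active_state=active_state,
                                            outer_index=t)
            diag.active_groups_per_outer.append(
                int(groups.n_groups - active_state.stable.sum()))
        else:
            w, info = _solver.projected_gradient_minimize(sub, w, config)
        diag.inner_iterations.append(info["iterations"])
        diag.n_outer = t

        f_new = full_objective(w, loss_obj, None, groups, params)
        diag.objective_trace.append(f_new)
        if f_prev - f_new <= tol_outer * max(1.0, abs(f_prev)):
            diag.converged = True
            f_prev = f_new
            break
        f_prev = f_new

    if active_state is not None:
        diag.stable = active_state.stable.copy()
        out = active_state.stabilization_outer.copy()
        out[out < 0] = diag.n_outer      # never-stable groups lasted all iterations
        diag.stabilization_outer = out
        diag.stabilization_inner = active_state.stabilization_inner.copy()
        diag.frozen_argmax_ok = active_state.frozen_argmax_ok
    diag.final_argmax = groups.argmax(w)
    return w, diag
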