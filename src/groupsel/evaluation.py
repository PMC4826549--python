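"""Oracles, baselines and metrics for one-per-group selections.

``brute_force_select`` enumerates every one-per-group combination and is the
exact solution of the combinatorial selection problem — feasible only for
small instances, used as the ground-truth oracle in tests.
``separate_select`` is the naive per-group baseline that ignores feature
interactions.  ``misclassification_count`` is the discrete criterion of the
worked toy example: the training error of the best possible deterministic
rule on a set of discrete features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GroupStructure, LabeledMatrix
from .losses import get_loss

ENUMERATION_CAP = 10 ** 6


@dataclass
class Selection:
    """One chosen feature index per group.

    indices are flat column indices into the feature matrix, ordered by
    group; provenance records which procedure produced the selection.
    """
    indices: np.ndarray
    group_ids: tuple = ()
    weights: np.ndarray | None = None
    provenance: str = "unknown"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if not self.group_ids:
            self.group_ids = tuple(range(1, self.indices.size + 1))
        if len(self.group_ids) != self.indices.size:
            raise ValueError("one index per group required")

    def validate(self, groups: GroupStructure) -> None:
        if self.indices.size != groups.n_groups:
            raise ValueError("selection size does not match number of groups")
        if not np.array_equal(groups.codes[self.indices],
                              np.arange(groups.n_groups)):
            raise ValueError("each selected index must belong to its group")

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"group_id": list(self.group_ids),
                           "selected_index": self.indices})
        if feature_ids is not None:
            df["selected_feature_id"] = [feature_ids[i] for i in self.indices]
        if self.weights is not None:
            df["final_weight"] = self.weights[self.indices]
        return df


def misclassification_count(values: np.ndarray, labels: np.ndarray) -> int:
    """Training error of the best deterministic rule on discrete features.

    Samples are grouped by their joint pattern on the given columns; within a
    pattern the best rule predicts the majority class, so the pattern
    contributes min(#class+, #class-) errors.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim == 2 and values.shape[0] == 1 and len(labels) > 1:
        values = values.T
    if not np.allclose(values, np.round(values)):
        raise TypeError("misclassification_count requires discrete-valued "
                        "features")
    labels = np.asarray(labels)
    _, inverse = np.unique(values, axis=0, return_inverse=True)
    n_pat = inverse.max() + 1
    pos = np.bincount(inverse[labels == 1], minlength=n_pat)
    neg = np.bincount(inverse[labels == -1], minlength=n_pat)
    return int(np.minimum(pos, neg).sum())


def _criterion_fn(criterion, X: LabeledMatrix):
    """Normalize a criterion to a callable over index tuples (lower=better)."""
    if callable(criterion):
        return criterion
    if criterion in ("error", "misclassification"):
        return lambda idx: float(
            misclassification_count(X.values[:, list(idx)], X.labels))
    loss = get_loss(criterion, X)
    N = X.n_features

    def f(idx):
        w = np.zeros(N)
        w[list(idx)] = 1.0
        return loss.value(w)
    return f


def brute_force_select(X: LabeledMatrix, groups: GroupStructure,
                       criterion="error", cap: int = ENUMERATION_CAP
                       ) -> Selection:
    """Exhaustive oracle: the one-per-group combination minimizing the
    criterion, ties resolved to the lexicographically smallest index tuple.

    criterion: "error" (best-rule misclassifications, discrete data only),
    a loss name ("logistic" | "class_separation": the loss at the one-hot
    weight vector of the combination), or a callable over index tuples.
    """
    n_comb = int(np.prod(groups.sizes.astype(object)))
    if n_comb > cap:
        raise ValueError(f"enumeration size {n_comb} exceeds cap {cap}")
    f = _criterion_fn(criterion, X)
    per_group = [np.sort(groups.indices(g)) for g in range(groups.n_groups)]
    best_idx, best_val = None, np.inf
    for combo in itertools.product(*per_group):
        val = f(combo)
        if val < best_val:           # strict: keeps lexicographically smallest
            best_idx, best_val = combo, val
    return Selection(indices=np.array(best_idx), group_ids=groups.group_ids,
                     provenance="brute_force")


def separate_select(X: LabeledMatrix, groups: GroupStructure,
                    criterion="error") -> Selection:
    """Naive baseline: per group independently, the single feature minimizing
    the criterion evaluated on that feature alone; ties -> lowest index."""
    f = _criterion_fn(criterion, X)
    chosen = []
    for g in range(groups.n_groups):
        members = np.sort(groups.indices(g))
        vals = [f((i,)) for i in members]
        chosen.append(members[int(np.argmin(vals))])   # argmin keeps first tie
    return Selection(indices=np.array(chosen), group_ids=groups.group_ids,
                     provenance="separate")


def recovery_rate(sel: Selection, truth: np.ndarray) -> float:
    """Fraction of groups whose selected feature equals the planted one."""
    truth = np.asarray(truth)
    if truth.shape != sel.indices.shape:
        raise ValueError(f"selection has {sel.indices.size} groups but truth "
                         f"has {truth.size}")
    return float(np.mean(sel.indices == truth))


def redundancy_score(X: LabeledMatrix, sel: Selection) -> float:
    """Sum of the absolute-Pearson-correlation matrix of the selected
    features (diagonal included); lower means a more diverse selection.
    Absolute correlation is used so anti-correlated duplicates still count
    as redundant."""
    if sel.indices.size < 1:
        raise ValueError("need at least one selected feature")
    cols = X.values[:, sel.indices]
    sd = cols.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance selected feature(s); "
                      "their correlations are defined as 0", stacklevel=2)
    k = cols.shape[1]
    if k == 1:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(cols.T)
    C[np.ix_(zero, np.arange(k))] = 0.0
    C[np.ix_(np.arange(k), zero)] = 0.0
    np.fill_diagonal(C, 1.0)
    return float(np.abs(C).sum())
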