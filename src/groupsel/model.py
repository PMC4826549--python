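"""Model/Results interface over the selection machinery.

``GroupedSelectionModel`` holds the data, the group structure and the loss;
``fit()`` runs the CCCP outer loop with the chosen inner solver and returns
a ``GroupedSelectionResults`` carrying the final weights, the selection, the
objective trace and per-group stabilization diagnostics, with a ``summary()``
table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import data as _data
from . import evaluation as _eval
from . import objective as _obj
from . import solver as _solver
from .data import GroupStructure, LabeledMatrix


class GroupedSelectionModel:
    """Select one jointly discriminative representative feature per group.

    Parameters
    ----------
    data : LabeledMatrix
        Samples x features with binary labels in {-1, +1}.
    groups : GroupStructure, optional
        Known feature partition.  If omitted, ``n_groups`` must be given and
        groups are built by hierarchical clustering on |Pearson r|.
    n_groups : int, optional
        Number of correlation clusters to build when no partition is given.
    loss : {"logistic", "class_separation"}
        Convex data-fit term.
    standardize : bool
        Column-standardize feature values before optimization (default).
    """

    def __init__(self, data: LabeledMatrix, groups: GroupStructure | None = None,
                 n_groups: int | None = None, loss: str = "logistic",
                 standardize: bool = True):
        self.data = data
        self.loss = loss
        self.standardized = bool(standardize)
        self.working = _data.standardize(data) if standardize else data
        if groups is None:
            if n_groups is None:
                raise ValueError("provide either groups or n_groups")
            groups = _data.build_groups(data, n_groups)
        elif groups.n_features != data.n_features:
            raise ValueError("group structure does not match the matrix")
        self.groups = groups

    @classmethod
    def from_arrays(cls, values, labels, positive_label=None, **kwargs):
        X = _data.validate_dataset(values, labels, positive_label=positive_label)
        return cls(X, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       positive_label=None, **kwargs):
        """Build from a DataFrame whose index holds sample ids, one column
        the labels, and the remaining columns the features."""
        if label_col not in df.columns:
            raise _data.DataError(f"label column {label_col!r} not found")
        feats = df.drop(columns=[label_col])
        X = _data.validate_dataset(feats.to_numpy(dtype=float),
                                   df[label_col].to_numpy(),
                                   sample_ids=tuple(map(str, df.index)),
                                   feature_ids=tuple(map(str, feats.columns)),
                                   positive_label=positive_label)
        return cls(X, **kwargs)

    def fit(self, lambda1: float = 100.0, lambda2: float = 100.0,
            solver: str = "bcgd",
            solver_config: _solver.SolverConfig | None = None,
            tol_outer: float = 1e-6, max_outer: int = 50
            ) -> "GroupedSelectionResults":
        params = _obj.PenaltyParams(lambda1=lambda1, lambda2=lambda2)
        config = solver_config or _solver.SolverConfig()
        w, diag = _obj.cccp_solve(self.working, self.groups, loss=self.loss,
                                  params=params, inner=solver, config=config,
                                  tol_outer=tol_outer, max_outer=max_outer)
        selection = _solver.select_features(w, self.groups)
        selection.provenance = solver
        return GroupedSelectionResults(self, w, selection, diag, params,
                                       config, solver)


class GroupedSelectionResults:
    """Fit outcome: final weights, the per-group selection and diagnostics."""

    def __init__(self, model: GroupedSelectionModel, params: np.ndarray,
                 selection: _eval.Selection, diagnostics: _obj.CccpDiagnostics,
                 penalties: _obj.PenaltyParams, config: _solver.SolverConfig,
                 solver: str):
        self.model = model
        self.params = params                # final weight vector
        self.selection = selection
        self.diagnostics = diagnostics
        self.penalties = penalties
        self.config = config
        self.solver = solver

    # -- convenience accessors ------------------------------------------------

    @property
    def selected_indices(self) -> np.ndarray:
        return self.selection.indices

    @property
    def selected_feature_ids(self) -> tuple:
        ids = self.model.data.feature_ids
        return tuple(ids[i] for i in self.selection.indices)

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    @property
    def objective_trace(self) -> np.ndarray:
        return np.asarray(self.diagnostics.objective_trace)

    @property
    def stabilization_iterations(self) -> np.ndarray | None:
        """Outer iteration at which each group's weights froze into a near
        one-hot pattern (groups that never froze report the total number of
        outer iterations).  Only tracked by the BCGD solver."""
        return self.diagnostics.stabilization_outer

    def recovery(self, truth) -> float:
        return _eval.recovery_rate(self.selection, truth)

    def redundancy(self) -> float:
        return _eval.redundancy_score(self.model.data, self.selection)

    def to_frame(self) -> pd.DataFrame:
        df = self.selection.to_frame(self.model.data.feature_ids)
        if self.stabilization_iterations is not None:
            df["stable"] = self.diagnostics.stable
            df["stabilization_iteration"] = self.stabilization_iterations
        return df

    def save_selection(self, path) -> None:
        df = self.selection.to_frame(self.model.data.feature_ids)
        df[["group_id", "selected_feature_id", "final_weight"]].to_csv(
            path, sep="\t", index=False)

    # -- reporting ------------------------------------------------------------

    def summary(self, max_rows: int = 10) -> str:
        m = self.model
        d = self.diagnostics
        conv = "yes" if d.converged else "NO"
        n_stable = int(d.stable.sum()) if d.stable is not None else None
        left = [
            ("Loss:", m.loss), ("Solver:", self.solver),
            ("lambda1:", f"{self.penalties.lambda1:g}"),
            ("lambda2:", f"{self.penalties.lambda2:g}"),
            ("Outer iterations:", d.n_outer),
            ("Converged:", conv),
        ]
        right = [
            ("No. samples:", m.data.n_samples),
            ("No. features:", m.data.n_features),
            ("No. groups:", m.groups.n_groups),
            ("Final objective:", f"{d.objective_trace[-1]:.4f}"),
            ("Stable groups:", "n/a" if n_stable is None
             else f"{n_stable}/{m.groups.n_groups}"),
            ("Standardized:", "yes" if m.standardized else "no"),
        ]
        width = 64
        lines = ["Grouped Feature Selection Results".center(width),
                 "=" * width]
        for (lk, lv), (rk, rv) in zip(left, right):
            lines.append(f"{lk:<18}{lv!s:<13}{rk:<18}{rv!s}")
        lines.append("-" * width)
        df = self.to_frame()
        shown = df.head(max_rows)
        lines.append(shown.to_string(index=False))
        if len(df) > max_rows:
            lines.append(f"... ({len(df) - max_rows} more groups)")
        lines.append("=" * width)
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------------

    def plot_objective(self, ax=None):
        """DC-objective value across CCCP outer iterations."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.objective_trace)), self.objective_trace,
                marker="o")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel("objective")
        return ax

    def plot_stabilization(self, ax=None):
        """Per-group stabilization iteration (the wider a group's bar, the
        longer the solver kept optimizing it)."""
        import matplotlib.pyplot as plt
        if self.stabilization_iterations is None:
            raise ValueError("stabilization diagnostics require the BCGD solver")
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(1, len(self.stabilization_iterations) + 1),
               self.stabilization_iterations, width=1.0)
        ax.set_xlabel("group")
        ax.set_ylabel("stabilization iteration")
        return ax
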