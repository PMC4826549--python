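"""Data model for labeled feature matrices and feature-group partitions.

The selection problem operates on a samples x features matrix with binary
sample labels and a partition of the features into groups.  Groups either
come from prior knowledge (a feature -> group map on disk) or are built here
by hierarchical clustering on absolute Pearson correlation, the standard way
co-expressed genes are grouped in microarray analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform


class DataError(ValueError):
    """Malformed feature matrix (missing values, ragged rows, ...)."""


class LabelError(ValueError):
    """Labels cannot be mapped to two classes."""


class GroupFormatError(ValueError):
    """A feature->group map is not a total, single-valued partition."""


@dataclass(frozen=True)
class LabeledMatrix:
    """An M x N feature matrix with one binary label in {-1, +1} per sample.

    Attributes
    ----------
    values : ndarray, shape (M, N)
        Feature values (unitless expression levels); no missing entries.
    labels : ndarray, shape (M,)
        Class labels, -1 or +1; both classes must be present.
    sample_ids, feature_ids : tuple of str
        Row / column identifiers; feature ids are unique.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: tuple = ()
    feature_ids: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise DataError(f"expected a 2-D matrix, got ndim={values.ndim}")
        M, N = values.shape
        if M < 2:
            raise DataError("need at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise DataError("feature matrix contains missing/non-finite values")
        if labels.shape != (M,):
            raise DataError(f"labels length {labels.shape} does not match M={M}")
        if not np.all(np.isin(labels, (-1, 1))):
            raise LabelError("labels must be -1 or +1 (use validate_dataset to remap)")
        if len(np.unique(labels)) < 2:
            raise LabelError("both classes must be present")
        sample_ids = tuple(self.sample_ids) or tuple(f"s{m}" for m in range(M))
        feature_ids = tuple(self.feature_ids) or tuple(f"f{i}" for i in range(N))
        if len(feature_ids) != N:
            raise DataError("feature_ids length must equal N")
        if len(set(feature_ids)) != N:
            raise DataError("feature_ids must be unique")
        if len(sample_ids) != M:
            raise DataError("sample_ids length must equal M")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels.astype(np.int8))
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids),
                          columns=list(self.feature_ids))
        df.insert(0, label_col, self.labels)
        df.index.name = "sample_id"
        return df


class GroupStructure:
    """A total partition of N features into G non-empty groups.

    Internally features carry integer group codes 0..G-1; ``group_ids`` keeps
    the original (possibly string) group labels.  Segmented reductions over
    groups (sums, maxima, softmax, ...) are precomputed-index operations so
    the solver stays vectorized even with tens of thousands of features.
    """

    def __init__(self, assignment: Sequence, group_ids: Sequence | None = None):
        assignment = np.asarray(assignment)
        if assignment.ndim != 1 or assignment.size == 0:
            raise GroupFormatError("assignment must be a non-empty 1-D sequence")
        if group_ids is None:
            group_ids, codes = np.unique(assignment, return_inverse=True)
        else:
            group_ids = np.asarray(group_ids)
            lookup = {g: k for k, g in enumerate(group_ids)}
            try:
                codes = np.array([lookup[a] for a in assignment])
            except KeyError as e:  # pragma: no cover - defensive
                raise GroupFormatError(f"unknown group id {e.args[0]!r}") from None
        self.codes = codes.astype(np.intp)
        self.group_ids = tuple(group_ids.tolist())
        self.n_groups = len(self.group_ids)
        self.n_features = self.codes.size
        self.sizes = np.bincount(self.codes, minlength=self.n_groups)
        if np.any(self.sizes == 0):
            raise GroupFormatError("every group must contain at least one feature")
        # stable sort keeps original feature order within a group, which is
        # what makes lowest-index tie-breaking fall out of "first in segment"
        self.order = np.argsort(self.codes, kind="stable")
        self.starts = np.concatenate(([0], np.cumsum(self.sizes)))
        self.segment_of = np.repeat(np.arange(self.n_groups), self.sizes)

    # -- segmented reductions -------------------------------------------------

    def sums(self, x: np.ndarray) -> np.ndarray:
        """Per-group sums of a length-N vector."""
        return np.bincount(self.codes, weights=x, minlength=self.n_groups)

    def maxima(self, x: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(x[self.order], self.starts[:-1])

    def argmax(self, x: np.ndarray) -> np.ndarray:
        """Per-group index (into the flat feature vector) of the max weight;
        ties broken by lowest feature index."""
        ox = x[self.order]
        mx = self.maxima(x)
        pos = np.where(ox == mx[self.segment_of],
                       np.arange(self.n_features), self.n_features)
        first = np.minimum.reduceat(pos, self.starts[:-1])
        return self.order[first]

    def second_maxima(self, x: np.ndarray) -> np.ndarray:
        """Per-group largest value excluding the argmax position (the value at
        the argmax, not the tied value: a duplicated max shows up here)."""
        masked = x.astype(float, copy=True)
        masked[self.argmax(x)] = -np.inf
        out = np.maximum.reduceat(masked[self.order], self.starts[:-1])
        out[self.sizes == 1] = -np.inf
        return out

    def logsumexp(self, x: np.ndarray) -> np.ndarray:
        mx = self.maxima(x)
        e = np.exp(x[self.order] - mx[self.segment_of])
        return mx + np.log(np.add.reduceat(e, self.starts[:-1]))

    def softmax(self, x: np.ndarray) -> np.ndarray:
        mx = self.maxima(x)
        e = np.exp(x[self.order] - mx[self.segment_of])
        z = np.add.reduceat(e, self.starts[:-1])
        out = np.empty_like(e)
        out[...] = e / z[self.segment_of]
        res = np.empty_like(out)
        res[self.order] = out
        return res

    def expand(self, per_group: np.ndarray) -> np.ndarray:
        """Broadcast a length-G vector to feature length."""
        return per_group[self.codes]

    def indices(self, g: int) -> np.ndarray:
        """Feature indices of group code ``g`` in ascending order."""
        return self.order[self.starts[g]:self.starts[g + 1]]

    def member_mask(self, group_mask: np.ndarray) -> np.ndarray:
        """Feature-level boolean mask from a group-level boolean mask."""
        return group_mask[self.codes]

    def __eq__(self, other):
        return (isinstance(other, GroupStructure)
                and np.array_equal(self.codes, other.codes)
                and self.group_ids == other.group_ids)

    def __repr__(self):
        return (f"GroupStructure(n_features={self.n_features}, "
                f"n_groups={self.n_groups})")


# -- construction and preprocessing -------------------------------------------

def validate_dataset(raw_values, raw_labels, sample_ids=None, feature_ids=None,
                     positive_label=None) -> LabeledMatrix:
    """Build a LabeledMatrix from raw values and arbitrary two-class labels.

    Labels are remapped to {-1, +1}: by default the lexically smaller class
    label becomes -1 and the larger +1; pass ``positive_label`` to override.
    """
    try:
        values = np.asarray(raw_values, dtype=float)
    except (ValueError, TypeError) as e:
        raise DataError(f"matrix is not numeric/rectangular: {e}") from None
    if values.dtype == object or values.ndim != 2:
        raise DataError("matrix must be rectangular and numeric")
    labels = np.asarray(raw_labels)
    classes = sorted(map(str, np.unique(labels)))
    if len(classes) == 1:
        raise LabelError(f"only one class present: {classes[0]!r}")
    if len(classes) > 2:
        raise LabelError(f"expected two classes, found {len(classes)}: {classes}")
    if positive_label is not None:
        pos = str(positive_label)
        if pos not in classes:
            raise LabelError(f"positive_label {pos!r} not among classes {classes}")
    else:
        pos = classes[1]
    mapped = np.where(np.char.equal(labels.astype(str), pos), 1, -1)
    return LabeledMatrix(values, mapped, sample_ids=sample_ids or (),
                         feature_ids=feature_ids or ())


def standardize(X: LabeledMatrix) -> LabeledMatrix:
    """Column-standardize to mean 0 / unit (population) variance.

    Zero-variance features become all-zero columns, with a warning — they can
    never discriminate and a zero column keeps them inert in every loss.
    """
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s) mapped to "
                      "all-zero columns", stacklevel=2)
    safe = np.where(zero, 1.0, sd)
    Z = (X.values - mu) / safe
    Z[:, zero] = 0.0
    return LabeledMatrix(Z, X.labels, sample_ids=X.sample_ids,
                         feature_ids=X.feature_ids)


def build_groups(X: LabeledMatrix, n_groups: int) -> GroupStructure:
    """Cluster features into ``n_groups`` groups by Pearson correlation.

    Agglomerative clustering with average linkage on the distance 1 - |r|,
    tree cut at exactly ``n_groups`` clusters.  |r| is used so that strongly
    anti-correlated features land in the same group, and the result is
    invariant to feature sign flips.  Zero-variance features are maximally
    distant (distance 1) from everything.
    """
    N = X.n_features
    if not 1 <= n_groups <= N:
        raise ValueError(f"n_groups must be in [1, {N}], got {n_groups}")
    if n_groups == N:
        return GroupStructure(np.arange(1, N + 1), group_ids=np.arange(1, N + 1))
    Z = standardize(X).values
    zero = np.all(Z == 0, axis=0)
    C = np.abs(Z.T @ Z) / X.n_samples
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    dist = np.clip(1.0 - C, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    labels = cut_tree(tree, n_clusters=n_groups).ravel()
    # relabel so group ids follow first appearance in feature order
    _, first_pos = np.unique(labels, return_index=True)
    relabel = {labels[p]: k + 1 for k, p in enumerate(np.sort(first_pos))}
    assignment = np.array([relabel[l] for l in labels])
    return GroupStructure(assignment, group_ids=np.arange(1, n_groups + 1))


def load_groups(path, feature_ids: Sequence[str]) -> GroupStructure:
    """Read a two-column feature_id<TAB>group_id map and validate it against
    the matrix's feature ids (total, single-valued partition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "group_id"}
    if not required.issubset(df.columns):
        raise GroupFormatError(
            f"group map must have columns {sorted(required)}, got {list(df.columns)}")
    dupes = df["feature_id"][df["feature_id"].duplicated()].tolist()
    if dupes:
        raise GroupFormatError(f"feature(s) listed more than once: {dupes[:5]}")
    mapping = dict(zip(df["feature_id"], df["group_id"]))
    unknown = set(mapping) - set(feature_ids)
    if unknown:
        raise GroupFormatError(f"unknown feature id(s): {sorted(unknown)[:5]}")
    missing = [f for f in feature_ids if f not in mapping]
    if missing:
        raise GroupFormatError(f"feature(s) absent from map: {missing[:5]}")
    assignment = np.array([mapping[f] for f in feature_ids])
    return GroupStructure(assignment)


def save_groups(groups: GroupStructure, feature_ids: Sequence[str], path) -> None:
    gids = [groups.group_ids[c] for c in groups.codes]
    pd.DataFrame({"feature_id": list(feature_ids), "group_id": gids}).to_csv(
        path, sep="\t", index=False)


def read_matrix(path, label_col: str = "label",
                positive_label=None) -> LabeledMatrix:
    """Read a delimited feature matrix (TSV/CSV by extension): first column
    sample_id, one designated label column, remaining columns features."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if label_col not in df.columns:
        raise DataError(f"label column {label_col!r} not found in {path.name}")
    labels = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col])
    return validate_dataset(feats.to_numpy(dtype=float), labels,
                            sample_ids=tuple(map(str, df.index)),
                            feature_ids=tuple(map(str, feats.columns)),
                            positive_label=positive_label)


def write_matrix(X: LabeledMatrix, path, label_col: str = "label") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    X.to_frame(label_col).to_csv(path, sep=sep)
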