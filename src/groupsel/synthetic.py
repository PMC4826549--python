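"""Seeded generators of planted-truth datasets for the selection problem.

The simulation design: samples carry balanced binary labels; each feature
group contains exactly one planted "representative" feature that equals the
label except on a stated fraction of samples whose values are flipped, and
all remaining features are label-independent background noise.  Flip counts
are exact — round(fraction * M) samples, drawn without replacement — so a
stated noise level of 10 % means literally 10 % of samples disagree.

Binary mode (the default) uses 0/1 indicator values, the convention of the
toy worked example: the representative feature is the indicator of the
positive class (1 where the label is +1, 0 where it is -1), and flipping a
sample replaces x by 1 - x.  Indicator data is meant to be consumed
unstandardized: with nonnegative weights and no intercept, raw indicators
keep the negative class at low scores, so the logistic loss keeps
discriminating at any problem width.  A continuous mode is provided as
well: background features are standard normal and the representative is the
(+/-1) label plus Gaussian noise scaled so that the sign of the feature
disagrees with the label with the requested probability (the
flip-equivalent noise level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import GroupStructure, LabeledMatrix

GRADED_NOISE_LEVELS = (0.0, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)


@dataclass
class SyntheticSpec:
    """Parameters of one planted-truth dataset.

    noise_fractions may be a scalar (shared by all groups) or one value per
    group, each in [0, 0.5].  representative_position, if given, fixes the
    within-group position of the planted feature per group; by default it is
    drawn uniformly per group from the seed.
    """
    M: int
    G: int
    group_size: int | None = None
    sizes: tuple | None = None
    noise_fractions: float | tuple = 0.0
    representative_position: tuple | None = None
    seed: int = 0
    mode: str = "binary"          # "binary" | "continuous"

    def __post_init__(self):
        if self.M < 2 or self.M % 2:
            raise ValueError("M must be an even integer >= 2 (balanced classes)")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.sizes is None:
            if self.group_size is None or self.group_size < 1:
                raise ValueError("provide group_size >= 1 or explicit sizes")
            self.sizes = (self.group_size,) * self.G
        self.sizes = tuple(int(s) for s in self.sizes)
        if len(self.sizes) != self.G or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must list one positive size per group")
        fr = self.noise_fractions
        fr = (float(fr),) * self.G if np.isscalar(fr) else tuple(float(f) for f in fr)
        if len(fr) != self.G:
            raise ValueError("noise_fractions must be scalar or one per group")
        if any(not 0.0 <= f <= 0.5 for f in fr):
            raise ValueError("noise fractions must lie in [0, 0.5]")
        self.noise_fractions = fr
        if self.representative_position is not None:
            rp = tuple(int(p) for p in self.representative_position)
            if len(rp) != self.G or any(not 0 <= p < s for p, s in zip(rp, self.sizes)):
                raise ValueError("representative_position must give one valid "
                                 "within-group index per group")
            self.representative_position = rp
        if self.mode not in ("binary", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def N(self) -> int:
        return int(sum(self.sizes))


@dataclass
class SyntheticDataset:
    """A generated dataset together with its planted ground truth."""
    data: LabeledMatrix
    groups: GroupStructure
    truth: np.ndarray = field(default=None)       # flat feature index per group
    noise_fractions: tuple = ()

    @property
    def truth_feature_ids(self):
        return tuple(self.data.feature_ids[i] for i in self.truth)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the planted design, fully reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    M, N, G = spec.M, spec.N, spec.G
    labels = np.concatenate([np.ones(M // 2, dtype=np.int8),
                             -np.ones(M // 2, dtype=np.int8)])

    if spec.mode == "binary":
        values = rng.choice((0.0, 1.0), size=(M, N))
    else:
        values = rng.standard_normal((M, N))

    starts = np.concatenate(([0], np.cumsum(spec.sizes)))
    assignment = np.repeat(np.arange(1, G + 1), spec.sizes)
    if spec.representative_position is not None:
        positions = np.asarray(spec.representative_position)
    else:
        positions = np.array([rng.integers(0, s) for s in spec.sizes])
    truth = starts[:-1] + positions

    y = labels.astype(float)
    for g in range(G):
        frac = spec.noise_fractions[g]
        col = truth[g]
        if spec.mode == "binary":
            rep = (y + 1.0) / 2.0          # indicator of the positive class
            n_flip = int(round(frac * M))
            if n_flip:
                flip = rng.choice(M, size=n_flip, replace=False)
                rep[flip] = 1.0 - rep[flip]
            values[:, col] = rep
        else:
            # sd chosen so that P(sign(y + eps) != y) = frac
            sd = 0.0 if frac == 0.0 else 1.0 / norm.ppf(1.0 - frac)
            values[:, col] = y + sd * rng.standard_normal(M)

    width = max(1, len(str(N - 1)))
    feature_ids = tuple(f"f{i:0{width}d}" for i in range(N))
    sample_ids = tuple(f"s{m:03d}" for m in range(M))
    data = LabeledMatrix(values, labels, sample_ids=sample_ids,
                         feature_ids=feature_ids)
    groups = GroupStructure(assignment, group_ids=np.arange(1, G + 1))
    return SyntheticDataset(data=data, groups=groups, truth=truth,
                            noise_fractions=spec.noise_fractions)


def graded_noise_spec(M: int, G: int, group_size: int, seed: int = 0,
                      mode: str = "binary") -> SyntheticSpec:
    """The graded-noise design: groups are split into ten consecutive blocks
    of equal size whose representative-feature flip fractions are
    0, 0.10, 0.15, ..., 0.50 — the first block is noise-free, the last is
    pure noise."""
    levels = GRADED_NOISE_LEVELS
    if G % len(levels):
        raise ValueError(f"G must be divisible by {len(levels)}, got {G}")
    per = G // len(levels)
    fractions = tuple(np.repeat(levels, per))
    return SyntheticSpec(M=M, G=G, group_size=group_size,
                         noise_fractions=fractions, seed=seed, mode=mode)


def toy_fixture() -> SyntheticDataset:
    """The 8-sample, 4-feature worked example: two groups of two features.

    Within group 1 the best *single* feature is f1 (one training error versus
    two for f2), within group 2 it is f4 — yet the pair (f1, f4) leaves one
    sample misclassified because the first and last samples agree on (f1, f4)
    while carrying opposite labels.  The pair (f2, f4) separates the classes
    perfectly: class +1 exactly when both features are 1.  Separate per-group
    selection therefore returns a strictly worse answer than joint selection.
    """
    rows = np.array([
        [1, 1, 0, 1],
        [1, 1, 1, 1],
        [1, 1, 0, 1],
        [1, 1, 1, 1],
        [0, 1, 1, 0],
        [0, 1, 0, 0],
        [0, 0, 1, 0],
        [1, 0, 0, 1],
    ], dtype=float)
    labels = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=np.int8)
    data = LabeledMatrix(rows, labels,
                         sample_ids=tuple(f"s{m+1}" for m in range(8)),
                         feature_ids=("f1", "f2", "f3", "f4"))
    groups = GroupStructure(np.array([1, 1, 2, 2]), group_ids=(1, 2))
    # jointly optimal representatives: f2 (index 1) and f4 (index 3)
    return SyntheticDataset(data=data, groups=groups,
                            truth=np.array([1, 3]),
                            noise_fractions=(0.0, 0.0))
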