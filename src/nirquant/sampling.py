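"""Kennard–Stone calibration/prediction partitioning and split-balance checks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .dataset import SpectraSet
from .errors import SplitError


@dataclass
class KSSplit:
    """A calibration/prediction partition.

    ``train_indices`` are in Kennard–Stone *selection order*; together with
    ``test_indices`` they cover every sample exactly once.
    """

    train_indices: list[int]
    test_indices: list[int]

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)


def ks_split(spectra, n_train: int) -> KSSplit:
    """Kennard–Stone selection of a uniformly covering calibration set.

    The first two picks are the pair at maximum Euclidean distance; each
    further pick is the unselected sample with the largest distance to its
    nearest already-selected neighbour (max–min rule).  Ties break to the
    lowest index.  Fully deterministic.

    ``spectra`` may be a :class:`SpectraSet` (the preprocessed spectra being
    modelled) or a plain feature matrix.
    """
    X = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra, float)
    n = X.shape[0]
    if not (2 <= n_train <= n):
        raise SplitError(f"need 2 <= n_train <= {n}, got {n_train}")
    D = cdist(X, X)
    # seed pair: lexicographically first argmax of the distance matrix
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    mask = np.zeros(n, dtype=bool)
    mask[selected] = True
    min_d = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        min_d_masked = np.where(mask, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))  # argmax returns the lowest tied index
        selected.append(nxt)
        mask[nxt] = True
        min_d = np.minimum(min_d, D[nxt])
    test = [int(k) for k in range(n) if not mask[k]]
    return KSSplit(selected, test)


def train_size(n_samples: int, train_frac: float = 0.7) -> int:
    """Calibration-set size for a fractional split, rounded up."""
    return int(math.ceil(train_frac * n_samples))


@dataclass
class BoxplotStats:
    """Tukey boxplot summary: median, quartiles, whiskers, 1.5·IQR outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def boxplot_stats(values) -> BoxplotStats:
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return BoxplotStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo) | (v > hi)]),
    )


@dataclass
class BalanceResult:
    """Welch t-test p-value plus boxplot summaries for both partitions."""

    p_value: float
    train: BoxplotStats
    test: BoxplotStats


def balance_test(y_train, y_test) -> BalanceResult:
    """Check that a split left the target distribution balanced.

    Two-sided Welch (unequal-variance) two-sample t-test on the target values
    of the two partitions; a large p-value means no evidence of a mean shift
    between calibration and prediction sets.
    """
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, float)
    if y_train.size < 2 or y_test.size < 2:
        raise SplitError("balance test needs >= 2 values in each group")
    if y_train.var(ddof=1) == 0 and y_test.var(ddof=1) == 0:
        if y_train.mean() == y_test.mean():
            p = 1.0
        else:
            raise SplitError("balance test undefined: both groups constant")
    else:
        t, p = stats.ttest_ind(y_train, y_test, equal_var=False)
        p = float(p)
    return BalanceResult(p, boxplot_stats(y_train), boxplot_stats(y_test))
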