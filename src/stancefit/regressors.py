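"""Lagged regression spaces, cohort splitting, and mRMR shrinkage.

The regression vector at time k collects lagged copies of the four cleaned
series (control torque tau_c — the AR part — plus sway angle and the two
EMG envelopes as exogenous inputs) up to a lag limit of 20 samples at
100 Hz.  Pooled per-condition training matrices are reduced to the five
most relevant columns by greedy minimum-redundancy-maximum-relevance (mRMR)
selection with a binned plug-in mutual-information estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SIGNALS",
    "LagCoordinate",
    "RegressionDataset",
    "SplitPlan",
    "build_lagged_space",
    "pool_condition",
    "split_cohort",
    "nested_split",
    "mutual_information",
    "equal_frequency_bins",
    "mrmr_select",
]

log = logging.getLogger(__name__)

SIGNALS = ("tau_c", "theta", "ga", "ta")


@dataclass(frozen=True)
class LagCoordinate:
    """One regressor: a signal name and its lag in samples (100 Hz).

    tau_c lags form the autoregressive part; theta/ga/ta lags the exogenous
    part.  Lags start at 1 (the current sample never regresses on itself).
    """

    signal: str
    lag: int

    def __post_init__(self) -> None:
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    def __str__(self) -> str:
        return f"{self.signal}-{self.lag}"

    @classmethod
    def parse(cls, s: str) -> "LagCoordinate":
        sig, lag = s.rsplit("-", 1)
        return cls(sig, int(lag))


@dataclass
class RegressionDataset:
    """Design matrix with (signal, lag)-labelled columns and target torque."""

    X: np.ndarray
    y: np.ndarray
    columns: list[LagCoordinate]
    groups: np.ndarray          # subject id per row
    condition: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X and y are misaligned")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column labels do not match X width")
        if self.groups.size != self.y.size:
            raise ValueError("groups misaligned with rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_d(self) -> int:
        return self.X.shape[1]

    def select_columns(self, columns: Sequence[LagCoordinate]) -> "RegressionDataset":
        idx = [self.columns.index(c) for c in columns]
        return RegressionDataset(X=self.X[:, idx], y=self.y.copy(),
                                 columns=list(columns), groups=self.groups.copy(),
                                 condition=self.condition)

    def subset_subjects(self, subjects: Sequence) -> "RegressionDataset":
        mask = np.isin(self.groups, list(subjects))
        return RegressionDataset(X=self.X[mask], y=self.y[mask],
                                 columns=list(self.columns),
                                 groups=self.groups[mask], condition=self.condition)


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level train/test partition of the cohort."""

    train_subjects: tuple
    test_subjects: tuple
    fraction: float

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subjects overlap")


def build_lagged_space(epoch, max_lag: int = 20) -> RegressionDataset:
    """Lag-limited regression space of one cleaned epoch.

    Rows run over k = max_lag..N-1; the row for time k pairs y = tau_c(k)
    with regressors [tau_c(k-1..k-L), theta(k-1..k-L), ga(...), ta(...)].
    Defaults give an 80 x 80 matrix for a 100-sample epoch.
    """
    n = epoch.tau_c.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    series = {s: epoch.channel(s) for s in SIGNALS}
    columns = [LagCoordinate(s, lag) for s in SIGNALS for lag in range(1, max_lag + 1)]
    rows = n - max_lag
    X = np.empty((rows, len(columns)))
    for j, col in enumerate(columns):
        v = series[col.signal]
        X[:, j] = v[max_lag - col.lag: n - col.lag]
    y = series["tau_c"][max_lag:]
    subj = epoch.subject if epoch.subject is not None else 0
    return RegressionDataset(X=X, y=y, columns=columns,
                             groups=np.full(rows, subj), condition=epoch.condition)


def pool_condition(datasets: Sequence[RegressionDataset]) -> RegressionDataset:
    """Row-concatenate per-subject datasets, preserving the lag coordinates."""
    if not datasets:
        raise ValueError("nothing to pool")
    first = datasets[0]
    if len(datasets) == 1:
        return first
    for d in datasets[1:]:
        if d.columns != first.columns:
            raise ValueError("datasets have differing lag coordinates")
        if d.condition != first.condition:
            raise ValueError("datasets belong to different conditions")
    return RegressionDataset(
        X=np.vstack([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        columns=list(first.columns),
        groups=np.concatenate([d.groups for d in datasets]),
        condition=first.condition,
    )


def split_cohort(subject_ids: Sequence, fraction: float, seed) -> SplitPlan:
    """Deterministic subject-level train/test split (never row-level)."""
    if fraction not in (0.7, 0.6, 0.5):
        raise ValueError("supported fractions are 0.7, 0.6 and 0.5")
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = tuple(sorted(ids[i] for i in perm[:n_train]))
    test = tuple(sorted(ids[i] for i in perm[n_train:]))
    return SplitPlan(train_subjects=train, test_subjects=test, fraction=fraction)


def nested_split(base: SplitPlan, fraction: float) -> SplitPlan:
    """Shrink a split by moving the lowest-indexed training subjects to test.

    Keeps the 60/40 and 50/50 partitions nested inside the 70/30 one so the
    three robustness runs differ only by which subjects leave training.
    """
    if fraction not in (0.7, 0.6, 0.5):
        raise ValueError("supported fractions are 0.7, 0.6 and 0.5")
    total = len(base.train_subjects) + len(base.test_subjects)
    n_train = int(round(fraction * total))
    if n_train > len(base.train_subjects):
        raise ValueError("nested split cannot grow the training set")
    train = sorted(base.train_subjects)
    moved, kept = train[: len(train) - n_train], train[len(train) - n_train:]
    return SplitPlan(train_subjects=tuple(kept),
                     test_subjects=tuple(sorted(list(base.test_subjects) + moved)),
                     fraction=fraction)


# ---------------------------------------------------------------------------
# mutual information + mRMR
# ---------------------------------------------------------------------------

def equal_frequency_bins(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Rank-based discretization: bin edges at empirical quantiles.

    Invariant under strictly monotone (in particular positive affine)
    transforms of x; a constant column maps to a single bin.
    """
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, x, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in MI (nats) between equal-frequency binned variables."""
    ia = equal_frequency_bins(a, n_bins)
    ib = equal_frequency_bins(b, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (pa * pb), 1.0)
        mi = np.sum(np.where(joint > 0, joint * np.log(ratio), 0.0))
    return float(max(mi, 0.0))


def mrmr_select(dataset: RegressionDataset, k: int = 5, n_bins: int = 8) -> list[LagCoordinate]:
    """Greedy mRMR (Peng difference criterion) over the dataset's columns.

    Picks first the column with maximal relevance MI(x_j; y), then
    iteratively the maximizer of relevance minus mean redundancy to the
    already-selected set.  Ties break toward the lower column index.
    Constant columns get zero relevance/redundancy (logged).
    """
    if k > dataset.n_d:
        raise ValueError("cannot select more columns than available")
    y = dataset.y
    if np.ptp(y) == 0:
        raise ValueError("target is constant; mRMR undefined")
    ncol = dataset.n_d
    constant = np.array([np.ptp(dataset.X[:, j]) == 0 for j in range(ncol)])
    if constant.any():
        log.warning("mRMR: %d constant column(s) assigned zero relevance",
                    int(constant.sum()))

    relevance = np.array([
        0.0 if constant[j] else mutual_information(dataset.X[:, j], y, n_bins)
        for j in range(ncol)
    ])
    selected: list[int] = [int(np.argmax(relevance))]
    red_cache = np.zeros(ncol)  # summed redundancy to the selected set
    while len(selected) < k:
        last = selected[-1]
        for j in range(ncol):
            if j in selected or constant[j] or constant[last]:
                continue
            red_cache[j] += mutual_information(dataset.X[:, j], dataset.X[:, last], n_bins)
        score = relevance - red_cache / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return [dataset.columns[j] for j in selected]
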