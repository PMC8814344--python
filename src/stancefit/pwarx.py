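"""Piecewise-affine ARX (PWARX) identification of the ankle controller.

Pipeline: spectral clustering of the (optionally output-augmented)
regression vectors, silhouette-based choice of the number of sub-models s,
soft-margin linear SVM estimation of the separating hyperplanes over the
regression space, and per-region affine least squares via the pseudo-inverse
(points lying on a hyperplane are discarded).  Model quality is summarized
by the NRMSE-complement fit percentage

    fit% = 100 (1 - ||y - y_hat|| / ||y - mean(y)||)

with one-step-ahead prediction by default.  Diagnostics cover the per-trial
switching signal (region membership over time), residual autocorrelation
with whiteness bounds, and boundary-continuity of the fitted affine maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score
from sklearn.svm import SVC
from statsmodels.tsa.stattools import acf as sm_acf

from .regressors import LagCoordinate, RegressionDataset

__all__ = [
    "PWARXModel",
    "SwitchingSignal",
    "IdentifyConfig",
    "spectral_cluster",
    "silhouette_select",
    "fit_boundary",
    "fit_arx_submodels",
    "identify",
    "predict",
    "predict_region",
    "fit_percent",
    "switching_signal",
    "residual_acf",
    "check_continuity",
]

log = logging.getLogger(__name__)


@dataclass
class PWARXModel:
    """s affine ARX sub-models over a polyhedral partition of regressor space.

    ``submodels[j]`` has length n_d + 1 with the affine offset last.
    ``boundaries`` holds one hyperplane row [w, b] per region pair (ordered
    as itertools.combinations of region indices); membership of region i
    against region j (i < j) uses w.x + b <= 0 -> region i.
    """

    submodels: np.ndarray          # (s, n_d + 1)
    boundaries: np.ndarray | None  # (n_pairs, n_d + 1) or None when s == 1
    columns: list[LagCoordinate]
    s: int
    noise_sd_hat: float = float("nan")
    silhouette: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.submodels = np.atleast_2d(np.asarray(self.submodels, dtype=float))
        if self.submodels.shape[0] != self.s:
            raise ValueError("submodel count disagrees with s")
        if self.boundaries is not None:
            self.boundaries = np.atleast_2d(np.asarray(self.boundaries, dtype=float))

    @property
    def n_d(self) -> int:
        return self.submodels.shape[1] - 1


@dataclass
class SwitchingSignal:
    """Per-sample active-region index with switch count and first-switch time."""

    sigma: np.ndarray              # region indices, 1-based
    time: np.ndarray               # s, relative to perturbation onset
    switch_count: int
    first_switch_time: float | None


@dataclass(frozen=True)
class IdentifyConfig:
    """Tunables of the identification stage (defaults follow the study design)."""

    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    cluster_on_output: bool = True    # cluster joint [x; y] rather than x alone
    svm_C: float = 1.0
    boundary_tol: float = 1e-9
    standardize_clustering: bool = True
    relabel_by_region: bool = True    # sub-model data = polyhedral region members
    seed: int = 0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _gaussian_affinity(points: np.ndarray) -> np.ndarray:
    d = pdist(points)
    scale = np.median(d)
    if scale == 0:
        raise ValueError("all points identical; affinity scale collapsed")
    A = np.exp(-squareform(d) ** 2 / (2 * scale**2))
    return A


def spectral_cluster(points: np.ndarray, k: int, seed) -> np.ndarray:
    """Normalized-Laplacian spectral clustering, Gaussian affinity.

    The affinity scale is the median pairwise distance; the spectral
    embedding is partitioned by k-means (seeded, hence deterministic).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k > n:
        raise ValueError("more clusters than points")
    if k == n:
        return np.arange(n)
    A = _gaussian_affinity(points)
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", assign_labels="kmeans",
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
        n_init=10,
    )
    return model.fit_predict(A)


def silhouette_select(points: np.ndarray, k_range=(2, 3, 4, 5, 6), seed=0,
                      return_scores: bool = False):
    """Number of sub-models s = argmax over k of the mean silhouette width.

    Ties resolve to the smallest k.  Candidate k exceeding n - 1 are dropped
    with a warning.
    """
    points = np.asarray(points, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if min(ks) < 2:
        raise ValueError("silhouette needs k >= 2")
    usable = [k for k in ks if k <= points.shape[0] - 1]
    if len(usable) < len(ks):
        log.warning("silhouette_select: shrinking k range to %s (too few points)", usable)
    if not usable:
        raise ValueError("too few points for any candidate k")
    scores: dict[int, float] = {}
    for k in usable:
        labels = spectral_cluster(points, k, seed)
        if np.unique(labels).size < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(points, labels))
    best = max(usable, key=lambda k: (scores[k], -k))
    return (best, scores) if return_scores else best


# ---------------------------------------------------------------------------
# boundary + sub-model estimation
# ---------------------------------------------------------------------------

def fit_boundary(X: np.ndarray, labels: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Soft-margin linear SVM hyperplanes between region pairs.

    Returns one row [w, b] per ordered pair (i < j) of present classes, with
    the sign fixed so w.x + b <= 0 selects the lower-indexed region.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("boundary estimation needs at least two classes")
    rows = []
    for a in range(classes.size):
        for b in range(a + 1, classes.size):
            ca, cb = classes[a], classes[b]
            mask = (labels == ca) | (labels == cb)
            svc = SVC(kernel="linear", C=C, class_weight="balanced")
            svc.fit(X[mask], (labels[mask] == cb).astype(int))
            w = svc.coef_.ravel()
            b0 = float(svc.intercept_[0])
            # decision > 0 -> class cb, so w.x + b <= 0 already selects ca
            rows.append(np.concatenate([w, [b0]]))
    return np.vstack(rows)


def _boundary_mask(X: np.ndarray, H: np.ndarray, tol: float) -> np.ndarray:
    """True for rows lying on any hyperplane (|w.x + b| <= tol * ||w||)."""
    on = np.zeros(X.shape[0], dtype=bool)
    for row in np.atleast_2d(H):
        w, b = row[:-1], row[-1]
        on |= np.abs(X @ w + b) <= tol * np.linalg.norm(w)
    return on


def _region_labels(X: np.ndarray, H: np.ndarray, s: int) -> np.ndarray:
    """Polyhedral-region index per row of X by majority vote over the
    pairwise hyperplanes; ties go to the smallest region index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    votes = np.zeros((X.shape[0], s), dtype=int)
    pair = 0
    for i in range(s):
        for j in range(i + 1, s):
            row = H[pair]
            val = X @ row[:-1] + row[-1]
            votes[val <= 0, i] += 1
            votes[val > 0, j] += 1
            pair += 1
    return np.argmax(votes, axis=1)


def fit_arx_submodels(
    dataset: RegressionDataset,
    labels: np.ndarray,
    H: np.ndarray | None,
    boundary_tol: float = 1e-9,
    *,
    s: int | None = None,
    noise_from: str = "pooled",
) -> PWARXModel:
    """Per-region affine least squares via the pseudo-inverse.

    Points numerically on a hyperplane are discarded from every region's
    fit.  A region left with fewer than n_d + 2 points raises, naming it.
    Rank-deficient regions fall back to the minimum-norm solution (logged by
    numpy's lstsq semantics of pinv).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if s is None:
        s = classes.size
    elif classes.size != s:
        raise ValueError(f"labels cover {classes.size} regions but s = {s} "
                         "(a region is empty)")
    n_d = dataset.n_d
    keep = ~_boundary_mask(dataset.X, H, boundary_tol) if H is not None else np.ones(
        dataset.y.size, dtype=bool)

    submodels = np.empty((s, n_d + 1))
    residuals = []
    for idx, c in enumerate(classes):
        mask = (labels == c) & keep
        if mask.sum() < n_d + 2:
            raise ValueError(f"region {c} starved: {int(mask.sum())} points "
                             f"after boundary discard (need >= {n_d + 2})")
        A = np.column_stack([dataset.X[mask], np.ones(int(mask.sum()))])
        theta = np.linalg.pinv(A) @ dataset.y[mask]
        submodels[idx] = theta
        residuals.append(dataset.y[mask] - A @ theta)
    resid = np.concatenate(residuals)
    return PWARXModel(submodels=submodels, boundaries=H, columns=list(dataset.columns),
                      s=s, noise_sd_hat=float(np.std(resid)))


def identify(train: RegressionDataset, config: IdentifyConfig = IdentifyConfig()) -> PWARXModel:
    """End-to-end PWARX identification on a pooled, lag-selected training set.

    Clusters the joint [x; y] vectors (configurable), selects s by
    silhouette, fits pairwise SVM hyperplanes on x alone, and solves the
    per-region least squares.  Stage failures are re-raised tagged with the
    stage name.
    """
    if train.y.size == 0:
        raise ValueError("identify: empty training set")
    pts = np.column_stack([train.X, train.y]) if config.cluster_on_output else train.X
    if config.standardize_clustering:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd

    try:
        s, scores = silhouette_select(pts, config.k_range, config.seed, return_scores=True)
        labels = spectral_cluster(pts, s, config.seed)
    except Exception as e:
        raise RuntimeError(f"clustering stage failed: {e}") from e
    try:
        H = fit_boundary(train.X, labels, C=config.svm_C) if s > 1 else None
    except Exception as e:
        raise RuntimeError(f"boundary stage failed: {e}") from e
    if H is not None and config.relabel_by_region:
        # sub-models belong to the polyhedral regions, so each is estimated
        # from the points its region actually contains
        labels = _region_labels(train.X, H, s)
    try:
        model = fit_arx_submodels(train, labels, H, config.boundary_tol, s=s)
    except Exception as e:
        raise RuntimeError(f"least-squares stage failed: {e}") from e
    model.silhouette = scores
    return model


# ---------------------------------------------------------------------------
# prediction + diagnostics
# ---------------------------------------------------------------------------

def predict_region(model: PWARXModel, X: np.ndarray) -> np.ndarray:
    """Region index (0-based) for each row of X.

    s = 2: sign of the single hyperplane (<= 0 -> region 0).  s > 2:
    majority vote over pairwise hyperplanes, ties to the smallest index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_d:
        raise ValueError(f"regressor dimension {X.shape[1]} != model n_d {model.n_d}")
    if model.s == 1:
        return np.zeros(X.shape[0], dtype=int)
    return _region_labels(X, model.boundaries, model.s)


def predict(model: PWARXModel, X: np.ndarray) -> np.ndarray:
    """One-step-ahead PWARX output: theta_sigma . [x; 1] per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    region = predict_region(model, X)
    A = np.column_stack([X, np.ones(X.shape[0])])
    out = np.einsum("ij,ij->i", A, model.submodels[region])
    return out


def fit_percent(y, y_hat) -> float:
    """NRMSE-complement goodness of fit, 100 (1 - ||y-y_hat||/||y-mean(y)||)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("need two equal-length series of >= 2 samples")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("constant target: fit percentage undefined")
    return float(100.0 * (1.0 - np.linalg.norm(y - y_hat) / denom))


def switching_signal(
    model: PWARXModel,
    dataset: RegressionDataset,
    *,
    max_lag: int = 20,
    fs: float = 100.0,
) -> dict:
    """Per-trial switching signals from region membership of each x_k.

    ``dataset`` rows must be time-ordered within each subject (contiguous
    groups); the row index plus the lag offset converts to seconds after
    onset.  Returns {subject: SwitchingSignal}.
    """
    out: dict = {}
    groups = dataset.groups
    # verify contiguity (unordered rows would scramble the signal)
    seen = []
    for g in groups:
        if not seen or seen[-1] != g:
            if g in seen:
                raise ValueError("dataset rows are not contiguous per subject")
            seen.append(g)
    for g in seen:
        mask = groups == g
        sigma = predict_region(model, dataset.X[mask]) + 1
        t = (max_lag + np.arange(sigma.size)) / fs
        flips = np.nonzero(np.diff(sigma) != 0)[0]
        out[g] = SwitchingSignal(
            sigma=sigma, time=t, switch_count=int(flips.size),
            first_switch_time=float(t[flips[0] + 1]) if flips.size else None,
        )
    return out


def residual_acf(residuals, max_lag: int = 20) -> tuple[np.ndarray, float]:
    """Sample autocorrelation (lags 0..max_lag) and the +-1.96/sqrt(N) band."""
    r = np.asarray(residuals, dtype=float)
    if r.size <= max_lag:
        raise ValueError("series shorter than the requested lag range")
    if np.ptp(r) == 0:
        raise ValueError("zero-variance residuals: ACF undefined")
    vals = sm_acf(r, nlags=max_lag, fft=False)
    band = 1.96 / np.sqrt(r.size)
    return vals, float(band)


def check_continuity(model: PWARXModel, boundary_points: np.ndarray) -> float:
    """Diagnostic: max inter-model disagreement |(theta_i - theta_j).[x;1]|
    over supplied near-boundary points.  Zero for a continuous PWA map."""
    P = np.atleast_2d(np.asarray(boundary_points, dtype=float))
    if P.size == 0:
        raise ValueError("no near-boundary points supplied")
    A = np.column_stack([P, np.ones(P.shape[0])])
    worst = 0.0
    for i in range(model.s):
        for j in range(i + 1, model.s):
            gap = np.abs(A @ (model.submodels[i] - model.submodels[j]))
            worst = max(worst, float(gap.max()))
    return worst
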