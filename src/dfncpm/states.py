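"""Discrete brain states: clustering, dominant-state sequences, dwell stats.

Windowed-FC vectors pooled across subjects are clustered into k discrete
connectivity states with a city-block (L1) k-means — i.e. k-medians, since
the coordinate-wise median is the L1-optimal centroid — run from several
seeded initializations, keeping the replicate with the least total
within-cluster distance.  Each subject's windows are then assigned to their
nearest state, yielding a categorical dominant-state sequence from which
occupancy fractions, mean dwell times and transition matrices are computed.
Group comparisons of dwell statistics use the pooled-variance (homoscedastic)
two-sample t-test.

States are relabeled 1..k in descending order of overall occupancy so that
labels are deterministic across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats

from ._errors import ValidationError
from .dfnc import WindowedFCSeries

__all__ = [
    "StateModel",
    "StateSequence",
    "DwellStats",
    "TTestResult",
    "fit_states",
    "select_k_elbow",
    "assign_states",
    "dwell_statistics",
    "compare_groups_ttest",
    "ttest_from_stats",
]


@dataclass(frozen=True)
class StateModel:
    """k cluster centroids in FC-vector space plus the fit metadata."""

    k: int
    centroids: np.ndarray  # k x P
    distance: str  # "cityblock" | "euclidean"
    n_replicates: int
    seed: int
    inertia: float  # total within-cluster distance of the kept replicate
    cvi_curve: tuple = ()  # ((k, validity index), ...) when from select_k_elbow


@dataclass(frozen=True)
class StateSequence:
    """Per-subject dominant-state labels (1..k), one per window."""

    subject_id: str
    labels: np.ndarray
    tr_seconds: float = 2.0
    step_tr: int = 1


@dataclass(frozen=True)
class DwellStats:
    """Occupancy and dwell summary of one state sequence.

    ``mean_dwell_windows[s-1]`` is the mean contiguous run length of state
    s in windows (NaN when the state never occurs); seconds are windows x
    step x TR.  ``transition_matrix`` rows with no outgoing transitions are
    NaN and listed in ``absorbing_rows``.
    """

    k: int
    fraction_time: np.ndarray
    mean_dwell_windows: np.ndarray
    mean_dwell_seconds: np.ndarray
    n_runs: np.ndarray
    n_transitions: int
    transition_counts: np.ndarray
    transition_matrix: np.ndarray
    absorbing_rows: tuple


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int


# ---------------------------------------------------------------------------
# clustering

def _distances(X, centroids, metric):
    return cdist(X, centroids, metric=metric)


def _objective(dist_to_own, metric):
    # euclidean k-means minimizes squared distance; k-medians minimizes L1
    return float((dist_to_own**2).sum() if metric == "euclidean" else dist_to_own.sum())


def _update_centroid(points, metric):
    return np.mean(points, axis=0) if metric == "euclidean" else np.median(points, axis=0)


def _seed_centroids(X, k, rng, metric):
    """k-means++-style seeding adapted to the metric: the next centroid is
    drawn with probability proportional to the distance (L1) or squared
    distance (L2) to the nearest centroid chosen so far."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    d = _distances(X, X[idx], metric).ravel()
    for _ in range(1, k):
        weights = d**2 if metric == "euclidean" else d
        total = weights.sum()
        if total <= 0:  # all points coincide with a centroid
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=weights / total)))
        d = np.minimum(d, _distances(X, X[[idx[-1]]], metric).ravel())
    return X[idx].copy()


def _lloyd(X, k, metric, rng, max_iter=300):
    centroids = _seed_centroids(X, k, rng, metric)
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        D = _distances(X, centroids, metric)
        new_labels = D.argmin(axis=1)
        nearest = D[np.arange(len(X)), new_labels]
        for c in range(k):
            if not np.any(new_labels == c):
                # reseed an empty cluster at the point farthest from its
                # nearest centroid
                far = int(np.argmax(nearest))
                centroids[c] = X[far]
                new_labels[far] = c
                nearest[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = _update_centroid(X[labels == c], metric)
    D = _distances(X, centroids, metric)
    labels = D.argmin(axis=1)
    inertia = _objective(D[np.arange(len(X)), labels], metric)
    return centroids, labels, inertia


def fit_states(
    windows: np.ndarray,
    k: int = 3,
    distance: str = "cityblock",
    n_replicates: int = 5,
    seed: int = 0,
) -> StateModel:
    """Cluster pooled FC windows into k states.

    Runs ``n_replicates`` metric-adapted k-means++ initializations of
    Lloyd's alternation (median update under city-block distance) and keeps
    the replicate with least total within-cluster distance.  Cluster labels
    are then reordered so state 1 is the most occupied.
    """
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2:
        raise ValidationError("windows must be a 2-D matrix")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if X.shape[0] < k:
        raise ValidationError(f"need at least k={k} windows, got {X.shape[0]}")
    if distance not in ("cityblock", "euclidean"):
        raise ValidationError(f"unknown distance {distance!r}")
    best = None
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        centroids, labels, inertia = _lloyd(X, k, distance, rng)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    centroids, labels, inertia = best
    # deterministic labels: descending occupancy
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    centroids = centroids[order]
    return StateModel(
        k=k,
        centroids=centroids,
        distance=distance,
        n_replicates=n_replicates,
        seed=seed,
        inertia=inertia,
    )


def select_k_elbow(
    windows: np.ndarray,
    k_range,
    distance: str = "cityblock",
    n_replicates: int = 5,
    seed: int = 0,
):
    """Choose k by the elbow of a cluster validity index.

    For each k the index is total within-cluster distance divided by total
    between-centroid distance (sum of pairwise centroid distances); k* is
    the point of maximum positive second difference of the index curve.

    Returns ``(k_star, cvi_curve, low_confidence)`` where ``cvi_curve`` is
    a tuple of (k, index) pairs.  ``low_confidence`` flags structure-free
    data: it is set when the maximum second difference of the raw
    within-cluster distance curve is below 10% of that curve's range.  (The
    ratio index itself decays steeply in k for any data because the
    between-centroid denominator grows with the number of centroid pairs,
    so the no-elbow diagnosis is made on the within-cluster distances.)
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValidationError("k_range must contain at least 3 values")
    if ks != list(range(ks[0], ks[0] + len(ks))) or ks[0] < 2:
        raise ValidationError("k_range must be contiguous with min >= 2")
    curve = []
    inertias = []
    for k in ks:
        model = fit_states(windows, k=k, distance=distance,
                           n_replicates=n_replicates, seed=seed)
        between = cdist(model.centroids, model.centroids, metric=distance)
        total_between = between[np.triu_indices(k, 1)].sum()
        index = model.inertia / total_between if total_between > 0 else np.inf
        curve.append((k, float(index)))
        inertias.append(model.inertia)
    vals = np.array([v for _, v in curve])
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]  # defined at interior ks
    k_star = ks[1 + int(np.argmax(second))]
    inert = np.array(inertias)
    inert_second = inert[:-2] - 2 * inert[1:-1] + inert[2:]
    inert_range = inert.max() - inert.min()
    low_confidence = (
        bool(inert_second.max() < 0.1 * inert_range) if inert_range > 0 else True
    )
    return k_star, tuple(curve), low_confidence


def assign_states(model: StateModel, series) -> StateSequence:
    """Assign each window of a subject's FC series to its nearest state.

    Ties break toward the lower state label.  ``series`` may be a
    WindowedFCSeries or a bare N_w x P array.
    """
    if isinstance(series, WindowedFCSeries):
        X, sid, tr = series.values, series.subject_id, series.tr_seconds
    else:
        X, sid, tr = np.asarray(series, dtype=float), "", 2.0
    if X.ndim != 2 or X.shape[1] != model.centroids.shape[1]:
        raise ValidationError(
            f"series dimension {X.shape} does not match centroids "
            f"{model.centroids.shape}"
        )
    D = _distances(X, model.centroids, model.distance)
    labels = D.argmin(axis=1) + 1  # argmin takes the lowest index on ties
    return StateSequence(subject_id=sid, labels=labels.astype(np.int64), tr_seconds=tr)


# ---------------------------------------------------------------------------
# dwell statistics

def _runs(labels: np.ndarray):
    """(state, run length) pairs of maximal constant runs."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(labels)]))
    return labels[starts], ends - starts


def dwell_statistics(seq: StateSequence, k: int | None = None) -> DwellStats:
    """Run-length scan of one dominant-state sequence.

    A state that never occurs has fraction 0 and NaN mean dwell.
    """
    labels = np.asarray(seq.labels)
    if labels.size == 0:
        raise ValidationError("state sequence is empty")
    k = int(k if k is not None else labels.max())
    if labels.min() < 1 or labels.max() > k:
        raise ValidationError(f"labels must lie in 1..{k}")
    n_w = labels.size
    fraction = np.bincount(labels, minlength=k + 1)[1:] / n_w
    run_states, run_lengths = _runs(labels)
    n_runs = np.zeros(k, dtype=np.int64)
    mean_dwell = np.full(k, np.nan)
    for s in range(1, k + 1):
        lens = run_lengths[run_states == s]
        n_runs[s - 1] = lens.size
        if lens.size:
            mean_dwell[s - 1] = lens.mean()
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    off = counts.copy()
    np.fill_diagonal(off, 0)
    n_transitions = int(off.sum())
    out_trans = off.sum(axis=1)
    trans = np.full((k, k), np.nan)
    absorbing = []
    for s in range(k):
        if out_trans[s] > 0:
            trans[s] = off[s] / out_trans[s]
        else:
            absorbing.append(s + 1)
    seconds = mean_dwell * seq.step_tr * seq.tr_seconds
    return DwellStats(
        k=k,
        fraction_time=fraction,
        mean_dwell_windows=mean_dwell,
        mean_dwell_seconds=seconds,
        n_runs=n_runs,
        n_transitions=n_transitions,
        transition_counts=counts,
        transition_matrix=trans,
        absorbing_rows=tuple(absorbing),
    )


# ---------------------------------------------------------------------------
# group comparison

def ttest_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> TTestResult:
    """Pooled-variance (homoscedastic) two-sample t-test from summaries.

    t = (m_a - m_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with
    s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2); the
    two-tailed p comes from the t distribution with n_a + n_b - 2 df.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 observations")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if pooled_var <= 0:
        if diff == 0:
            raise ValidationError("both groups degenerate: zero variance, equal means")
        warnings.warn("zero pooled variance with unequal means: p = 0")
        return TTestResult(t=float(np.sign(diff) * np.inf), p=0.0, df=df)
    t = diff / np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(p), df=df)


def compare_groups_ttest(values_a, values_b) -> TTestResult:
    """Pooled two-sample t-test of two groups of per-subject values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    return ttest_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
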