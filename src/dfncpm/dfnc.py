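"""Sliding-window dynamic functional connectivity estimation.

Each subject's T x C component time-course matrix is scanned with a
Gaussian-tapered sliding window (default 26 TR wide, taper sigma 3 TR,
advanced 1 TR at a time).  Within each window the connectivity among the C
components is estimated either as a taper-weighted Pearson correlation
matrix or as partial correlations from an L1-regularized (graphical lasso)
sparse inverse covariance.  The vectorized upper triangles across windows
form the subject's windowed-FC series, optionally Fisher z-transformed.

Window-count convention: with step 1, a T-volume series yields T - W
windows (the final window starting at T - W is dropped), so a 196-volume
acquisition with a 26-TR window gives 170 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso

from ._errors import ValidationError

__all__ = [
    "WindowSpec",
    "WindowedFCSeries",
    "build_taper",
    "sliding_windows",
    "estimate_windowed_fc",
    "pair_index",
]

_DEFAULT_LAMBDA_GRID = tuple(np.logspace(np.log10(0.01), 0.0, 10))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window and estimator settings.

    Defaults are the study parameters: 26-TR window, 1-TR step, Gaussian
    taper sigma of 3 TR, 10 subsampling repeats for the regularization
    selection, Fisher z on.
    """

    width_tr: int = 26
    step_tr: int = 1
    taper_sigma_tr: float = 3.0
    estimator: str = "pearson"  # "pearson" | "glasso"
    lambda_grid: tuple = _DEFAULT_LAMBDA_GRID
    n_regularization_repeats: int = 10
    fisher_z: bool = True

    def validate(self, n_volumes: int | None = None) -> None:
        if self.width_tr < 1:
            raise ValidationError("window width must be >= 1 TR")
        if self.step_tr < 1:
            raise ValidationError("window step must be >= 1 TR")
        if self.taper_sigma_tr <= 0:
            raise ValidationError("taper sigma must be positive")
        if self.estimator not in ("pearson", "glasso"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.estimator == "glasso" and len(self.lambda_grid) == 0:
            raise ValidationError("lambda grid must be nonempty for glasso")
        if n_volumes is not None and self.width_tr > n_volumes:
            raise ValidationError("window width exceeds the number of volumes")


@dataclass(frozen=True)
class WindowedFCSeries:
    """Per-subject sequence of vectorized window-wise FC estimates.

    ``values`` is N_w x P with P = C(C-1)/2; columns follow the row-major
    upper triangle (i < j, 0-based) ordering given by ``pairs``.
    """

    subject_id: str
    values: np.ndarray
    window_starts: np.ndarray
    pairs: tuple
    estimator: str
    fisher_z: bool
    lambda_: float | None = None
    tr_seconds: float = 2.0

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def pair_index(n_components: int) -> tuple:
    """Row-major upper-triangle (i, j) pairs, i < j, 0-based."""
    return tuple(
        (i, j) for i in range(n_components) for j in range(i + 1, n_components)
    )


def build_taper(width: int, sigma: float) -> np.ndarray:
    """Gaussian-tapered window weights.

    A rectangular window of length ``width`` is discretely convolved with a
    unit-area Gaussian kernel of standard deviation ``sigma`` (truncated at
    +/- 4 sigma); the central ``width`` samples are kept and renormalized to
    sum 1.  As sigma -> 0 the weights approach the uniform window.
    """
    if width < 1:
        raise ValidationError("width must be >= 1")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    half = int(np.ceil(4.0 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(width), kernel, mode="full")
    # crop the central `width` samples of the length width + 2*half result
    w = full[half : half + width]
    w = np.maximum(w, 0.0)
    return w / w.sum()


def sliding_windows(n_volumes: int, width: int, step: int = 1) -> np.ndarray:
    """Start indices of sliding windows under the T - W convention.

    Starts run 0, step, 2*step, ... while start + width <= n_volumes - 1,
    i.e. the window flush with the end of the series is dropped; with step 1
    this yields exactly n_volumes - width windows (196 volumes, width 26
    -> 170 windows).  Raises when no window fits.
    """
    if width > n_volumes:
        raise ValidationError(
            f"window width {width} exceeds series length {n_volumes}"
        )
    if step < 1:
        raise ValidationError("step must be >= 1")
    last = n_volumes - 1 - width  # largest admissible start
    if last < 0:
        raise ValidationError(
            f"no sliding window fits: width {width}, {n_volumes} volumes"
        )
    return np.arange(0, last + 1, step, dtype=np.int64)


def _weighted_correlation(X: np.ndarray, w: np.ndarray):
    """Taper-weighted covariance and correlation of window data X (W x C)."""
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    return cov, sd


def _window_correlation(X, w, subject_id, start):
    cov, sd = _weighted_correlation(X, w)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValidationError(
            f"subject {subject_id!r}: zero-variance column {int(bad[0])} "
            f"in window starting at volume {start}"
        )
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _glasso_precision(S: np.ndarray, lam: float) -> np.ndarray:
    if lam < 1e-12:
        return np.linalg.inv(S)
    _, precision = graphical_lasso(S, alpha=lam)
    return precision


def _select_lambda(corrs, spec: WindowSpec, rng: np.random.Generator):
    """Pick lambda* by repeated 80/20 subsampling of the subject's windows.

    For each split, graphical lasso is fitted at every grid value on the
    mean tapered correlation of the training windows; each fit is scored by
    the mean held-out Gaussian log-likelihood logdet(Theta) - tr(S_w Theta)
    over the test windows.  lambda* maximizes the mean score across splits;
    grid values that fail to converge on any split are dropped.
    """
    n_w = len(corrs)
    grid = np.asarray(spec.lambda_grid, dtype=float)
    scores = np.zeros(len(grid))
    alive = np.ones(len(grid), dtype=bool)
    n_test = max(1, int(round(0.2 * n_w)))
    for _ in range(spec.n_regularization_repeats):
        perm = rng.permutation(n_w)
        test, train = perm[:n_test], perm[n_test:]
        if train.size == 0:
            train = perm
        S_train = np.mean([corrs[i] for i in train], axis=0)
        for j, lam in enumerate(grid):
            if not alive[j]:
                continue
            try:
                theta = _glasso_precision(S_train, lam)
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                alive[j] = False
                warnings.warn(f"graphical lasso failed at lambda={lam:.4g}; dropped")
                continue
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                alive[j] = False
                continue
            ll = np.mean([logdet - np.trace(corrs[i] @ theta) for i in test])
            scores[j] += ll
    if not alive.any():
        raise ValidationError("graphical lasso failed at every lambda in the grid")
    scores[~alive] = -np.inf
    return float(grid[int(np.argmax(scores))])


def estimate_windowed_fc(
    timecourses: np.ndarray,
    spec: WindowSpec = WindowSpec(),
    subject_id: str = "",
    tr_seconds: float = 2.0,
    seed: int = 0,
) -> WindowedFCSeries:
    """Estimate a subject's windowed-FC series.

    Per window the columns are centered with the taper weights, the
    taper-weighted correlation matrix is formed and, for the ``glasso``
    estimator, converted to partial correlations
    rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj) from the L1-regularized
    precision at the subject-level lambda*.  Upper triangles are vectorized
    and Fisher z-transformed when enabled (atanh with |r| clipped at
    1 - 1e-7).
    """
    X = np.asarray(timecourses, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("timecourses must be T x C with C >= 2")
    if not np.isfinite(X).all():
        raise ValidationError("timecourses contain non-finite values")
    T, C = X.shape
    spec.validate(n_volumes=T)
    starts = sliding_windows(T, spec.width_tr, spec.step_tr)
    w = build_taper(spec.width_tr, spec.taper_sigma_tr)
    corrs = [
        _window_correlation(X[s : s + spec.width_tr], w, subject_id, s)
        for s in starts
    ]
    lam = None
    if spec.estimator == "glasso":
        rng = np.random.default_rng(seed)
        lam = _select_lambda(corrs, spec, rng)
        mats = [_partial_correlations(_glasso_precision(S, lam)) for S in corrs]
    else:
        mats = corrs
    iu = np.triu_indices(C, k=1)
    values = np.stack([m[iu] for m in mats])
    if spec.fisher_z:
        values = np.arctanh(np.clip(values, -1 + 1e-7, 1 - 1e-7))
    return WindowedFCSeries(
        subject_id=subject_id,
        values=values,
        window_starts=starts,
        pairs=pair_index(C),
        estimator=spec.estimator,
        fisher_z=spec.fisher_z,
        lambda_=lam,
        tr_seconds=tr_seconds,
    )
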