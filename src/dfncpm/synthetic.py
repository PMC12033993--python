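"""Synthetic cohorts of network time courses with Markov-switching covariance.

This module generates per-subject multivariate BOLD-like component time
courses whose instantaneous covariance switches among a small number of
latent connectivity states according to a group-specific first-order Markov
chain.  Every downstream stage of the pipeline (windowed connectivity,
state clustering, dwell statistics, sequential pattern mining,
classification) can therefore be validated against known ground truth:
the hidden state path, the generating covariances, and the group labels.

The default configuration emulates a resting-state acquisition of 196
volumes at TR = 2 s reduced to 11 network component time courses, with
three latent states — a hypo-connected state, a hyper-connected state and
an anticorrelated-block state — and two groups whose chains differ in how
strongly they dwell in the hypo-connected state.

Rows of the data matrix are independent draws given the hidden state (no
temporal autocorrelation); the hidden path is simulated at volume
resolution so sliding windows genuinely mix states around transitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError

__all__ = [
    "GroupSpec",
    "MotifSpec",
    "SyntheticConfig",
    "Subject",
    "Cohort",
    "GroundTruth",
    "default_groups",
    "make_state_covariances",
    "stationary_distribution",
    "simulate_state_sequence",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Correlation-profile names understood by :func:`make_state_covariances`.
PROFILES = ("hypo", "hyper", "anticorrelated-block")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size and its state transition matrix."""

    label: str
    n_subjects: int
    transition_matrix: tuple  # k x k nested tuples, row-stochastic

    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)


@dataclass(frozen=True)
class MotifSpec:
    """A group-specific state subsequence injected into hidden paths.

    With probability ``prob`` per subject of group ``group``, the states of
    ``states`` are written into the hidden path at a random position, each
    held for ``dwell_volumes`` consecutive volumes so the motif survives
    window-level dominant-state extraction.
    """

    group: str
    states: tuple
    prob: float
    dwell_volumes: int = 30


def default_groups() -> tuple:
    """Two-group default mirroring an impaired cohort biased toward the
    hypo-connected state 1: the "MCI"-like group has an elevated state-1
    self-transition and increased inflow to state 1."""
    p_hc = (
        (0.970, 0.015, 0.015),
        (0.010, 0.980, 0.010),
        (0.010, 0.010, 0.980),
    )
    p_mci = (
        (0.990, 0.005, 0.005),
        (0.020, 0.970, 0.010),
        (0.020, 0.010, 0.970),
    )
    return (GroupSpec("HC", 15, p_hc), GroupSpec("MCI", 15, p_mci))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the study-like conditions: C = 11 components,
    T = 196 volumes, TR = 2 s, k = 3 latent states.
    """

    n_components: int = 11
    n_states: int = 3
    n_volumes: int = 196
    tr_seconds: float = 2.0
    groups: tuple = field(default_factory=default_groups)
    noise_sd: float = 0.2
    seed: int = 0
    profiles: tuple = PROFILES
    motifs: tuple = ()

    def validate(self) -> None:
        if self.n_components < 2:
            raise ValidationError("n_components must be >= 2")
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.n_volumes <= 0:
            raise ValidationError("n_volumes must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if len(self.profiles) != self.n_states:
            raise ValidationError("need one covariance profile per state")
        group_labels = {g.label for g in self.groups}
        for g in self.groups:
            _validate_transition_matrix(g.matrix(), self.n_states)
            if g.n_subjects < 0:
                raise ValidationError(f"group {g.label!r}: negative size")
        for m in self.motifs:
            if m.group not in group_labels:
                raise ValidationError(f"motif group {m.group!r} not in cohort")
            if not all(1 <= s <= self.n_states for s in m.states):
                raise ValidationError("motif states out of range")
            if not 0.0 <= m.prob <= 1.0:
                raise ValidationError("motif probability must be in [0, 1]")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    tr_seconds: float
    data: np.ndarray  # T x C


@dataclass(frozen=True)
class Cohort:
    subjects: tuple

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "tr_seconds": [s.tr_seconds for s in self.subjects],
            }
        )

    def by_group(self) -> dict:
        out: dict = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Hidden state paths (labels 1..k), generating covariances, groups."""

    state_paths: dict  # subject_id -> length-T int array
    covariances: tuple  # k SPD C x C matrices, index s-1 for state s
    groups: dict  # subject_id -> group label


def _validate_transition_matrix(P: np.ndarray, k: int | None = None) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("transition matrix must be square")
    if k is not None and P.shape[0] != k:
        raise ValidationError(f"transition matrix must be {k}x{k}")
    if np.any(P < 0) or np.any(P > 1):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError("transition matrix rows must sum to 1")
    return P


def make_state_covariances(n_components, n_states, profiles, seed=0):
    """Build one SPD correlation matrix per latent state.

    Profiles
    --------
    ``hypo``
        Near-diagonal: every off-diagonal correlation has magnitude <= 0.1.
    ``hyper``
        One-factor structure with all off-diagonal correlations ~0.5
        (mean >= 0.4).
    ``anticorrelated-block``
        Two blocks with opposite-signed factor loadings, so cross-block
        correlations are <= -0.3.

    All constructions are factor models plus a positive diagonal, hence SPD
    by construction; a jittered retry guards against numerically borderline
    draws of the hypo profile.
    """
    if n_components < 2:
        raise ValidationError("n_components must be >= 2")
    if len(profiles) != n_states:
        raise ValidationError("need exactly one profile per state")
    rng = np.random.default_rng(seed)
    mats = []
    for profile in profiles:
        if profile not in PROFILES:
            raise ValidationError(f"unknown profile {profile!r}")
        mats.append(_one_covariance(n_components, profile, rng))
    return mats


def _one_covariance(C: int, profile: str, rng: np.random.Generator) -> np.ndarray:
    for attempt in range(20):
        if profile == "hypo":
            off = rng.uniform(-0.05, 0.05, size=(C, C))
            off = (off + off.T) / 2.0
            np.fill_diagonal(off, 0.0)
            sigma = np.eye(C) + off / (attempt + 1)
        elif profile == "hyper":
            loading = np.full(C, np.sqrt(0.5))
            sigma = np.outer(loading, loading)
            np.fill_diagonal(sigma, 1.0)
        else:  # anticorrelated-block
            half = C // 2
            loading = np.full(C, np.sqrt(0.35))
            loading[half:] *= -1.0
            sigma = np.outer(loading, loading)
            np.fill_diagonal(sigma, 1.0)
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals.min() > 1e-8:
            return sigma
    raise ValidationError(f"could not build an SPD {profile!r} covariance")


def stationary_distribution(transition_matrix) -> np.ndarray:
    """Stationary distribution of a row-stochastic chain.

    Solved as the least-squares solution of pi (P - I) = 0 with sum(pi) = 1;
    for reducible chains (e.g. the identity) this returns one valid
    stationary distribution.
    """
    P = _validate_transition_matrix(transition_matrix)
    k = P.shape[0]
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_state_sequence(transition_matrix, length, seed=None, rng=None):
    """Simulate a hidden state path of ``length`` labels in 1..k.

    The initial state is drawn from the chain's stationary distribution so
    occupancy statistics are stationary from the first volume.
    """
    P = _validate_transition_matrix(transition_matrix)
    if length < 1:
        raise ValidationError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = P.shape[0]
    pi = stationary_distribution(P)
    path = np.empty(length, dtype=np.int64)
    state = rng.choice(k, p=pi)
    path[0] = state + 1
    # cumulative rows let each step be a single uniform draw
    cum = np.cumsum(P, axis=1)
    u = rng.random(length - 1)
    for t in range(1, length):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        state = min(state, k - 1)
        path[t] = state + 1
    return path


def _inject_motif(path: np.ndarray, motif: MotifSpec, rng: np.random.Generator) -> np.ndarray:
    block = np.repeat(np.asarray(motif.states, dtype=np.int64), motif.dwell_volumes)
    if len(block) > len(path):
        raise ValidationError("motif longer than the time course")
    start = int(rng.integers(0, len(path) - len(block) + 1))
    out = path.copy()
    out[start : start + len(block)] = block
    return out


def simulate_cohort(config: SyntheticConfig):
    """Simulate a full cohort.

    Per subject, row t of the T x C matrix is drawn from a zero-mean
    multivariate normal with the covariance of the hidden state at volume t,
    plus isotropic Gaussian noise of standard deviation ``noise_sd``.

    Each subject uses an independent random substream keyed by
    ``(seed, group index, subject index)``, so subject i of a group is
    bit-for-bit identical regardless of how many other subjects exist.

    Returns ``(Cohort, GroundTruth)``.
    """
    config.validate()
    covs = make_state_covariances(
        config.n_components, config.n_states, config.profiles, seed=config.seed
    )
    chol = [np.linalg.cholesky(S) for S in covs]
    subjects = []
    paths: dict = {}
    groups: dict = {}
    for gi, group in enumerate(config.groups):
        P = group.matrix()
        motifs = [m for m in config.motifs if m.group == group.label]
        for si in range(group.n_subjects):
            rng = np.random.default_rng([config.seed, gi, si])
            path = simulate_state_sequence(P, config.n_volumes, rng=rng)
            for m in motifs:
                if rng.random() < m.prob:
                    path = _inject_motif(path, m, rng)
            z = rng.standard_normal((config.n_volumes, config.n_components))
            data = np.empty_like(z)
            for s in range(1, config.n_states + 1):
                mask = path == s
                data[mask] = z[mask] @ chol[s - 1].T
            if config.noise_sd > 0:
                data += config.noise_sd * rng.standard_normal(data.shape)
            sid = f"{group.label}_{si:03d}"
            subjects.append(Subject(sid, group.label, config.tr_seconds, data))
            paths[sid] = path
            groups[sid] = group.label
    return Cohort(tuple(subjects)), GroundTruth(paths, tuple(covs), groups)


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir) -> Path:
    """Write per-subject headerless CSVs, a manifest CSV and truth JSON.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        path = outdir / f"{s.subject_id}.csv"
        np.savetxt(path, s.data, delimiter=",")
        rows.append((s.subject_id, s.group, s.tr_seconds, path.name))
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "tr_seconds", "path"])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    truth_json = {
        "state_paths": {k: v.tolist() for k, v in truth.state_paths.items()},
        "covariances": [c.tolist() for c in truth.covariances],
        "groups": dict(truth.groups),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json))
    return manifest_path


def load_cohort(manifest_path) -> Cohort:
    """Load a cohort from a manifest CSV (columns subject_id, group,
    tr_seconds, path; paths relative to the manifest's directory)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ValidationError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "tr_seconds", "path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    subjects = []
    for row in manifest.itertuples(index=False):
        fp = Path(row.path)
        if not fp.is_absolute():
            fp = base / fp
        if not fp.exists():
            raise ValidationError(f"time-course file not found: {fp}")
        data = np.loadtxt(fp, delimiter=",", ndmin=2)
        subjects.append(Subject(str(row.subject_id), str(row.group), float(row.tr_seconds), data))
    return Cohort(tuple(subjects))
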