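import numpy as np
import pytest
from hypothesis import settings

import dfncpm as d

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject, 5-component cohort for fast integration tests."""
    base = (
        (0.95, 0.025, 0.025),
        (0.02, 0.96, 0.02),
        (0.02, 0.02, 0.96),
    )
    cfg = d.SyntheticConfig(
        n_components=5,
        n_volumes=120,
        groups=(d.GroupSpec("A", 3, base), d.GroupSpec("B", 3, base)),
        seed=7,
    )
    return d.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale default cohort: 30 subjects, 11 components, 196 volumes."""
    return d.simulate_cohort(d.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_series(default_cohort):
    cohort, _ = default_cohort
    spec = d.WindowSpec()
    return [
        d.estimate_windowed_fc(s.data, spec, subject_id=s.subject_id)
        for s in cohort.subjects
    ]


def brute_force_mine(sequences, alphabet, min_count, min_length, max_length):
    """Independent miner: enumerate every label tuple up to max_length and
    count sequence-level containment directly."""
    from itertools import product

    out = {}
    for L in range(min_length, max_length + 1):
        for pat in product(alphabet, repeat=L):
            count = sum(
                1 for s in sequences if _is_subsequence(pat, s)
            )
            if count >= min_count:
                out[pat] = count
    return out


def _is_subsequence(pattern, sequence):
    """Exhaustive-style containment check independent of the package."""
    pos = 0
    for x in sequence:
        if pos < len(pattern) and x == pattern[pos]:
            pos += 1
    return pos == len(pattern)
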