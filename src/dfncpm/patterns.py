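"""Sequential pattern mining over dominant-state sequences.

A sequential pattern is an ordered tuple of state labels contained — with
gaps allowed — in a subject's dominant-state sequence; its support in a
group is the number (or fraction) of that group's sequences containing it
at least once.  Mining uses prefix-projected depth-first enumeration
(PrefixSpan-style) with antimonotone support pruning, so the result is
exactly the set of patterns meeting the minimum support, with exact
sequence-level supports.

Dichotomic pattern mining runs the miner separately on two groups and
partitions the union of mined patterns into group-A-unique, group-B-unique
and shared sets.

By default sequences are run-length compressed before mining (maximal runs
of a repeated state collapse to one occurrence), so patterns describe the
transition structure — e.g. state 2 to state 1 and back to state 2 — rather
than raw dwell lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError

__all__ = [
    "MiningSpec",
    "PatternSet",
    "DPMResult",
    "compress_runs",
    "contains_pattern",
    "mine_patterns",
    "dichotomic_split",
    "pattern_name",
]


@dataclass(frozen=True)
class MiningSpec:
    """Mining constraints: minimum support as a fraction of the group's
    sequences, pattern length bounds, and the run-compression convention."""

    min_support: float = 0.05
    min_length: int = 2
    max_length: int = 10
    compress: bool = True

    def validate(self, n_sequences: int | None = None) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValidationError("min_support must be in (0, 1]")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValidationError("need 1 <= min_length <= max_length")
        if n_sequences is not None and self.absolute_support(n_sequences) < 1:
            raise ValidationError("support threshold below one sequence")

    def absolute_support(self, n_sequences: int) -> int:
        return math.ceil(self.min_support * n_sequences)


@dataclass(frozen=True)
class PatternSet:
    """Mined patterns of one group: pattern tuple -> sequence-level support."""

    patterns: dict
    n_sequences: int
    spec: MiningSpec

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, items) -> bool:
        return tuple(items) in self.patterns


@dataclass(frozen=True)
class DPMResult:
    """Dichotomic partition of two groups' mined patterns.

    Each mapping is pattern -> (support in A, support in B); a pattern
    missing from a group's mined set has support below that group's
    threshold and is reported as 0 here.
    """

    unique_a: dict
    unique_b: dict
    shared: dict

    @property
    def total(self) -> int:
        return len(self.unique_a) + len(self.unique_b) + len(self.shared)

    def summary(self) -> dict:
        return {
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "shared": len(self.shared),
            "total": self.total,
        }


def pattern_name(items) -> str:
    """Render a pattern as hyphen-joined state labels, e.g. '2-1-2'."""
    return "-".join(str(int(s)) for s in items)


def compress_runs(sequence):
    """Collapse maximal runs of identical labels to single occurrences."""
    seq = np.asarray(sequence)
    if seq.size == 0:
        raise ValidationError("sequence is empty")
    keep = np.concatenate(([True], seq[1:] != seq[:-1]))
    return seq[keep]


def contains_pattern(sequence, pattern) -> bool:
    """True iff ``pattern`` is a subsequence of ``sequence`` (order
    preserved, gaps allowed).  Greedy leftmost matching, which is exact for
    subsequence containment."""
    pattern = tuple(pattern)
    if len(pattern) == 0:
        raise ValidationError("pattern must be nonempty")
    it = iter(sequence)
    return all(any(x == p for x in it) for p in pattern)


def _prefixspan(sequences, threshold, max_length, min_length, out):
    """Depth-first prefix projection.

    ``projections`` maps nothing explicitly: each call receives, per
    sequence still active, the index from which the next item may match.
    """

    def recurse(prefix, proj, prefix_support):
        if len(prefix) >= max_length:
            return
        # candidate extensions: items occurring in any active suffix
        support: dict = {}
        for seq_idx, pos in proj:
            seen = set()
            seq = sequences[seq_idx]
            for x in seq[pos:]:
                if x not in seen:
                    seen.add(x)
                    support[x] = support.get(x, 0) + 1
        for item in sorted(support):
            s = support[item]
            if s < threshold:
                continue  # antimonotone pruning
            assert s <= prefix_support, "support must be antimonotone"
            new_prefix = prefix + (item,)
            new_proj = []
            for seq_idx, pos in proj:
                seq = sequences[seq_idx]
                j = _find_from(seq, item, pos)
                if j >= 0:
                    new_proj.append((seq_idx, j + 1))
            if len(new_prefix) >= min_length:
                out[new_prefix] = s
            recurse(new_prefix, new_proj, s)

    root = [(i, 0) for i in range(len(sequences))]
    recurse((), root, len(sequences))


def _find_from(seq, item, pos):
    for j in range(pos, len(seq)):
        if seq[j] == item:
            return j
    return -1


def mine_patterns(sequences, spec: MiningSpec = MiningSpec()) -> PatternSet:
    """Mine all sequential patterns meeting the minimum support.

    ``sequences`` is a collection of label sequences (arrays, lists or
    StateSequence-like objects with a ``labels`` attribute).  Sequences are
    run-length compressed first when ``spec.compress`` is on.  Returns the
    patterns p with min_length <= |p| <= max_length contained in at least
    ceil(min_support * n_sequences) sequences, with exact supports, in
    lexicographic order.
    """
    seqs = []
    for s in sequences:
        labels = getattr(s, "labels", s)
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValidationError("empty sequence in input")
        if spec.compress:
            labels = compress_runs(labels)
        seqs.append(tuple(int(x) for x in labels))
    if not seqs:
        raise ValidationError("no sequences to mine")
    spec.validate(n_sequences=len(seqs))
    threshold = spec.absolute_support(len(seqs))
    found: dict = {}
    _prefixspan(seqs, threshold, spec.max_length, spec.min_length, found)
    ordered = dict(sorted(found.items()))
    return PatternSet(patterns=ordered, n_sequences=len(seqs), spec=spec)


def dichotomic_split(patterns_a: PatternSet, patterns_b: PatternSet) -> DPMResult:
    """Partition two groups' mined pattern sets.

    unique_a = A \\ B, unique_b = B \\ A, shared = A intersect B, by exact
    item-tuple equality.  Both inputs must have been mined under the same
    MiningSpec.
    """
    if patterns_a.spec != patterns_b.spec:
        raise ValidationError("pattern sets were mined under different specs")
    a, b = patterns_a.patterns, patterns_b.patterns
    unique_a = {p: (s, 0) for p, s in a.items() if p not in b}
    unique_b = {p: (0, s) for p, s in b.items() if p not in a}
    shared = {p: (s, b[p]) for p, s in a.items() if p in b}
    result = DPMResult(unique_a=unique_a, unique_b=unique_b, shared=shared)
    # partition identity, asserted on every run
    assert result.total == len(set(a) | set(b))
    return result
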