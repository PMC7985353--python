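"""Temporal sequences: extraction, similarity, basis decomposition.

A Temporal Sequence (TSeq) is the causal walk of a single signal on the
graph: a time-ordered list of (node, step) pairs from a stimulated start
node to an end node of interest, with each hop an actual network edge
traversed in exactly its delay.  TSeqs are read off the simulation event
log by following causal parent links.

Three analyses operate on TSeq sets:

* A greedy in-order similarity measure between sequences, aggregated into
  per-threshold counts (how many reference walks survive in a comparison
  network).
* A basis decomposition splitting a TSeq set into One-Time sequences and
  groups of Repeating sequences that differ only in how many times a
  primitive sub-sequence (a realized graph cycle) repeats.
* Class-interaction counts: how many walks traverse every class in a given
  subset of node classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .engine import EventLog

__all__ = [
    "TemporalSequence",
    "TSeqSet",
    "CompressedTSeq",
    "BasisDecomposition",
    "SimilarityTable",
    "extract_tseqs",
    "pairwise_match_fraction",
    "lcs_match_fraction",
    "similarity_count",
    "similarity_table",
    "canonicalize",
    "recompose",
    "decompose_basis",
    "class_interaction_counts",
    "DEFAULT_ALPHAS",
]

DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class TemporalSequence:
    """A timed causal walk: node labels with strictly increasing steps."""

    nodes: tuple[str, ...]
    steps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.steps):
            raise ValueError("nodes and steps must have equal length")
        if not self.nodes:
            raise ValueError("a temporal sequence cannot be empty")
        if any(b <= a for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("steps must be strictly increasing")

    @property
    def start(self) -> tuple[str, int]:
        return self.nodes[0], self.steps[0]

    @property
    def terminus(self) -> tuple[str, int]:
        return self.nodes[-1], self.steps[-1]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class TSeqSet:
    """A deduplicated collection of TSeqs sharing a start node and end set."""

    sequences: tuple[TemporalSequence, ...]
    start_node: str
    end_nodes: frozenset[str]

    def __post_init__(self) -> None:
        keys = [(s.nodes, s.steps) for s in self.sequences]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate sequences in TSeqSet")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def label_sequences(self) -> list[tuple[str, ...]]:
        return [s.nodes for s in self.sequences]


class PathExplosionError(RuntimeError):
    """Raised when causal-path enumeration exceeds the configured cap."""


def extract_tseqs(
    log: EventLog,
    start_node: str,
    end_nodes: Iterable[str],
    max_paths: int | None = 10**6,
    dedupe_labels: bool = False,
) -> TSeqSet:
    """Enumerate every causal walk from the start node to the end nodes.

    Depth-first traversal of the causal event graph from each root
    (stimulus-driven) event of ``start_node``.  Every visit to an event of
    an end node — emitting or inhibited — records the current path as one
    TSeq; walks continuing past an end node yield additional, longer
    sequences.  Inhibited activations terminate a walk (no signal is
    emitted past them, so they have no causal children).

    By default two walks tracing the same labels at different times are
    distinct; ``dedupe_labels=True`` collapses them to one per label
    sequence.  Exceeding ``max_paths`` raises :class:`PathExplosionError`
    rather than truncating silently.
    """
    ends = frozenset(end_nodes)
    roots = log.root_events(start_node)
    if not roots:
        raise ValueError(f"start node {start_node!r} has no root event in log")
    by_id = log.events_by_id()
    children = log.children()

    found: dict[tuple, TemporalSequence] = {}
    # iterative DFS; stack entries are (event_id, path_so_far)
    for root in roots:
        stack: list[tuple[int, tuple[tuple[str, int], ...]]] = [
            (root.event_id, ((root.node, root.step),))
        ]
        while stack:
            eid, path = stack.pop()
            ev = by_id[eid]
            if ev.node in ends:
                seq = TemporalSequence(
                    nodes=tuple(n for n, _ in path),
                    steps=tuple(s for _, s in path),
                )
                key = seq.nodes if dedupe_labels else (seq.nodes, seq.steps)
                found.setdefault(key, seq)
                if max_paths is not None and len(found) > max_paths:
                    raise PathExplosionError(
                        f"more than {max_paths} causal paths; raise max_paths"
                    )
            for cid in children[eid]:
                child = by_id[cid]
                stack.append((cid, path + ((child.node, child.step),)))
    ordered = sorted(found.values(), key=lambda s: (s.steps[-1], s.nodes))
    return TSeqSet(
        sequences=tuple(ordered), start_node=start_node, end_nodes=ends
    )


def pairwise_match_fraction(
    x: TemporalSequence | Sequence[str], y: TemporalSequence | Sequence[str]
) -> float:
    """Greedy in-order label match of x against y, as a fraction of |x|.

    A single cursor scans y left to right: each successive label of x is
    matched to the first occurrence at or after the cursor, which then
    advances past it.  Asymmetric by construction — x is the reference.
    """
    xl = x.nodes if isinstance(x, TemporalSequence) else tuple(x)
    yl = y.nodes if isinstance(y, TemporalSequence) else tuple(y)
    if not xl or not yl:
        raise ValueError("sequences must be non-empty")
    cursor = 0
    matches = 0
    for label in xl:
        for w in range(cursor, len(yl)):
            if yl[w] == label:
                matches += 1
                cursor = w + 1
                break
    return matches / len(xl)


def lcs_match_fraction(
    x: TemporalSequence | Sequence[str], y: TemporalSequence | Sequence[str]
) -> float:
    """Longest-common-subsequence fraction |LCS(x, y)| / |x|.

    Diagnostic alternative to the greedy measure; never smaller than the
    greedy fraction is *not* guaranteed in general, but LCS is the maximal
    in-order match.  Not used by the standard pipeline.
    """
    xl = x.nodes if isinstance(x, TemporalSequence) else tuple(x)
    yl = y.nodes if isinstance(y, TemporalSequence) else tuple(y)
    if not xl or not yl:
        raise ValueError("sequences must be non-empty")
    prev = [0] * (len(yl) + 1)
    for a in xl:
        cur = [0]
        for j, b in enumerate(yl, 1):
            cur.append(prev[j - 1] + 1 if a == b else max(cur[-1], prev[j]))
        prev = cur
    return prev[-1] / len(xl)


def similarity_count(
    X: TSeqSet | Sequence, Y: TSeqSet | Sequence, alpha: float
) -> int:
    """Number of reference sequences whose best match in Y reaches alpha.

    c_alpha = |{x in X : max_y fraction(x, y) >= alpha}|.  Iteration over Y
    stops early once the threshold is met (the count is unchanged).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    xs = list(X)
    ys = list(Y)
    if not xs:
        raise ValueError("reference set X is empty")
    count = 0
    for x in xs:
        for y in ys:
            if pairwise_match_fraction(x, y) >= alpha:
                count += 1
                break
    return count


@dataclass(frozen=True)
class SimilarityTable:
    """Per-threshold match counts of a reference set against a comparison set."""

    alphas: tuple[float, ...]
    counts: tuple[int, ...]
    n_reference: int
    n_comparison: int

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.alphas, self.alphas[1:])):
            raise ValueError("alphas must be sorted ascending")
        if any(c2 > c1 for c1, c2 in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing in alpha")

    def as_rows(self) -> list[dict]:
        return [
            {
                "alpha": a,
                "count": c,
                "ref_size": self.n_reference,
                "cmp_size": self.n_comparison,
            }
            for a, c in zip(self.alphas, self.counts)
        ]


def similarity_table(
    X: TSeqSet | Sequence,
    Y: TSeqSet | Sequence,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> SimilarityTable:
    """Similarity counts across a grid of thresholds (default 0..1 by 0.25)."""
    alphas = tuple(alphas)
    counts = tuple(similarity_count(X, Y, a) for a in alphas)
    return SimilarityTable(
        alphas=alphas,
        counts=counts,
        n_reference=len(list(X)),
        n_comparison=len(list(Y)),
    )


@dataclass(frozen=True)
class CompressedTSeq:
    """Run-length form of a label sequence over primitive blocks.

    ``units`` is an ordered list of (block, count) pairs; expanding every
    block ``count`` times reproduces the original label sequence exactly.
    ``canonical`` is the fixed point of repeated tandem-repeat collapse —
    the label sequence with all repetition stripped — and is the key used
    to group sequences that differ only in repetition counts.
    """

    units: tuple[tuple[tuple[str, ...], int], ...]
    canonical: tuple[str, ...]

    def expand(self, counts: Sequence[int] | None = None) -> tuple[str, ...]:
        return recompose(self, counts)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(k for _, k in self.units)


def _collapse_once(
    labels: tuple[str, ...],
) -> tuple[tuple[tuple[str, ...], int], ...]:
    """One left-to-right pass collapsing maximal tandem repeats.

    At each position the smallest block period with >= 2 contiguous copies
    is collapsed (leftmost position wins by construction of the scan).
    """
    units: list[tuple[tuple[str, ...], int]] = []
    i, n = 0, len(labels)
    while i < n:
        hit = None
        for period in range(1, (n - i) // 2 + 1):
            block = labels[i : i + period]
            k = 1
            while labels[i + k * period : i + (k + 1) * period] == block:
                k += 1
            if k >= 2:
                hit = (block, k)
                break
        if hit is None:
            units.append(((labels[i],), 1))
            i += 1
        else:
            block, k = hit
            units.append((block, k))
            i += len(block) * k
    # merge adjacent singleton literals into runs for compactness
    merged: list[tuple[tuple[str, ...], int]] = []
    for block, k in units:
        if (
            k == 1
            and merged
            and merged[-1][1] == 1
            and len(merged[-1][0]) >= 1
            and len(block) == 1
        ):
            merged[-1] = (merged[-1][0] + block, 1)
        else:
            merged.append((block, k))
    return tuple(merged)


def canonicalize(x: TemporalSequence | Sequence[str]) -> CompressedTSeq:
    """Collapse tandem repeats into (primitive block, repetition) units.

    The stored units come from the first collapse pass, so expansion with
    the stored counts reproduces the input exactly.  The canonical label
    sequence iterates the collapse to a fixed point, handling nested
    repeats (e.g. ABABAB -> AB in one pass; AABAAB -> ABAB -> AB in two).
    """
    labels = x.nodes if isinstance(x, TemporalSequence) else tuple(x)
    if not labels:
        raise ValueError("cannot canonicalize an empty sequence")
    units = _collapse_once(labels)
    canon = tuple(itertools.chain.from_iterable(b for b, _ in units))
    while True:
        nxt = tuple(
            itertools.chain.from_iterable(b for b, _ in _collapse_once(canon))
        )
        if nxt == canon:
            break
        canon = nxt
    return CompressedTSeq(units=units, canonical=canon)


def recompose(
    c: CompressedTSeq, counts: Sequence[int] | None = None
) -> tuple[str, ...]:
    """Expand a compressed sequence, optionally with replacement counts."""
    if counts is None:
        counts = c.counts
    if len(counts) != len(c.units):
        raise ValueError(
            f"expected {len(c.units)} counts, got {len(counts)}"
        )
    if any(k < 1 for k in counts):
        raise ValueError("repetition counts must be positive")
    out: list[str] = []
    for (block, _), k in zip(c.units, counts):
        out.extend(block * k)
    return tuple(out)


@dataclass(frozen=True)
class BasisDecomposition:
    """Partition of a TSeq set into One-Time and Repeating sequences.

    ``repeating_groups`` maps a canonical label sequence to the members
    that collapse to it (each paired with its compressed form); groups have
    at least two members.  ``one_time`` holds every remaining sequence.
    The basis is one representative compressed sequence per repeating group
    plus all One-Time sequences: with repetition counts, it regenerates the
    whole set.
    """

    one_time: tuple[TemporalSequence, ...]
    repeating_groups: Mapping[
        tuple[str, ...], tuple[tuple[TemporalSequence, CompressedTSeq], ...]
    ]
    total: int

    @property
    def n_one_time(self) -> int:
        return len(self.one_time)

    @property
    def n_repeating_groups(self) -> int:
        return len(self.repeating_groups)

    @property
    def n_repeating_members(self) -> int:
        return sum(len(g) for g in self.repeating_groups.values())

    def basis(self) -> list[CompressedTSeq | TemporalSequence]:
        reps: list[CompressedTSeq | TemporalSequence] = [
            group[0][1] for group in self.repeating_groups.values()
        ]
        reps.extend(self.one_time)
        return reps


def decompose_basis(X: TSeqSet | Sequence) -> BasisDecomposition:
    """Group sequences by repeat-collapsed canonical form.

    Sequences sharing a canonical form (labels only; times ignored) differ
    only in repetition counts of primitive sub-sequences — realized graph
    cycles — and form one Repeating group.  Singleton canonical forms are
    One-Time sequences.  The result is a partition: every input sequence is
    in exactly one of the two sets.
    """
    xs = list(X)
    if not xs:
        raise ValueError("cannot decompose an empty TSeq set")
    compressed = [(x, canonicalize(x)) for x in xs]
    groups: dict[
        tuple[str, ...], list[tuple[TemporalSequence, CompressedTSeq]]
    ] = {}
    for x, c in compressed:
        groups.setdefault(c.canonical, []).append((x, c))
    one_time: list[TemporalSequence] = []
    repeating: dict[
        tuple[str, ...], tuple[tuple[TemporalSequence, CompressedTSeq], ...]
    ] = {}
    for canon, members in groups.items():
        if len(members) >= 2:
            repeating[canon] = tuple(members)
        else:
            one_time.append(members[0][0])
    return BasisDecomposition(
        one_time=tuple(one_time),
        repeating_groups=repeating,
        total=len(xs),
    )


def class_interaction_counts(
    X: TSeqSet | Sequence,
    class_map: Mapping[str, str | None],
    classes: Sequence[str],
    k: int,
) -> dict[frozenset[str], int]:
    """Count walks traversing every class of each k-subset of ``classes``.

    A walk counts toward subset S if it contains at least one node of every
    class in S (unordered containment); a walk may count toward many
    subsets.  Returns a count for every k-subset, including zeros.
    """
    classes = list(classes)
    if not 1 <= k <= len(classes):
        raise ValueError("k must satisfy 1 <= k <= len(classes)")
    known = {c for c in class_map.values() if c is not None}
    unknown = set(classes) - known
    if unknown:
        raise ValueError(f"classes absent from class map: {sorted(unknown)}")
    counts: dict[frozenset[str], int] = {
        frozenset(sub): 0 for sub in itertools.combinations(classes, k)
    }
    for x in X:
        labels = x.nodes if isinstance(x, TemporalSequence) else tuple(x)
        present = {
            class_map.get(n) for n in labels if class_map.get(n) in classes
        }
        for sub in counts:
            if sub <= present:
                counts[sub] += 1
    return counts
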