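"""Randomized network null models.

Three constructions used to ask whether an observed dynamical feature is a
consequence of the specific wiring or generic to networks of the same size:

* Gilbert randomization — every ordered node pair becomes an edge
  independently with probability p = e / (N (N - 1)), matching the expected
  edge count of the original network.
* Degree-preserving edge swap — pairs of edges exchange their targets,
  preserving every node's in- and out-degree and weak connectedness.
* Embedded randomization — a randomized subnetwork is substituted back into
  the full network, leaving all edges touching outside nodes intact.

Node positions, polarities and class labels are always preserved; only the
edge set changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import GeometricNetwork

__all__ = [
    "RandomizationReport",
    "gilbert_randomize",
    "edge_swap_randomize",
    "embed_randomized_subnetwork",
]


@dataclass(frozen=True)
class RandomizationReport:
    """Provenance record of one randomization run."""

    method: str
    seed: int | None
    n_edges_before: int
    n_edges_after: int
    n_successful_swaps: int | None = None
    connectedness_preserved: bool | None = None

    def __post_init__(self) -> None:
        if self.method == "edge_swap" and self.n_edges_before != self.n_edges_after:
            raise ValueError("edge swap must preserve the edge count")


def gilbert_randomize(
    net: GeometricNetwork, seed: int
) -> tuple[GeometricNetwork, RandomizationReport]:
    """Directed Gilbert (Erdos–Renyi G(n, p)) surrogate of ``net``.

    Each ordered pair (i, j), i != j, becomes an edge independently with
    probability p = e / (N (N - 1)); the diagonal is excluded (no
    self-loops).  The expected edge count equals the original edge count.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("Gilbert randomization needs at least 2 nodes")
    p = net.n_edges / (n * (n - 1))
    rng = np.random.default_rng(seed)
    names = net.node_names
    draws = rng.random((n, n))
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and draws[i, j] < p
    ]
    out = net.with_edges(edges)
    report = RandomizationReport(
        method="gilbert",
        seed=seed,
        n_edges_before=net.n_edges,
        n_edges_after=out.n_edges,
        connectedness_preserved=out.is_weakly_connected(),
    )
    return out, report


def edge_swap_randomize(
    net: GeometricNetwork, n_iterations: int = 10, seed: int = 0
) -> tuple[GeometricNetwork, RandomizationReport]:
    """Degree-preserving randomization by repeated target swaps.

    Per iteration, |E| swap attempts are made.  Each attempt draws two
    distinct edges (a, b) and (c, d) uniformly; the swap to (a, d), (c, b)
    is applied only when all four endpoints are pairwise distinct and
    neither new edge already exists.  A swap that disconnects the graph
    (weakly) is reverted and counted as unsuccessful, so edge count, both
    degree sequences and weak connectedness are preserved unconditionally.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not net.is_weakly_connected():
        raise ValueError("edge swap requires a weakly connected input network")
    rng = np.random.default_rng(seed)
    edges = list(net.edges)
    edge_set = set(edges)
    n_success = 0
    m = len(edges)
    for _ in range(n_iterations):
        for _ in range(m):
            if m < 2:
                break
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if len({a, b, c, d}) < 4:
                continue
            new1, new2 = (a, d), (c, b)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard((a, b))
            edge_set.discard((c, d))
            edge_set.add(new1)
            edge_set.add(new2)
            edges[i], edges[j] = new1, new2
            if net.with_edges(edges).is_weakly_connected():
                n_success += 1
            else:  # revert: the swap split off a component
                edge_set.discard(new1)
                edge_set.discard(new2)
                edge_set.add((a, b))
                edge_set.add((c, d))
                edges[i], edges[j] = (a, b), (c, d)
    out = net.with_edges(edges)
    report = RandomizationReport(
        method="edge_swap",
        seed=seed,
        n_edges_before=net.n_edges,
        n_edges_after=out.n_edges,
        n_successful_swaps=n_success,
        connectedness_preserved=out.is_weakly_connected(),
    )
    return out, report


def embed_randomized_subnetwork(
    full: GeometricNetwork,
    randomized_sub: GeometricNetwork,
    member_names: Sequence[str],
) -> GeometricNetwork:
    """Substitute a randomized subnetwork's edges back into the full network.

    Edges with both endpoints in ``member_names`` are replaced by the edges
    of ``randomized_sub``; every edge with at least one endpoint outside the
    member set is preserved.  Positions and polarities come from ``full``.
    """
    members = set(member_names)
    if set(randomized_sub.node_names) != members:
        raise ValueError("randomized_sub node set must equal member_names")
    if not members <= set(full.node_names):
        raise ValueError("member_names must be a subset of the full network")
    outside = [
        (u, v) for u, v in full.edges if u not in members or v not in members
    ]
    inside = list(randomized_sub.edges)
    return full.with_edges(outside + inside)
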