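"""Directed geometric networks and deterministic network constructions.

A geometric network is a directed graph whose nodes carry 3-D soma positions
(in micrometres), a signaling polarity (excitatory or inhibitory) and an
optional class label (e.g. "VB", "DB").  Edge signal delays are derived from
the Euclidean distance between somata and a constant conduction velocity,
discretized onto the simulation time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GeometricNetwork",
    "SignalingParams",
    "EXCITATORY",
    "INHIBITORY",
    "build_network",
    "euclidean_delay_steps",
    "extract_subnetwork",
    "lattice_variant",
]

EXCITATORY = "E"
INHIBITORY = "I"

#: Micrometres per millimetre; positions are stored in um, velocities in mm/s.
_UM_PER_MM = 1000.0


@dataclass(frozen=True)
class SignalingParams:
    """Physical signaling parameters of a simulation run.

    Parameters
    ----------
    conduction_velocity : float
        Signal conduction velocity in mm/s.
    refractory_period : float
        Node refractory period in seconds.
    dt : float
        Duration of one simulation step in seconds.
    n_steps : int
        Number of discrete simulation steps.

    The defaults model ~0.15 s of activity in 6000 steps (dt = 25 us) with an
    80 mm/s conduction velocity and a 4 ms refractory period.
    """

    conduction_velocity: float = 80.0
    refractory_period: float = 0.004
    dt: float = 0.15 / 6000
    n_steps: int = 6000

    def __post_init__(self) -> None:
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be positive")
        if self.refractory_period <= 0:
            raise ValueError("refractory_period must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be a positive integer")
        if self.refractory_steps < 1:
            raise ValueError("refractory_period must span at least one step")

    @property
    def refractory_steps(self) -> int:
        """Refractory period expressed in whole simulation steps."""
        return max(1, round(self.refractory_period / self.dt))


@dataclass(frozen=True)
class GeometricNetwork:
    """A validated directed graph with positions, polarities and class labels.

    ``positions`` may be ``None`` for networks used only with explicit delay
    assignments (e.g. the lattice variant).  Node order is the declaration
    order of ``node_names``; file exports index nodes by sorted name.
    """

    node_names: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    positions: Mapping[str, np.ndarray] | None
    polarity: Mapping[str, str]
    class_label: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.node_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        name_set = set(names)
        seen: set[tuple[str, str]] = set()
        for u, v in self.edges:
            if u not in name_set or v not in name_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
        if self.positions is not None:
            missing = name_set - set(self.positions)
            if missing:
                raise ValueError(f"positions missing for nodes: {sorted(missing)}")
            for name in names:
                p = np.asarray(self.positions[name], dtype=float)
                if p.shape != (3,):
                    raise ValueError(f"position of {name!r} is not 3-D")
                if not np.all(np.isfinite(p)):
                    raise ValueError(f"non-finite coordinate for node {name!r}")
        missing_pol = name_set - set(self.polarity)
        if missing_pol:
            raise ValueError(f"polarity missing for nodes: {sorted(missing_pol)}")
        for name in names:
            if self.polarity[name] not in (EXCITATORY, INHIBITORY):
                raise ValueError(
                    f"polarity of {name!r} must be {EXCITATORY!r} or {INHIBITORY!r}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def successors(self) -> dict[str, list[str]]:
        """Adjacency map source -> list of targets (edge declaration order)."""
        adj: dict[str, list[str]] = {name: [] for name in self.node_names}
        for u, v in self.edges:
            adj[u].append(v)
        return adj

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name in self.node_names:
            attrs: dict = {
                "polarity": self.polarity[name],
                "class_label": self.class_label.get(name),
            }
            if self.positions is not None:
                attrs["position"] = tuple(float(c) for c in self.positions[name])
            g.add_node(name, **attrs)
        g.add_edges_from(self.edges)
        return g

    def with_edges(self, edges: Iterable[tuple[str, str]]) -> "GeometricNetwork":
        """Copy of this network with a replacement edge set."""
        return GeometricNetwork(
            node_names=self.node_names,
            edges=tuple(edges),
            positions=self.positions,
            polarity=self.polarity,
            class_label=self.class_label,
        )

    def is_weakly_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        return nx.is_weakly_connected(self.to_networkx())


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def build_network(
    edge_list: Sequence[tuple[str, str]],
    node_table: Mapping[str, Mapping],
) -> tuple[GeometricNetwork, list[str]]:
    """Assemble a validated network from an edge list and a node table.

    ``node_table`` maps node name -> record with keys ``position`` (3-sequence
    in um, or ``None``), ``polarity`` ("E"/"I") and optional ``class_label``.
    Nodes whose position is ``None`` are dropped together with their incident
    edges — mirroring the reduction of the 302-neuron connectome to the
    neurons with known soma positions — and the dropped names are returned.

    Returns
    -------
    (network, dropped_names)
    """
    names = list(node_table)
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names in node table")
    for u, v in edge_list:
        if u not in node_table:
            raise ValueError(f"edge source {u!r} not in node table")
        if v not in node_table:
            raise ValueError(f"edge target {v!r} not in node table")

    dropped = [n for n in names if node_table[n].get("position") is None]
    dropped_set = set(dropped)
    kept = [n for n in names if n not in dropped_set]

    positions = {
        n: np.asarray(node_table[n]["position"], dtype=float) for n in kept
    }
    polarity = {n: node_table[n]["polarity"] for n in kept}
    class_label = {n: node_table[n].get("class_label") for n in kept}
    edges = tuple(
        (u, v)
        for u, v in edge_list
        if u not in dropped_set and v not in dropped_set
    )
    net = GeometricNetwork(
        node_names=tuple(kept),
        edges=edges,
        positions=positions,
        polarity=polarity,
        class_label=class_label,
    )
    return net, dropped


def euclidean_delay_steps(
    net: GeometricNetwork, params: SignalingParams
) -> dict[tuple[str, str], int]:
    """Integer edge delays from straight-line soma distance and velocity.

    delay(i, j) = max(1, round(||p_i - p_j|| / v / dt)), with half-away-from-
    zero rounding.  The clamp to one step prevents zero-delay causality
    violations for co-located somata.
    """
    if net.positions is None:
        raise ValueError("network has no positions; cannot derive delays")
    delays: dict[tuple[str, str], int] = {}
    for u, v in net.edges:
        dist_um = float(np.linalg.norm(net.positions[u] - net.positions[v]))
        dist_mm = dist_um / _UM_PER_MM
        raw = dist_mm / params.conduction_velocity / params.dt
        delays[(u, v)] = max(1, _round_half_away(raw))
    return delays


def extract_subnetwork(
    net: GeometricNetwork, member_names: Sequence[str]
) -> GeometricNetwork:
    """Induced subgraph on ``member_names``; attributes inherited unchanged."""
    member_set = set(member_names)
    unknown = member_set - set(net.node_names)
    if unknown:
        raise ValueError(f"unknown member names: {sorted(unknown)}")
    kept = tuple(n for n in net.node_names if n in member_set)
    edges = tuple((u, v) for u, v in net.edges if u in member_set and v in member_set)
    positions = (
        None
        if net.positions is None
        else {n: net.positions[n] for n in kept}
    )
    return GeometricNetwork(
        node_names=kept,
        edges=edges,
        positions=positions,
        polarity={n: net.polarity[n] for n in kept},
        class_label={n: net.class_label.get(n) for n in kept},
    )


def lattice_variant(
    net: GeometricNetwork,
    steps_per_tu: int = 10,
    n_steps: int = 6000,
) -> tuple[GeometricNetwork, dict[tuple[str, str], int], SignalingParams]:
    """Uniform-delay control network: geometry removed, adjacency kept.

    Every edge delay is one arbitrary time unit (tu) and the refractory
    period is 0.9 tu.  One tu is realized as ``steps_per_tu`` simulation
    steps (default 10) so the 0.9 refraction ratio is exact in integers:
    delay 10 steps, refractory 9 steps.  Positions are ignored.
    """
    if steps_per_tu < 10 or steps_per_tu % 10 != 0:
        raise ValueError("steps_per_tu must be a positive multiple of 10")
    delay_steps = steps_per_tu
    refractory_steps = (9 * steps_per_tu) // 10
    lattice = GeometricNetwork(
        node_names=net.node_names,
        edges=net.edges,
        positions=None,
        polarity=net.polarity,
        class_label=net.class_label,
    )
    delays = {edge: delay_steps for edge in net.edges}
    # dt chosen so refractory_period/dt lands exactly on refractory_steps
    params = SignalingParams(
        conduction_velocity=1.0,
        refractory_period=float(refractory_steps),
        dt=1.0,
        n_steps=n_steps,
    )
    return lattice, delays, params
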