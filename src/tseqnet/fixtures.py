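"""Deterministic toy networks with known ground truth, plus oracles.

Every generator is a pure function of its arguments, so fixtures are
regenerated from first principles at test time rather than stored.  The
geometric fixtures emulate the real inputs at toy scale: directed graphs
with 3-D soma positions in a worm-like elongated box, per-node polarity
and optional class labels.

The oracles (`oracle_enumerate_paths`, `oracle_unique_states`) are naive
exhaustive computations kept deliberately independent of the engine and
extraction code paths they cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import EventLog, StimulusEvent, run_simulation
from .network import EXCITATORY, GeometricNetwork, SignalingParams
from .tseq import TSeqSet, TemporalSequence

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "make_chain",
    "make_diamond",
    "make_cycle_with_tap",
    "make_random_geometric",
    "make_two_population",
    "oracle_enumerate_paths",
    "oracle_unique_states",
]

#: Worm-like placement box (x, y, z extents in um): long and thin so the
#: random fixtures get heterogeneous edge delays like the real embedding.
DEFAULT_BOX_UM = (50.0, 1000.0, 50.0)


def _params(n_steps: int, refractory_steps: int = 1) -> SignalingParams:
    """Unit-step parameters: dt = 1 s, velocity chosen so delays are explicit."""
    return SignalingParams(
        conduction_velocity=1.0,
        refractory_period=float(refractory_steps),
        dt=1.0,
        n_steps=n_steps,
    )


@dataclass(frozen=True)
class Fixture:
    """A generated network with machine-checkable ground truth."""

    network: GeometricNetwork
    delays: Mapping[tuple[str, str], int]
    params: SignalingParams
    stimuli: tuple[StimulusEvent, ...]
    #: expected (node, step) emitting activations, when forced by topology
    expected_firings: frozenset[tuple[str, int]] | None = None
    #: expected label sequences of TSeqs to the fixture's end set
    expected_tseq_labels: frozenset[tuple[str, ...]] | None = None
    end_nodes: frozenset[str] = frozenset()
    start_node: str = ""

    def run(self) -> EventLog:
        return run_simulation(self.network, self.delays, self.params, self.stimuli)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture (pure-function generation)."""

    kind: str
    n: int = 3
    delays: tuple[int, ...] | None = None
    delay: int = 3
    refractory: int = 2
    n_steps: int = 20
    p: float = 0.1
    seed: int = 0
    inhibitory: tuple[str, ...] = ()
    box_um: tuple[float, float, float] = DEFAULT_BOX_UM


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    if spec.kind == "chain":
        return make_chain(
            n=spec.n, delays=spec.delays, n_steps=spec.n_steps,
            inhibitory=spec.inhibitory,
        )
    if spec.kind == "diamond":
        return make_diamond(n_steps=spec.n_steps)
    if spec.kind == "cycle_with_tap":
        return make_cycle_with_tap(
            delay=spec.delay, refractory=spec.refractory, n_steps=spec.n_steps
        )
    if spec.kind == "random_geometric":
        return make_random_geometric(
            n=spec.n, p=spec.p, seed=spec.seed, n_steps=spec.n_steps,
            box_um=spec.box_um,
        )
    if spec.kind == "two_population":
        return make_two_population(n_steps=spec.n_steps)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def _line_net(
    names: Sequence[str],
    edges: Sequence[tuple[str, str]],
    inhibitory: Iterable[str] = (),
    classes: Mapping[str, str] | None = None,
) -> GeometricNetwork:
    inh = set(inhibitory)
    positions = {
        name: np.array([0.0, 10.0 * i, 0.0]) for i, name in enumerate(names)
    }
    return GeometricNetwork(
        node_names=tuple(names),
        edges=tuple(edges),
        positions=positions,
        polarity={n: ("I" if n in inh else EXCITATORY) for n in names},
        class_label={n: (classes or {}).get(n) for n in names},
    )


def make_chain(
    n: int = 3,
    delays: Sequence[int] | None = None,
    n_steps: int = 20,
    inhibitory: Iterable[str] = (),
) -> Fixture:
    """Feed-forward chain N0 -> N1 -> ... with explicit per-edge delays.

    Firing times are forced: node i fires at the prefix sum of delays
    (when all nodes are excitatory).
    """
    if n < 1:
        raise ValueError("chain needs at least one node")
    names = [f"N{i}" for i in range(n)]
    delays = tuple(delays) if delays is not None else tuple([2] * (n - 1))
    if len(delays) != n - 1:
        raise ValueError("need one delay per chain edge")
    edges = [(names[i], names[i + 1]) for i in range(n - 1)]
    net = _line_net(names, edges, inhibitory)
    delay_map = {e: d for e, d in zip(edges, delays)}
    times = np.concatenate([[0], np.cumsum(delays)]).astype(int)
    inh = set(inhibitory)
    expected: set[tuple[str, int]] = set()
    for name, t in zip(names, times):
        if t >= n_steps:
            break
        expected.add((name, int(t)))
        if name in inh:
            # downstream of the first inhibitory node nothing propagates:
            # the next node activates non-emitting, the rest stay silent
            break
    return Fixture(
        network=net,
        delays=delay_map,
        params=_params(n_steps),
        stimuli=(StimulusEvent(names[0], 0),),
        expected_firings=frozenset(expected),
        expected_tseq_labels=frozenset({tuple(names)}) if not inh else None,
        end_nodes=frozenset({names[-1]}),
        start_node=names[0],
    )


def make_diamond(n_steps: int = 20) -> Fixture:
    """Two equal-delay branches A -> {B, C} -> D.

    D's single activation has two causal parents, so exactly two TSeqs
    (A,B,D) and (A,C,D) reach D.
    """
    names = ["A", "B", "C", "D"]
    edges = [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    net = _line_net(names, edges)
    delays = {("A", "B"): 2, ("A", "C"): 2, ("B", "D"): 3, ("C", "D"): 3}
    return Fixture(
        network=net,
        delays=delays,
        params=_params(n_steps),
        stimuli=(StimulusEvent("A", 0),),
        expected_firings=frozenset({("A", 0), ("B", 2), ("C", 2), ("D", 5)}),
        expected_tseq_labels=frozenset(
            {("A", "B", "D"), ("A", "C", "D")}
        ),
        end_nodes=frozenset({"D"}),
        start_node="A",
    )


def make_cycle_with_tap(
    delay: int = 3, refractory: int = 2, n_steps: int = 13
) -> Fixture:
    """Oscillator A <-> B with a read-out tap B -> E.

    With both cycle delays equal and refractory < delay, the signal
    circulates with period 2 * delay; each B firing also drives E.  The
    number of TSeqs to E equals the number of B firings inside the window
    (each extra lap prepends one more (A, B) round trip).
    """
    if refractory >= delay:
        raise ValueError("refractory must be shorter than the cycle delay")
    names = ["A", "B", "E"]
    edges = [("A", "B"), ("B", "A"), ("B", "E")]
    net = _line_net(names, edges)
    delays = {("A", "B"): delay, ("B", "A"): delay, ("B", "E"): delay}
    b_firings = [t for t in range(delay, n_steps, 2 * delay)]
    e_firings = [t + delay for t in b_firings if t + delay < n_steps]
    expected_labels = set()
    for lap, _ in enumerate(e_firings):
        labels = ("A",) + ("B", "A") * lap + ("B", "E")
        expected_labels.add(labels)
    a_firings = [0] + [t + delay for t in b_firings if t + delay < n_steps]
    expected = (
        {("A", t) for t in a_firings}
        | {("B", t) for t in b_firings}
        | {("E", t) for t in e_firings}
    )
    return Fixture(
        network=net,
        delays=delays,
        params=_params(n_steps, refractory_steps=refractory),
        stimuli=(StimulusEvent("A", 0),),
        expected_firings=frozenset(expected),
        expected_tseq_labels=frozenset(expected_labels),
        end_nodes=frozenset({"E"}),
        start_node="A",
    )


def make_random_geometric(
    n: int = 30,
    p: float = 0.1,
    seed: int = 0,
    n_steps: int = 60,
    box_um: tuple[float, float, float] = DEFAULT_BOX_UM,
    inhibitory_fraction: float = 0.0,
    params: SignalingParams | None = None,
) -> Fixture:
    """Seeded directed random graph with uniform random 3-D placement.

    Placement is uniform in an elongated box (default 50 x 1000 x 50 um)
    so Euclidean delays are heterogeneous.  Delays here are drawn as small
    integers (1..5) to keep toy-scale dynamics busy; geometric delay
    derivation is exercised separately via `euclidean_delay_steps`.
    """
    rng = np.random.default_rng(seed)
    names = [f"R{i:02d}" for i in range(n)]
    positions = {
        name: rng.uniform([0, 0, 0], box_um) for name in names
    }
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    n_inh = int(round(inhibitory_fraction * n))
    inh = set(rng.choice(names, size=n_inh, replace=False)) if n_inh else set()
    net = GeometricNetwork(
        node_names=tuple(names),
        edges=tuple(edges),
        positions=positions,
        polarity={m: ("I" if m in inh else EXCITATORY) for m in names},
        class_label={m: None for m in names},
    )
    delays = {e: int(rng.integers(1, 6)) for e in edges}
    return Fixture(
        network=net,
        delays=delays,
        params=params or _params(n_steps),
        stimuli=(StimulusEvent(names[0], 0),),
        end_nodes=frozenset(names[-max(1, n // 5):]),
        start_node=names[0],
    )


def make_two_population(n_steps: int = 60) -> Fixture:
    """Start node driving two labeled groups through staggered delays.

    Mimics the ventral/dorsal motorneuron read-out at toy scale: an
    oscillating source alternately reaches the "V" group (short delays)
    and the "D" group (long delays), producing alternating class
    histograms.
    """
    v_nodes = [f"V{i}" for i in range(3)]
    d_nodes = [f"D{i}" for i in range(3)]
    names = ["S", "H"] + v_nodes + d_nodes
    edges = [("S", "H"), ("H", "S")]
    delays: dict[tuple[str, str], int] = {("S", "H"): 4, ("H", "S"): 4}
    for vn in v_nodes:
        edges.append(("S", vn))
        delays[("S", vn)] = 2
    for dn in d_nodes:
        edges.append(("H", dn))
        delays[("H", dn)] = 2
    # cross-population coupling so some walks traverse both classes; delay
    # chosen to land after the D nodes' refractory window
    for vn, dn in zip(v_nodes, d_nodes):
        edges.append((vn, dn))
        delays[(vn, dn)] = 7
    classes = {**{v: "V" for v in v_nodes}, **{d: "D" for d in d_nodes}}
    net = _line_net(names, edges, classes=classes)
    return Fixture(
        network=net,
        delays=delays,
        params=_params(n_steps, refractory_steps=3),
        stimuli=(StimulusEvent("S", 0),),
        end_nodes=frozenset(v_nodes + d_nodes),
        start_node="S",
    )


# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_enumerate_paths(
    log: EventLog, start: str, ends: Iterable[str], limit: int = 10**5
) -> TSeqSet:
    """Exhaustive causal-path enumeration by backward recursion.

    Walks parent links from every end-node event back to the start node's
    root events, enumerating every complete ancestry path.  Independent of
    `extract_tseqs` (which searches forward); results must agree exactly.
    """
    ends = frozenset(ends)
    by_id = log.events_by_id()
    roots = {ev.event_id for ev in log.root_events(start)}
    if not roots:
        raise ValueError(f"start node {start!r} has no root event in log")

    paths: set[tuple[tuple[str, ...], tuple[int, ...]]] = set()

    def back(eid: int, suffix: list[tuple[str, int]]) -> None:
        ev = by_id[eid]
        entry = (ev.node, ev.step)
        if eid in roots:
            full = [entry] + suffix
            paths.add(
                (tuple(n for n, _ in full), tuple(s for _, s in full))
            )
            if len(paths) > limit:
                raise RuntimeError("oracle search-space overflow")
        for pid in ev.parents:
            back(pid, [entry] + suffix)

    for ev in log.events:
        if ev.node in ends:
            back(ev.event_id, [])
    seqs = sorted(paths, key=lambda p: (p[1][-1], p[0]))
    return TSeqSet(
        sequences=tuple(
            TemporalSequence(nodes=n, steps=s) for n, s in seqs
        ),
        start_node=start,
        end_nodes=ends,
    )


def oracle_unique_states(state_matrix: np.ndarray) -> int:
    """Distinct-column count by naive set insertion over column tuples."""
    return len({tuple(col) for col in state_matrix.T})
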