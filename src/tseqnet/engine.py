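"""Discrete-time simulation of threshold-1 refractory signaling with delays.

The node model: a quiescent node activates the moment at least one signal
arrives.  On activation it emits one signal per outgoing edge (unless the
activation was triggered by an inhibitory signal, in which case nothing is
emitted) and becomes refractory for a fixed number of steps, during which
arriving signals are discarded.  Signals travel each edge in a fixed integer
number of steps.  Excitatory nodes emit excitatory signals, inhibitory
(GABAergic) nodes emit inhibitory signals; the threshold is one signal.

The output is an event log: every activation, time-stamped, with causal
parent links to the events whose signals triggered it.  The log is the
substrate for temporal-sequence extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import EXCITATORY, INHIBITORY, GeometricNetwork, SignalingParams

__all__ = [
    "StimulusEvent",
    "FiringEvent",
    "EventLog",
    "run_simulation",
    "firing_raster",
    "raster_node_order",
    "cumulative_unique_states",
    "class_activity_histogram",
]


@dataclass(frozen=True)
class StimulusEvent:
    """A single external pulse delivered to one node at one step."""

    node: str
    step: int = 0
    polarity: str = EXCITATORY


@dataclass(frozen=True)
class FiringEvent:
    """One node activation.

    ``emitted`` is False for activations triggered by an inhibitory signal
    (the node activates and becomes refractory but sends nothing on).
    ``parents`` holds the event ids of every same-step triggering arrival;
    it is empty only for stimulus-driven root events.
    """

    event_id: int
    node: str
    step: int
    emitted: bool
    parents: frozenset[int] = frozenset()


@dataclass(frozen=True)
class EventLog:
    """Step-ordered record of a simulation run."""

    events: tuple[FiringEvent, ...]
    network: GeometricNetwork
    delays: Mapping[tuple[str, str], int]
    params: SignalingParams
    stimuli: tuple[StimulusEvent, ...]

    def events_by_id(self) -> dict[int, FiringEvent]:
        return {ev.event_id: ev for ev in self.events}

    def children(self) -> dict[int, list[int]]:
        """Causal child links: event id -> ids of events it triggered."""
        kids: dict[int, list[int]] = {ev.event_id: [] for ev in self.events}
        for ev in self.events:
            for pid in ev.parents:
                kids[pid].append(ev.event_id)
        return kids

    def root_events(self, node: str) -> list[FiringEvent]:
        return [ev for ev in self.events if ev.node == node and not ev.parents]

    @property
    def n_emitting(self) -> int:
        return sum(1 for ev in self.events if ev.emitted)


def run_simulation(
    net: GeometricNetwork,
    delays: Mapping[tuple[str, str], int],
    params: SignalingParams,
    stimuli: Sequence[StimulusEvent],
) -> EventLog:
    """Run the threshold-1 delay/refractory model and return the event log.

    Arrivals are grouped per (node, step).  A node is eligible iff its last
    activation is at least ``refractory_steps`` ago; an eligible node with
    one or more arrivals activates.  If any arrival is inhibitory the
    activation is non-emitting (inhibition dominates within a step);
    otherwise one signal is emitted per outgoing edge, carrying the node's
    own polarity and arriving after the edge delay.  Arrivals at refractory
    nodes are discarded.  Signals still in flight at ``n_steps`` are lost.
    """
    if not stimuli:
        raise ValueError("at least one stimulus is required")
    names = set(net.node_names)
    for stim in stimuli:
        if stim.node not in names:
            raise ValueError(f"stimulus to unknown node {stim.node!r}")
        if not 0 <= stim.step < params.n_steps:
            raise ValueError(
                f"stimulus step {stim.step} outside [0, {params.n_steps})"
            )
    missing = net.edge_set() - set(delays)
    if missing:
        raise ValueError(f"delays missing for edges: {sorted(missing)[:5]}")

    succ = net.successors()
    refractory = params.refractory_steps
    # pending[step][node] -> list of (parent_event_id | None, polarity)
    pending: dict[int, dict[str, list[tuple[int | None, str]]]] = {}
    for stim in stimuli:
        pending.setdefault(stim.step, {}).setdefault(stim.node, []).append(
            (None, stim.polarity)
        )

    events: list[FiringEvent] = []
    last_fired: dict[str, int] = {}
    next_id = 0
    for step in range(params.n_steps):
        arrivals = pending.pop(step, None)
        if not arrivals:
            continue
        # deterministic order independent of arrival insertion order
        for node in sorted(arrivals):
            last = last_fired.get(node)
            if last is not None and step - last < refractory:
                continue  # refractory: arrivals discarded
            incoming = arrivals[node]
            inhibited = any(pol == INHIBITORY for _, pol in incoming)
            parents = frozenset(pid for pid, _ in incoming if pid is not None)
            ev = FiringEvent(
                event_id=next_id,
                node=node,
                step=step,
                emitted=not inhibited,
                parents=parents,
            )
            next_id += 1
            events.append(ev)
            last_fired[node] = step
            if ev.emitted:
                out_pol = net.polarity[node]
                for target in succ[node]:
                    arrive = step + delays[(node, target)]
                    if arrive < params.n_steps:
                        pending.setdefault(arrive, {}).setdefault(
                            target, []
                        ).append((ev.event_id, out_pol))
    return EventLog(
        events=tuple(events),
        network=net,
        delays=dict(delays),
        params=params,
        stimuli=tuple(stimuli),
    )


def raster_node_order(net: GeometricNetwork) -> list[str]:
    """Row order of the raster matrix: sorted node names (stable exports)."""
    return sorted(net.node_names)


def firing_raster(log: EventLog) -> np.ndarray:
    """N x T binary state matrix; y[i, t] = 1 iff node i emits at step t.

    Rows follow :func:`raster_node_order`.  Non-emitting (inhibited)
    activations are excluded: the state vector records signal output.
    """
    order = raster_node_order(log.network)
    index = {name: i for i, name in enumerate(order)}
    y = np.zeros((len(order), log.params.n_steps), dtype=np.uint8)
    for ev in log.events:
        if ev.emitted:
            y[index[ev.node], ev.step] = 1
    return y


def cumulative_unique_states(state_matrix: np.ndarray) -> np.ndarray:
    """Cumulative count of distinct network-state column vectors over time.

    c[t] = number of distinct columns among y(0..t); the all-zero quiescent
    state counts as a state.
    """
    n, t_max = state_matrix.shape
    seen: set[bytes] = set()
    counts = np.empty(t_max, dtype=np.int64)
    cols = np.ascontiguousarray(state_matrix.T)
    for t in range(t_max):
        seen.add(cols[t].tobytes())
        counts[t] = len(seen)
    return counts


def class_activity_histogram(
    log: EventLog,
    class_map: Mapping[str, str | None] | None = None,
    bin_steps: int = 250,
) -> dict[str, np.ndarray]:
    """Per-class time-binned counts of emitting activations.

    ``class_map`` defaults to the network's own class labels; nodes mapping
    to ``None`` are unclassified and excluded.  Bin k covers steps
    [k*bin_steps, (k+1)*bin_steps).
    """
    if bin_steps < 1:
        raise ValueError("bin_steps must be >= 1")
    if class_map is None:
        class_map = log.network.class_label
    n_bins = -(-log.params.n_steps // bin_steps)  # ceil division
    classes = sorted({c for c in class_map.values() if c is not None})
    hist = {c: np.zeros(n_bins, dtype=np.int64) for c in classes}
    for ev in log.events:
        if not ev.emitted:
            continue
        cls = class_map.get(ev.node)
        if cls is None:
            continue
        hist[cls][ev.step // bin_steps] += 1
    return hist
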