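"""File formats, run configuration and the end-to-end pipeline.

Network bundle (a directory):
    nodes.csv   — name,x_um,y_um,z_um,polarity,class  (class may be empty)
    edges.csv   — source,target
    delays.csv  — source,target,steps  (optional; overrides geometric delays)

Event logs are CSV (`event_id,node,step,emitted,parent_ids`, parents
semicolon-joined), TSeq sets are JSON lines, similarity tables are CSV.
All node references in files are by name; indices in matrix exports follow
sorted name order so outputs are stable across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import (
    EventLog,
    FiringEvent,
    StimulusEvent,
    class_activity_histogram,
    cumulative_unique_states,
    firing_raster,
    raster_node_order,
    run_simulation,
)
from .network import GeometricNetwork, SignalingParams, euclidean_delay_steps
from .tseq import (
    DEFAULT_ALPHAS,
    SimilarityTable,
    TSeqSet,
    TemporalSequence,
    decompose_basis,
    extract_tseqs,
    similarity_table,
)

__all__ = [
    "RunConfig",
    "save_network_bundle",
    "load_network_bundle",
    "save_event_log",
    "load_event_log_frame",
    "save_tseqs",
    "load_tseqs",
    "save_similarity_table",
    "tseq_plot_data",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Network bundle


def save_network_bundle(
    net: GeometricNetwork,
    dir_path: str | Path,
    delays: Mapping[tuple[str, str], int] | None = None,
) -> Path:
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(net.node_names):
        pos = net.positions[name] if net.positions is not None else (None,) * 3
        rows.append(
            {
                "name": name,
                "x_um": pos[0],
                "y_um": pos[1],
                "z_um": pos[2],
                "polarity": net.polarity[name],
                "class": net.class_label.get(name) or "",
            }
        )
    pd.DataFrame(rows).to_csv(out / "nodes.csv", index=False)
    pd.DataFrame(sorted(net.edges), columns=["source", "target"]).to_csv(
        out / "edges.csv", index=False
    )
    if delays is not None:
        pd.DataFrame(
            [(u, v, delays[(u, v)]) for u, v in sorted(net.edges)],
            columns=["source", "target", "steps"],
        ).to_csv(out / "delays.csv", index=False)
    return out


def load_network_bundle(
    dir_path: str | Path,
) -> tuple[GeometricNetwork, dict[tuple[str, str], int] | None]:
    """Load and validate a bundle; returns (network, delays-or-None)."""
    d = Path(dir_path)
    nodes_path, edges_path = d / "nodes.csv", d / "edges.csv"
    for p in (nodes_path, edges_path):
        if not p.exists():
            raise FileNotFoundError(f"missing bundle file: {p}")
    nodes = pd.read_csv(nodes_path, dtype={"name": str})
    required = {"name", "x_um", "y_um", "z_um", "polarity"}
    if not required <= set(nodes.columns):
        raise ValueError(f"nodes.csv must have columns {sorted(required)}")
    edges_df = pd.read_csv(edges_path, dtype=str)
    if not {"source", "target"} <= set(edges_df.columns):
        raise ValueError("edges.csv must have columns source,target")
    names = list(nodes["name"])
    name_set = set(names)
    for row_i, (u, v) in enumerate(zip(edges_df["source"], edges_df["target"])):
        if u not in name_set or v not in name_set:
            raise ValueError(
                f"edges.csv row {row_i}: edge ({u!r}, {v!r}) names unknown node"
            )
    have_pos = not nodes[["x_um", "y_um", "z_um"]].isna().any(axis=None)
    positions = (
        {
            r["name"]: np.array([r["x_um"], r["y_um"], r["z_um"]], dtype=float)
            for _, r in nodes.iterrows()
        }
        if have_pos
        else None
    )
    classes = (
        {
            r["name"]: (None if pd.isna(r.get("class")) or r.get("class") == ""
                        else str(r["class"]))
            for _, r in nodes.iterrows()
        }
        if "class" in nodes.columns
        else {}
    )
    net = GeometricNetwork(
        node_names=tuple(names),
        edges=tuple(zip(edges_df["source"], edges_df["target"])),
        positions=positions,
        polarity={r["name"]: r["polarity"] for _, r in nodes.iterrows()},
        class_label=classes,
    )
    delays = None
    if (d / "delays.csv").exists():
        ddf = pd.read_csv(d / "delays.csv", dtype={"source": str, "target": str})
        delays = {
            (r["source"], r["target"]): int(r["steps"]) for _, r in ddf.iterrows()
        }
        missing = net.edge_set() - set(delays)
        if missing:
            raise ValueError(f"delays.csv missing edges: {sorted(missing)[:5]}")
    return net, delays


# ---------------------------------------------------------------------------
# Event log / TSeq / table serialization


def save_event_log(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "event_id": ev.event_id,
            "node": ev.node,
            "step": ev.step,
            "emitted": int(ev.emitted),
            "parent_ids": ";".join(str(p) for p in sorted(ev.parents)),
        }
        for ev in log.events
    ]
    pd.DataFrame(
        rows, columns=["event_id", "node", "step", "emitted", "parent_ids"]
    ).to_csv(path, index=False)
    return path


def load_event_log_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"node": str, "parent_ids": str})


def save_tseqs(tseqs: TSeqSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for seq in tseqs:
            fh.write(
                json.dumps(
                    {
                        "nodes": list(seq.nodes),
                        "steps": list(seq.steps),
                        "terminus": seq.terminus[0],
                    }
                )
                + "\n"
            )
    return path


def load_tseqs(
    path: str | Path, start_node: str = "", end_nodes: Sequence[str] = ()
) -> TSeqSet:
    seqs = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            seqs.append(
                TemporalSequence(
                    nodes=tuple(obj["nodes"]), steps=tuple(obj["steps"])
                )
            )
    start = start_node or (seqs[0].nodes[0] if seqs else "")
    ends = frozenset(end_nodes) or frozenset(s.terminus[0] for s in seqs)
    return TSeqSet(sequences=tuple(seqs), start_node=start, end_nodes=ends)


def save_similarity_table(table: SimilarityTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(table.as_rows()).to_csv(path, index=False)
    return path


def tseq_plot_data(tseqs: TSeqSet, net: GeometricNetwork) -> pd.DataFrame:
    """Per-sequence polylines (step, node_index) for plotting.

    Node indices follow sorted name order; the end-node indices give the
    heights for horizontal guide lines.
    """
    order = {name: i for i, name in enumerate(raster_node_order(net))}
    rows = []
    for sid, seq in enumerate(tseqs):
        for node, step in zip(seq.nodes, seq.steps):
            rows.append({"tseq_id": sid, "step": step, "node_index": order[node]})
    return pd.DataFrame(rows, columns=["tseq_id", "step", "node_index"])


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation + analysis run."""

    network_dir: str
    out_dir: str
    start_node: str
    end_nodes: tuple[str, ...] = ()
    end_classes: tuple[str, ...] = ()
    stimulus_step: int = 0
    conduction_velocity: float = 80.0
    refractory_period: float = 0.004
    dt: float = 0.15 / 6000
    n_steps: int = 6000
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    bin_steps: int = 250
    dedupe_labels: bool = False
    max_paths: int = 10**6

    def params(self) -> SignalingParams:
        return SignalingParams(
            conduction_velocity=self.conduction_velocity,
            refractory_period=self.refractory_period,
            dt=self.dt,
            n_steps=self.n_steps,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("end_nodes", "end_classes", "alphas"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Simulate, summarize and analyze one network end to end.

    Writes the event log, raster, unique-state curve, class histograms,
    TSeq JSONL, self-similarity table, basis decomposition summary and a
    manifest.  Deterministic: rerunning an identical config reproduces
    byte-identical analysis artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "artifacts": []}

    def _stage(name: str):
        manifest["stage"] = name

    try:
        _stage("load")
        net, delays = load_network_bundle(cfg.network_dir)
        params = cfg.params()
        if delays is None:
            delays = euclidean_delay_steps(net, params)

        _stage("simulate")
        log = run_simulation(
            net, delays, params, [StimulusEvent(cfg.start_node, cfg.stimulus_step)]
        )
        save_event_log(log, out / "events.csv")
        manifest["artifacts"].append("events.csv")
        manifest["n_events"] = len(log.events)

        _stage("raster")
        y = firing_raster(log)
        coords = np.argwhere(y == 1)
        order = raster_node_order(net)
        pd.DataFrame(
            [(order[i], int(t)) for i, t in coords], columns=["node", "step"]
        ).to_csv(out / "raster.csv", index=False)
        manifest["artifacts"].append("raster.csv")

        _stage("unique_states")
        curve = cumulative_unique_states(y)
        pd.DataFrame(
            {"step": np.arange(len(curve)), "cumulative_unique_states": curve}
        ).to_csv(out / "unique_states.csv", index=False)
        manifest["artifacts"].append("unique_states.csv")
        manifest["n_unique_states"] = int(curve[-1])

        _stage("class_histogram")
        hist = class_activity_histogram(log, bin_steps=cfg.bin_steps)
        hrows = [
            {"class": cls, "bin": b, "count": int(c)}
            for cls, counts in hist.items()
            for b, c in enumerate(counts)
        ]
        pd.DataFrame(hrows, columns=["class", "bin", "count"]).to_csv(
            out / "class_histogram.csv", index=False
        )
        manifest["artifacts"].append("class_histogram.csv")

        _stage("tseqs")
        ends = set(cfg.end_nodes)
        if cfg.end_classes:
            ends |= {
                n
                for n in net.node_names
                if net.class_label.get(n) in set(cfg.end_classes)
            }
        if not ends:
            raise ValueError("config names no end nodes or end classes")
        tseqs = extract_tseqs(
            log,
            cfg.start_node,
            ends,
            max_paths=cfg.max_paths,
            dedupe_labels=cfg.dedupe_labels,
        )
        save_tseqs(tseqs, out / "tseqs.jsonl")
        manifest["artifacts"].append("tseqs.jsonl")
        manifest["n_tseqs"] = len(tseqs)
        tseq_plot_data(tseqs, net).to_csv(out / "tseq_plot.csv", index=False)
        manifest["artifacts"].append("tseq_plot.csv")

        _stage("similarity")
        if len(tseqs):
            table = similarity_table(tseqs, tseqs, cfg.alphas)
            save_similarity_table(table, out / "similarity_self.csv")
            manifest["artifacts"].append("similarity_self.csv")

        _stage("basis")
        if len(tseqs):
            basis = decompose_basis(tseqs)
            with open(out / "basis.json", "w") as fh:
                json.dump(
                    {
                        "n_tseqs": basis.total,
                        "n_one_time": basis.n_one_time,
                        "n_repeating_groups": basis.n_repeating_groups,
                        "n_repeating_members": basis.n_repeating_members,
                        "groups": [
                            {
                                "canonical": list(canon),
                                "size": len(members),
                            }
                            for canon, members in basis.repeating_groups.items()
                        ],
                    },
                    fh,
                    indent=2,
                )
            manifest["artifacts"].append("basis.json")

        _stage("done")
    finally:
        manifest.setdefault("n_tseqs", None)
        cfg.to_yaml(out / "config.yaml")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
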