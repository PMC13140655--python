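"""File formats: delimited recordings, manifests, network exports, config.

Recordings travel as one CSV per recording (``breath_index`` plus the
seven channel columns); a cohort is a directory of such files described
by a JSON manifest.  Networks are interchanged as adjacency CSV (the
canonical form; metadata in ``#`` comment lines), with edge-list JSON,
GraphML (node attributes ``ID``/``OD``, edge attribute ``te_bits``) and
node-size/edge-width diagram JSON as derived views.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import TEMatrix, weighted_degrees
from .series import CHANNELS, BreathSeries, ParticipantRecording
from .synthetic import Cohort

__all__ = [
    "write_recording", "read_recording", "write_cohort", "read_manifest",
    "write_network_csv", "read_network_csv", "write_network_json",
    "read_network_json", "write_network_graphml", "write_diagram_json",
    "PipelineConfig",
]


# ---------------------------------------------------------------------------
# Recordings and manifests

def write_recording(recording: ParticipantRecording, path) -> Path:
    """One row per breath: breath_index followed by the seven channels."""
    path = Path(path)
    data = {"breath_index": recording[CHANNELS[0]].breath_index}
    for c in CHANNELS:
        data[c] = recording[c].values
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_recording(path, *, participant_id: str, condition: str, phase: str,
                   column_map: dict[str, str] | None = None) -> ParticipantRecording:
    """Read a delimited recording; ``column_map`` renames vendor columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate columns {dup}")
    idx = (df["breath_index"].to_numpy(dtype=int)
           if "breath_index" in df.columns else np.arange(len(df)))
    for c in CHANNELS:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{path}: column {c} contains non-numeric cells")
    channels = {c: BreathSeries(c, df[c].to_numpy(dtype=float), idx.copy())
                for c in CHANNELS}
    return ParticipantRecording(participant_id=participant_id,
                                condition=condition, phase=phase,
                                channels=channels)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write every recording plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    flags = cohort.table.set_index(["participant_id", "condition"])
    for (pid, cond, phase), rec in sorted(cohort.recordings.items()):
        fname = f"{pid}_{cond}_{phase}.csv"
        write_recording(rec, rec_dir / fname)
        row = flags.loc[(pid, cond)]
        entries.append({
            "participant_id": pid, "sex": str(row["sex"]),
            "condition": cond, "phase": phase,
            "file": f"recordings/{fname}",
            "symptom": bool(row["symptom"]), "headache": bool(row["headache"]),
            "spo2": float(row["spo2"]), "fio2": float(row["fio2"]),
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=1))
    return manifest


def read_manifest(path) -> list[dict]:
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = payload["recordings"] if isinstance(payload, dict) else payload
    for e in entries:
        for key in ("participant_id", "condition", "phase", "file"):
            if key not in e:
                raise ValueError(f"manifest entry missing {key!r}: {e}")
    return entries


# ---------------------------------------------------------------------------
# Network formats

def write_network_csv(matrix: TEMatrix, path) -> Path:
    """Canonical adjacency CSV: header row/column, metadata as # comments."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(matrix.metadata.items())]
    df = pd.DataFrame(matrix.weights, index=matrix.nodes, columns=matrix.nodes)
    body = df.to_csv(float_format="%.17g")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path


def read_network_csv(path) -> TEMatrix:
    path = Path(path)
    metadata = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line.lstrip("# ").split("=", 1)
            metadata[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", index_col=0)
    return TEMatrix(weights=df.to_numpy(dtype=float),
                    nodes=tuple(df.index), metadata=metadata)


def write_network_json(matrix: TEMatrix, path) -> Path:
    """Edge-list JSON view (positive-weight edges only)."""
    path = Path(path)
    edges = [{"source": matrix.nodes[i], "target": matrix.nodes[j],
              "te_bits": float(matrix.weights[i, j])}
             for i, j in zip(*np.nonzero(matrix.weights > 0))]
    payload = {"nodes": list(matrix.nodes), "metadata": matrix.metadata,
               "edges": edges}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_network_json(path) -> TEMatrix:
    payload = json.loads(Path(path).read_text())
    nodes = tuple(payload["nodes"])
    idx = {n: i for i, n in enumerate(nodes)}
    weights = np.zeros((len(nodes), len(nodes)))
    for e in payload["edges"]:
        weights[idx[e["source"]], idx[e["target"]]] = e["te_bits"]
    return TEMatrix(weights=weights, nodes=nodes,
                    metadata=payload.get("metadata", {}))


def write_network_graphml(matrix: TEMatrix, path) -> Path:
    """GraphML with ID/OD node attributes and te_bits edge attributes."""
    g = nx.DiGraph()
    profile = weighted_degrees(matrix)
    for i, node in enumerate(matrix.nodes):
        g.add_node(node, ID=float(profile.indegree[i]),
                   OD=float(profile.outdegree[i]))
    for i, j in zip(*np.nonzero(matrix.weights > 0)):
        g.add_edge(matrix.nodes[i], matrix.nodes[j],
                   te_bits=float(matrix.weights[i, j]))
    for k, v in matrix.metadata.items():
        g.graph[k] = str(v)
    nx.write_graphml(g, path)
    return Path(path)


def write_diagram_json(matrix: TEMatrix, path, size_by: str = "ID") -> Path:
    """Plot-ready data: node sizes proportional to degree, widths to TE."""
    profile = weighted_degrees(matrix)
    sizes = profile.indegree if size_by == "ID" else profile.outdegree
    payload = {
        "metadata": matrix.metadata,
        "size_by": size_by,
        "nodes": [{"node": n, "size": float(s)}
                  for n, s in zip(matrix.nodes, sizes)],
        "edges": [{"source": matrix.nodes[i], "target": matrix.nodes[j],
                   "width": float(matrix.weights[i, j])}
                  for i, j in zip(*np.nonzero(matrix.weights > 0))],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Resolved settings for an end-to-end run; serialisable to YAML."""

    lag: int = 5
    partition: str = "quantile_bins"
    n_bins: int = 6
    n_shuffles: int = 100
    percentile: float = 95.0
    hampel_window: int = 11
    hampel_threshold: float = 3.0
    gg_threshold: float = 0.05
    seed: int = 0
    output_dir: str = "breathnet_out"
    control_condition: str = "CTR"
    column_map: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.lag < 1 or self.n_bins < 2:
            raise ValueError("lag must be >= 1 and n_bins >= 2")
        if self.n_shuffles < 20:
            raise ValueError("n_shuffles must be >= 20")
        if not 50 < self.percentile < 100:
            raise ValueError("percentile must lie in (50, 100)")
        if self.hampel_window < 3 or self.hampel_window % 2 == 0:
            raise ValueError("hampel_window must be an odd integer >= 3")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload).validate()

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return Path(path)
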