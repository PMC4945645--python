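"""Plain-text artifact exports for every pipeline stage.

Layers go out as TSV edge lists plus GraphML with a JSON band sidecar; the
supra-adjacency as sparse coordinate triples with a JSON header; descriptor
tables, distance matrices, quality trajectories and centrality profiles as
CSV; dendrograms as Newick strings over layer labels; classification reports
as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .connectivity import LayerNetwork
from .centrality import CentralityProfile
from .descriptors import LayerDescriptorSet
from .multiplex import MultiplexNetwork, supra_adjacency
from .reducibility import ReducibilityResult

__all__ = [
    "write_layers",
    "read_layer_edgelist",
    "write_supra_adjacency",
    "descriptor_table",
    "write_reducibility",
    "linkage_to_newick",
    "profile_table",
    "write_report",
]


def write_layers(layers: list[LayerNetwork], directory: str | Path, prefix: str = "layer") -> None:
    """One TSV edge list and one GraphML file per band + JSON band sidecar."""
    import networkx as nx

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for k, layer in enumerate(layers):
        stem = f"{prefix}_{k:02d}"
        i, j = np.nonzero(np.triu(layer.z, k=1))
        with open(directory / f"{stem}.tsv", "w") as fh:
            fh.write("node_i\tnode_j\tz\n")
            for a, b in zip(i, j):
                fh.write(f"{a}\t{b}\t{layer.z[a, b]:.12g}\n")
        g = layer.to_networkx()
        g.graph.pop("band", None)
        g.graph["band_low_hz"], g.graph["band_high_hz"] = map(float, layer.band)
        nx.write_graphml(g, directory / f"{stem}.graphml")
        meta.append({"file": f"{stem}.tsv", "band_hz": list(layer.band),
                     "n_nodes": layer.n_nodes, "n_edges": layer.n_edges})
    (directory / f"{prefix}_bands.json").write_text(json.dumps(meta, indent=2))


def read_layer_edgelist(path: str | Path, n_nodes: int, band: tuple[float, float]) -> LayerNetwork:
    """Rebuild a layer from a TSV edge list written by :func:`write_layers`."""
    z = np.zeros((n_nodes, n_nodes))
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        a, b = int(row.node_i), int(row.node_j)
        z[a, b] = z[b, a] = row.z
    return LayerNetwork(z=z, band=band)


def write_supra_adjacency(mux: MultiplexNetwork, path: str | Path) -> None:
    """Sparse coordinate triples (TSV) with a JSON header line."""
    m = supra_adjacency(mux)
    header = {"N": mux.n_nodes, "L": mux.n_layers, "D": mux.D,
              "bands_hz": [list(l.band) for l in mux.layers]}
    i, j = np.nonzero(np.triu(m, k=1))
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        fh.write("row\tcol\tweight\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{m[a, b]:.12g}\n")


def descriptor_table(rows: list[tuple[str, int, LayerDescriptorSet]]) -> pd.DataFrame:
    """Tidy table: one row per (subject, layer), one column per descriptor."""
    records = []
    for subject, layer_idx, desc in rows:
        rec = {"subject": subject, "layer": layer_idx}
        rec.update(asdict(desc))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Newick string for a scipy linkage matrix over the given leaf labels."""
    n = len(labels)

    def node(idx: int) -> str:
        if idx < n:
            return labels[idx]
        a, b, dist, _ = z[idx - n]
        return f"({node(int(a))},{node(int(b))}):{dist:.6g}"

    return node(2 * n - 2) + ";"


def write_reducibility(result: ReducibilityResult, directory: str | Path,
                       layer_labels: list[str] | None = None) -> None:
    """Distance matrix and quality trajectory as CSV, dendrogram as Newick."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    L = result.distance_matrix.shape[0]
    labels = layer_labels or [f"layer{k}" for k in range(L)]
    pd.DataFrame(result.distance_matrix, index=labels, columns=labels).to_csv(
        directory / "layer_distances.csv")
    pd.DataFrame({"step": np.arange(len(result.quality)),
                  "quality": result.quality}).to_csv(
        directory / "quality_trajectory.csv", index=False)
    (directory / "dendrogram.nwk").write_text(
        linkage_to_newick(result.merge_sequence, labels))
    (directory / "optimal.json").write_text(json.dumps({
        "optimal_step": result.optimal_step,
        "optimal_partition": result.optimal_partition,
    }, indent=2))


def profile_table(profiles: list[CentralityProfile],
                  subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-node stationary probabilities: per-layer columns plus the profile."""
    frames = []
    for s, p in enumerate(profiles):
        sid = subject_ids[s] if subject_ids else f"subject{s}"
        df = pd.DataFrame(p.pi_star.T,
                          columns=[f"pi_layer{b}" for b in range(p.pi_star.shape[0])])
        df.insert(0, "node", np.arange(p.n_nodes))
        df.insert(0, "subject", sid)
        df["pi_total"] = p.profile
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_report(report: ClassificationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(report), indent=2))
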