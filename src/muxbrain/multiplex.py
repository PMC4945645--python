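"""Interconnected multiplex assembly and aggregated single-layer baselines.

Layers (one per frequency band) share a node set of N ROIs.  The multiplex is
the edge-colored union of the layers plus inter-layer links joining every node
to each of its replicas in the other layers, all with a common weight D; the
flattened representation is the (N*L) x (N*L) supra-adjacency matrix whose
diagonal blocks are the layer adjacencies and whose off-diagonal blocks are
D times the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import LayerNetwork, RoiTimeSeriesSet, build_layers, make_band_scheme

__all__ = [
    "MultiplexNetwork",
    "assemble_multiplex",
    "supra_adjacency",
    "aggregate_sum",
    "conventional_band_network",
]


@dataclass
class MultiplexNetwork:
    """L node-aligned layers over N shared nodes, replica coupling weight D."""

    layers: list[LayerNetwork]
    D: float

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("multiplex needs at least one layer")
        n = self.layers[0].n_nodes
        if any(layer.n_nodes != n for layer in self.layers):
            raise ValueError("all layers must share the same node count")
        if self.D < 0:
            raise ValueError("inter-layer weight D must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def assemble_multiplex(layers: list[LayerNetwork], D: float) -> MultiplexNetwork:
    """Couple node-aligned layers all-to-all across replicas with weight D."""
    return MultiplexNetwork(layers=list(layers), D=float(D))


def supra_adjacency(mux: MultiplexNetwork) -> np.ndarray:
    """Flatten the adjacency tensor to an (N*L) x (N*L) supra-adjacency.

    State ordering is layer-major: state ``alpha * N + i`` is node ``i`` in
    layer ``alpha``.  Off-diagonal blocks are ``D * I`` (replica links for
    every ordered layer pair alpha != beta); entries with ``i != j`` and
    ``alpha != beta`` are zero.
    """
    n, L = mux.n_nodes, mux.n_layers
    m = np.zeros((n * L, n * L))
    eye = np.eye(n)
    for a in range(L):
        m[a * n : (a + 1) * n, a * n : (a + 1) * n] = mux.layers[a].z
        for b in range(L):
            if a != b:
                m[a * n : (a + 1) * n, b * n : (b + 1) * n] = mux.D * eye
    return m


def aggregate_sum(layers: list[LayerNetwork]) -> LayerNetwork:
    """Fully aggregated single-layer network: elementwise sum of layer weights."""
    if not layers:
        raise ValueError("cannot aggregate an empty layer list")
    n = layers[0].n_nodes
    if any(layer.n_nodes != n for layer in layers):
        raise ValueError("all layers must share the same node count")
    total = np.zeros((n, n))
    for layer in layers:
        total += layer.z
    band = (min(lo for lo, _ in (l.band for l in layers)),
            max(hi for _, hi in (l.band for l in layers)))
    return LayerNetwork(z=total, band=band, roi_ids=layers[0].roi_ids)


def conventional_band_network(
    ts: RoiTimeSeriesSet,
    f_low: float,
    f_high: float,
    n_surrogates: int = 100,
    z_threshold: float = 3.0,
    seed: int | None = None,
    **kwargs,
) -> LayerNetwork:
    """Single-layer baseline: coherence averaged over one wide band.

    Coherence is averaged over the whole ``[f_low, f_high)`` range treated as
    a single band, then surrogate-thresholded exactly as the per-band layers.
    The common baselines are the full band (0.01-0.25 Hz) and the typical
    band (0.01-0.1 Hz).
    """
    scheme = make_band_scheme(f_low, f_high, f_high - f_low)
    layers, _ = build_layers(
        ts, scheme, n_surrogates=n_surrogates, z_threshold=z_threshold, seed=seed, **kwargs
    )
    return layers[0]
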