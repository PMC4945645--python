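"""Per-layer structural descriptors of band-specific connectivity networks.

Degree/strength, assortative mixing, edge density, Barrat weighted
clustering, Louvain modularity, characteristic (hop-count) path length and
the small-world index

    S = (C / C_rand) / (l / l_rand),

with the random expectations taken over Erdos-Renyi G(N, m) graphs matching
the layer's node and edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import LayerNetwork

__all__ = [
    "LayerDescriptorSet",
    "basic_descriptors",
    "weighted_clustering",
    "modularity_partition",
    "characteristic_path_length",
    "small_world_index",
    "describe_layer",
]


@dataclass
class LayerDescriptorSet:
    mean_degree: float
    mean_strength: float
    assortativity: float | None
    edge_density: float
    mean_weighted_clustering: float
    modularity: float | None
    char_path_length: float | None
    connected_pair_fraction: float | None
    small_world_index: float | None


def _binary(layer: LayerNetwork) -> np.ndarray:
    return (layer.z > 0).astype(float)


def basic_descriptors(layer: LayerNetwork) -> tuple[float, float, float | None, float]:
    """(mean degree, mean strength, degree assortativity, edge density).

    Assortativity is the Pearson correlation of endpoint degrees over edges;
    it is undefined (returned as ``None``) when the endpoint degrees have zero
    variance, e.g. on a regular graph.
    """
    n = layer.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    a = _binary(layer)
    deg = a.sum(axis=1)
    strength = layer.z.sum(axis=1)
    m = layer.n_edges
    density = m / (n * (n - 1) / 2)
    if m == 0:
        return float(deg.mean()), float(strength.mean()), None, density
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = nx.degree_assortativity_coefficient(nx.from_numpy_array(a))
    assort = None if not np.isfinite(r) else float(r)
    return float(deg.mean()), float(strength.mean()), assort, float(density)


def weighted_clustering(layer: LayerNetwork) -> float:
    """Mean Barrat weighted clustering coefficient.

    Per node: c_i = 1 / (s_i (k_i - 1)) * sum_{j,h} (w_ij + w_ih)/2 a_ij a_ih a_jh.
    Nodes with degree < 2 contribute 0; the mean runs over all nodes.
    """
    if layer.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    a = _binary(layer)
    w = layer.z
    deg = a.sum(axis=1)
    strength = w.sum(axis=1)
    # sum_{j,h} (w_ij + w_ih)/2 * a_ij a_ih a_jh  ==  sum_j w_ij (A @ A)_ij
    tri = (w * (a @ a)).sum(axis=1)
    c = np.zeros(layer.n_nodes)
    ok = deg >= 2
    c[ok] = tri[ok] / (strength[ok] * (deg[ok] - 1))
    return float(c.mean())


def modularity_partition(
    layer: LayerNetwork, seed: int | None = None
) -> tuple[list[set[int]], float]:
    """Louvain community detection on the weighted graph; returns (partition, Q)."""
    if layer.n_edges == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    g = layer.to_networkx()
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    q = nx.community.modularity(g, parts, weight="weight")
    return [set(p) for p in parts], float(q)


def characteristic_path_length(layer: LayerNetwork) -> tuple[float, float]:
    """Mean hop-count shortest path over connected node pairs.

    Disconnected pairs are excluded; the fraction of connected (unordered)
    pairs is returned alongside the mean.
    """
    if layer.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if layer.n_edges == 0:
        raise ValueError("path length is undefined on an edgeless graph")
    from scipy.sparse.csgraph import shortest_path

    a = _binary(layer)
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(layer.n_nodes, k=1)
    dists = d[iu]
    finite = np.isfinite(dists)
    frac = float(finite.mean())
    return float(dists[finite].mean()), frac


def _er_baseline(
    n: int, m: int, n_random: int, seed: int | None
) -> tuple[float, float, bool]:
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    any_disconnected = False
    for _ in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        cs.append(nx.average_clustering(g))
        if g.number_of_edges() == 0:
            raise ValueError("random baseline graph has no edges")
        layer = LayerNetwork(nx.to_numpy_array(g), band=(0.0, 0.0))
        l, frac = characteristic_path_length(layer)
        if frac < 1.0:
            any_disconnected = True
        ls.append(l)
    return float(np.mean(cs)), float(np.mean(ls)), any_disconnected


def small_world_index(
    layer: LayerNetwork, n_random: int = 50, seed: int | None = None
) -> float:
    """Small-world index S on the binarized layer vs. a G(N, m) null.

    C and l are the binary average local clustering and the hop-count
    characteristic path length; C_rand and l_rand are their means over
    ``n_random`` Erdos-Renyi graphs with the same node and edge counts.  If
    part of the random ensemble is disconnected, the connected-pairs path
    length is used and a warning is recorded.
    """
    if n_random < 10:
        raise ValueError("need at least 10 random baseline graphs")
    g = nx.from_numpy_array(_binary(layer))
    c_bar = nx.average_clustering(g)
    l_bar, frac = characteristic_path_length(layer)
    if frac < 1.0:
        warnings.warn("layer disconnected; using connected-pairs path length")
    c_rand, l_rand, any_disc = _er_baseline(layer.n_nodes, layer.n_edges, n_random, seed)
    if any_disc:
        warnings.warn(
            "random baseline ensemble partly disconnected; "
            "connected-pairs path length used"
        )
    if c_rand == 0 or l_rand == 0 or l_bar == 0:
        raise ValueError("degenerate small-world baseline")
    return float((c_bar / c_rand) / (l_bar / l_rand))


def describe_layer(
    layer: LayerNetwork, n_random: int = 50, seed: int | None = None
) -> LayerDescriptorSet:
    """All structural descriptors of one layer, in a single record."""
    mean_deg, mean_str, assort, density = basic_descriptors(layer)
    clustering = weighted_clustering(layer) if layer.n_nodes >= 3 else 0.0
    if layer.n_edges > 0:
        _, q = modularity_partition(layer, seed=seed)
        cpl, frac = characteristic_path_length(layer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                swi = small_world_index(layer, n_random=n_random, seed=seed)
        except ValueError:
            # too sparse for a clustering baseline (C_rand = 0)
            swi = None
    else:
        q, cpl, frac, swi = None, None, None, None
    return LayerDescriptorSet(
        mean_degree=mean_deg,
        mean_strength=mean_str,
        assortativity=assort,
        edge_density=density,
        mean_weighted_clustering=clustering,
        modularity=q,
        char_path_length=cpl,
        connected_pair_fraction=frac,
        small_world_index=swi,
    )
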