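"""Community-level topological metrics.

Metrics are computed on the community's *induced subgraph*: a topological
predictor of functional homogeneity should reflect intra-community wiring, not
the community's embedding in the whole network.  (A whole-network variant of
the clustering coefficient is available behind a flag for sensitivity
checks.)  The headline metric is the mean clustering coefficient: per node,
the number of triangles the node belongs to over the number of connected
triples it belongs to, i.e. ``k*(k-1)/2`` for degree ``k``; nodes of degree
< 2 get c = 0 so means over small communities stay defined.

Conventions for degenerate inputs: geodesic-based means are over connected
node pairs only; diameter is the maximum over connected components; efficiency
(mean inverse geodesic over all distinct pairs, disconnected pairs
contributing 0) is the reciprocal of the harmonic-mean geodesic distance;
metrics undefined at a community's size (density of a single node,
assortativity of a regular subgraph) are reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx
import numpy as np

from commscale.network_io import Network


@dataclass
class MetricRecord:
    log_lambda: float | None
    community: int | None
    values: dict[str, float | None]


def node_clustering(graph: nx.Graph, node, whole_network: nx.Graph | None = None) -> float:
    """Clustering coefficient c = N_triangle / N_triple of one node.

    ``N_triple = k(k-1)/2`` counts connected triples centered on the node;
    c = 0 for degree < 2.  Pass ``whole_network`` to count triangles and
    triples in the full network instead of the (sub)graph given first.
    """
    g = whole_network if whole_network is not None else graph
    neighbors = [v for v in g.neighbors(node) if v != node]
    k = len(neighbors)
    if k < 2:
        return 0.0
    triangles = sum(
        1
        for idx, u in enumerate(neighbors)
        for v in neighbors[idx + 1 :]
        if g.has_edge(u, v)
    )
    return triangles / (k * (k - 1) / 2)


def _mean(values) -> float | None:
    values = list(values)
    return float(np.mean(values)) if values else None


def _geodesic_stats(g: nx.Graph) -> dict[str, float | None]:
    """Mean geodesic (connected pairs), diameter (max over components),
    efficiency (all pairs, disconnected -> 0) and harmonic mean geodesic."""
    n = g.number_of_nodes()
    if n < 2:
        return {
            "mean_geodesic": None,
            "diameter": None,
            "efficiency": None,
            "mean_harmonic_geodesic": None,
        }
    dists = []
    diam = 0
    inv_sum = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > 0:
                dists.append(d)
                inv_sum += 1.0 / d
                diam = max(diam, d)
    n_all_pairs = n * (n - 1)  # ordered
    efficiency = inv_sum / n_all_pairs
    return {
        "mean_geodesic": float(np.mean(dists)) if dists else None,
        "diameter": float(diam) if dists else None,
        "efficiency": efficiency,
        "mean_harmonic_geodesic": (1.0 / efficiency) if efficiency > 0 else None,
    }


def _metric_registry() -> dict:
    return {
        "mean_degree": _mean_degree,
        "degree_assortativity": _assortativity,
        "mean_clustering": _mean_clustering,
        "mean_betweenness": _mean_betweenness,
        "mean_closeness": _mean_closeness,
        "mean_eigenvector_centrality": _mean_eigenvector,
        "mean_geodesic": None,  # filled by _geodesic_stats
        "diameter": None,
        "mean_harmonic_geodesic": None,
        "efficiency": None,
        "cyclomatic_number": _cyclomatic,
        "density": _density,
        "fraction_articulation": _fraction_articulation,
        "largest_eigenvalue": _largest_eigenvalue,
    }


ALL_METRICS = [
    "mean_degree",
    "degree_assortativity",
    "mean_clustering",
    "mean_betweenness",
    "mean_closeness",
    "mean_eigenvector_centrality",
    "mean_geodesic",
    "diameter",
    "mean_harmonic_geodesic",
    "efficiency",
    "cyclomatic_number",
    "density",
    "fraction_articulation",
    "largest_eigenvalue",
]

_GEODESIC_METRICS = {"mean_geodesic", "diameter", "mean_harmonic_geodesic", "efficiency"}


def _mean_degree(g: nx.Graph):
    return _mean(d for _, d in g.degree())


def _assortativity(g: nx.Graph):
    if g.number_of_edges() < 2:
        return None
    with np.errstate(all="ignore"):
        r = nx.degree_assortativity_coefficient(g)
    return None if np.isnan(r) else float(r)


def _mean_clustering(g: nx.Graph):
    return _mean(node_clustering(g, v) for v in g.nodes())


def _mean_betweenness(g: nx.Graph):
    return _mean(nx.betweenness_centrality(g).values())


def _mean_closeness(g: nx.Graph):
    return _mean(nx.closeness_centrality(g).values())


def _mean_eigenvector(g: nx.Graph):
    if g.number_of_nodes() == 1:
        return None
    try:
        cent = nx.eigenvector_centrality(g, max_iter=10_000, tol=1e-8)
    except nx.PowerIterationFailedConvergence:
        return None
    return _mean(cent.values())


def _cyclomatic(g: nx.Graph):
    return float(g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g))


def _density(g: nx.Graph):
    n = g.number_of_nodes()
    if n < 2:
        return None
    return float(nx.density(g))


def _fraction_articulation(g: nx.Graph):
    return len(set(nx.articulation_points(g))) / g.number_of_nodes()


def _largest_eigenvalue(g: nx.Graph):
    if g.number_of_nodes() == 0:
        return None
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes(), key=str))
    return float(np.linalg.eigvalsh(a)[-1])


def community_metrics(
    net: Network,
    members: Iterable[Hashable],
    metrics: list[str] | None = None,
    log_lambda: float | None = None,
    community: int | None = None,
) -> MetricRecord:
    """Evaluate topological metrics on the induced subgraph of ``members``.

    Unknown metric names raise; metrics undefined for the subgraph come back
    as None.
    """
    metrics = list(metrics) if metrics is not None else list(ALL_METRICS)
    registry = _metric_registry()
    unknown = [m for m in metrics if m not in registry]
    if unknown:
        raise KeyError(f"unknown metrics: {unknown}; available: {ALL_METRICS}")
    members = set(members)
    extra = members - set(net.graph.nodes())
    if extra:
        raise KeyError(f"members not in network: {sorted(extra, key=str)[:3]}")
    if not members:
        raise ValueError("community must have at least one member")
    g = net.simple().subgraph(members).copy()

    values: dict[str, float | None] = {}
    if any(m in _GEODESIC_METRICS for m in metrics):
        geo = _geodesic_stats(g)
        for m in metrics:
            if m in _GEODESIC_METRICS:
                values[m] = geo[m]
    for m in metrics:
        if m in _GEODESIC_METRICS:
            continue
        values[m] = registry[m](g)
    return MetricRecord(log_lambda=log_lambda, community=community, values=values)


def sweep_metrics(net: Network, sw, metrics: list[str] | None = None, min_size: int = 4):
    """Metric records for every community of size >= min_size at every
    resolution of a partition sweep; returns a tidy DataFrame."""
    import pandas as pd

    rows = []
    for ll in sw.log_grid:
        part = sw.partitions[ll]
        for label, members in sorted(part.communities.items()):
            if len(members) < min_size:
                continue
            rec = community_metrics(net, members, metrics, log_lambda=ll, community=label)
            for name, val in rec.values.items():
                rows.append(
                    {
                        "log10_lambda": ll,
                        "community": label,
                        "size": len(members),
                        "metric": name,
                        "value": np.nan if val is None else val,
                    }
                )
    return pd.DataFrame(rows)
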