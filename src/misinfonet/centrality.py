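"""Node centrality measures and their daily-mean time series.

Degree, closeness (inverse sum of within-component distances) and
betweenness are backed by networkx.  Second-order centrality — the standard
deviation of a uniform random walk's return times to a node, lower meaning
more central — is computed both exactly (fundamental-matrix algebra on the
walk's transition kernel) and by seeded Monte-Carlo simulation, so each
route can validate the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError

__all__ = [
    "CentralityVector",
    "CentralitySeries",
    "degree_centrality",
    "closeness_centrality",
    "second_order_exact",
    "second_order_mc",
    "betweenness_centrality",
    "centrality_series",
    "top_k",
    "MEASURES",
]

MEASURES = ("degree", "closeness", "second_order", "betweenness")


@dataclass
class CentralityVector:
    measure: str
    values: dict[str, float]
    normalized: bool = False


@dataclass
class CentralitySeries:
    measure: str
    means: list[float]          # NaN marks a gap (empty graph)
    counts: list[int]


def degree_centrality(g: nx.Graph, normalized: bool = True) -> CentralityVector:
    """Raw degree, or degree / (N - 1) when ``normalized``."""
    n = g.number_of_nodes()
    if normalized and n >= 2:
        vals = {v: d / (n - 1) for v, d in g.degree()}
    else:
        vals = {v: float(d) for v, d in g.degree()}
        normalized = False
    return CentralityVector("degree", vals, normalized)


def closeness_centrality(g: nx.Graph, scaled: bool = False) -> CentralityVector:
    """Inverse sum of distances to all reachable nodes.

    The sum runs within the node's connected component; singletons get 0.
    ``scaled`` applies the component-size factor ``(reachable - 1) / (N - 1)``
    for cross-graph comparability.
    """
    n = g.number_of_nodes()
    vals: dict[str, float] = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(lengths.values())  # distance to self is 0
        reach = len(lengths) - 1
        if total == 0:
            vals[v] = 0.0
            continue
        c = 1.0 / total
        if scaled and n > 1:
            c *= reach / (n - 1)
        vals[v] = c
    return CentralityVector("closeness", vals, scaled)


def _second_order_component(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    # Variance of the first return time of the uniform random walk, from the
    # fundamental matrix Z = (I - P + 1 pi^T)^{-1}:
    #   E[T+] = 1/pi_i,  E[T+^2] = 2 Z_ii / pi_i^2 - 1/pi_i
    sub = g.subgraph(nodes)
    order = sorted(sub.nodes)
    a = nx.to_numpy_array(sub, nodelist=order)
    deg = a.sum(axis=1)
    p = a / deg[:, None]
    pi = deg / deg.sum()
    n = len(order)
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    var = 2.0 * np.diag(z) / pi**2 - 1.0 / pi - 1.0 / pi**2
    var = np.clip(var, 0.0, None)  # numerical noise on symmetric graphs
    return {v: float(np.sqrt(var[i])) for i, v in enumerate(order)}


def second_order_exact(g: nx.Graph) -> CentralityVector:
    """Exact return-time standard deviation for every node.

    Disconnected graphs are handled per connected component (with a
    warning); isolated nodes have no return time and get NaN.
    """
    if g.number_of_nodes() == 0:
        return CentralityVector("second_order", {})
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        warnings.warn(
            "graph is disconnected; second-order centrality computed per component",
            stacklevel=2,
        )
    vals: dict[str, float] = {}
    for comp in comps:
        if len(comp) == 1:
            vals[next(iter(comp))] = float("nan")
            continue
        vals.update(_second_order_component(g, list(comp)))
    return CentralityVector("second_order", vals)


def second_order_mc(g: nx.Graph, n_steps: int = 200_000, seed: int = 0) -> CentralityVector:
    """Monte-Carlo second-order centrality from one long seeded walk.

    Requires a connected graph with at least 2 nodes.  Nodes revisited fewer
    than twice within ``n_steps`` are reported as NaN.
    """
    if g.number_of_nodes() < 2:
        raise ConfigurationError("need at least 2 nodes")
    if not nx.is_connected(g):
        raise ConfigurationError("Monte-Carlo walk requires a connected graph")
    if n_steps < 10_000:
        raise ConfigurationError("n_steps must be >= 10^4")
    order = sorted(g.nodes)
    index = {v: i for i, v in enumerate(order)}
    nbrs = [np.array([index[u] for u in g.neighbors(v)]) for v in order]
    rng = np.random.default_rng(seed)
    last_seen = np.full(len(order), -1, dtype=np.int64)
    gaps: list[list[int]] = [[] for _ in order]
    cur = 0
    last_seen[0] = 0
    # pre-drawn uniforms, mapped to neighbour choices on the fly
    u = rng.random(n_steps)
    for t in range(1, n_steps + 1):
        nb = nbrs[cur]
        cur = int(nb[int(u[t - 1] * len(nb))])
        if last_seen[cur] >= 0:
            gaps[cur].append(t - last_seen[cur])
        last_seen[cur] = t
    vals: dict[str, float] = {}
    for i, v in enumerate(order):
        if len(gaps[i]) >= 2:
            vals[v] = float(np.std(gaps[i], ddof=1))
        else:
            vals[v] = float("nan")
    return CentralityVector("second_order", vals)


def betweenness_centrality(g: nx.Graph, normalized: bool = True) -> CentralityVector:
    vals = nx.betweenness_centrality(g, normalized=normalized)
    return CentralityVector("betweenness", {v: float(x) for v, x in vals.items()}, normalized)


_DISPATCH = {
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "second_order": second_order_exact,
    "betweenness": betweenness_centrality,
}


def compute(g: nx.Graph, measure: str, **kwargs) -> CentralityVector:
    if measure not in _DISPATCH:
        raise ConfigurationError(f"unknown measure {measure!r}")
    return _DISPATCH[measure](g, **kwargs)


def centrality_series(graphs: list[nx.Graph], measure: str, **kwargs) -> CentralitySeries:
    """Per-graph mean of a measure; empty graphs yield NaN gaps."""
    if not graphs:
        raise ConfigurationError("need at least one graph")
    means: list[float] = []
    counts: list[int] = []
    for g in graphs:
        if g.number_of_nodes() == 0:
            means.append(float("nan"))
            counts.append(0)
            continue
        vec = compute(g, measure, **kwargs)
        finite = [x for x in vec.values.values() if np.isfinite(x)]
        means.append(float(np.mean(finite)) if finite else float("nan"))
        counts.append(g.number_of_nodes())
    return CentralitySeries(measure, means, counts)


def top_k(vector: CentralityVector, k: int = 100) -> list[str]:
    """The ``k`` highest-valued node ids; ties broken lexicographically."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    ranked = sorted(vector.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [v for v, _ in ranked[:k]]
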