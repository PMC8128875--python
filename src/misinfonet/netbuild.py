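"""Similarity-network construction from embedded record streams.

Three formulations are supported:

* per-day static networks (cosine similarity above a threshold, default 0.7);
* cumulative growth from a day-0 base network (threshold 0.8, no deletion);
* cumulative growth with a deletion rule: a node that gains no new link for
  ``delta`` consecutive days is removed together with its edges.

The evolving formulations return a :class:`TemporalGraph` that keeps full
provenance — node birth/death days, edge creation days, cumulative-degree
histories — from which any daily snapshot can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .errors import ConfigurationError, StreamFormatError
from .synthetic_stream import Stream

__all__ = [
    "SimilarityConfig",
    "DeletionConfig",
    "TemporalGraph",
    "cosine_similarity",
    "build_daily_networks",
    "grow_cumulative",
    "grow_with_deletion",
    "snapshot",
]

DAILY_THRESHOLD = 0.7
CUMULATIVE_THRESHOLD = 0.8


@dataclass(frozen=True)
class SimilarityConfig:
    threshold: float = CUMULATIVE_THRESHOLD
    metric: str = "cosine"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")
        if self.metric != "cosine":
            raise ConfigurationError("only the cosine metric is supported")


@dataclass(frozen=True)
class DeletionConfig:
    delta: int = 3

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ConfigurationError("delta must be >= 1")


@dataclass
class _NodeRecord:
    birth_day: int
    death_day: Optional[int] = None
    embedding: Optional[np.ndarray] = None

    def alive_at(self, day: int) -> bool:
        return self.birth_day <= day and (self.death_day is None or day < self.death_day)


@dataclass
class TemporalGraph:
    """Evolving graph with full temporal provenance.

    ``degree_history`` records the *cumulative* number of links each node has
    attracted by the end of each day it was alive (non-decreasing; a node's
    growth history in the fitness sense).  Current degree at any day — which
    can drop when a neighbour dies — is available from :meth:`snapshot` /
    :meth:`snapshot_degrees`.
    """

    nodes: dict[str, _NodeRecord] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    degree_history: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    current_day: int = -1
    _adj: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _cum_gain: dict[str, int] = field(default_factory=dict, repr=False)

    # -- construction API -------------------------------------------------
    def add_node(self, node_id: str, day: int, embedding: Optional[np.ndarray] = None) -> None:
        if node_id in self.nodes:
            raise ConfigurationError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = _NodeRecord(birth_day=day, embedding=embedding)
        self._adj[node_id] = set()
        self._cum_gain[node_id] = 0
        self.degree_history[node_id] = []

    def add_edge(self, u: str, v: str, day: int) -> None:
        if u == v:
            raise ConfigurationError("self-loops are not allowed")
        for x in (u, v):
            rec = self.nodes.get(x)
            if rec is None or rec.birth_day > day or rec.death_day is not None:
                raise ConfigurationError(f"edge endpoint {x!r} not alive on day {day}")
        key = (u, v) if u < v else (v, u)
        if key in self.edges:
            raise ConfigurationError(f"duplicate edge {key}")
        self.edges[key] = day
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._cum_gain[u] += 1
        self._cum_gain[v] += 1

    def kill_node(self, node_id: str, day: int) -> None:
        rec = self.nodes[node_id]
        if rec.death_day is not None:
            raise ConfigurationError(f"node {node_id!r} already dead")
        rec.death_day = day
        for nb in self._adj[node_id]:
            self._adj[nb].discard(node_id)
        self._adj[node_id] = set()

    def finalize_day(self, day: int) -> None:
        """Append the cumulative-degree history point for every alive node."""
        for nid, rec in self.nodes.items():
            if rec.alive_at(day):
                self.degree_history[nid].append((day, self._cum_gain[nid]))
        self.current_day = day

    # -- queries ----------------------------------------------------------
    def alive_nodes(self, day: Optional[int] = None) -> list[str]:
        d = self.current_day if day is None else day
        return [nid for nid, rec in self.nodes.items() if rec.alive_at(d)]

    def alive_count_series(self) -> list[int]:
        """Alive-node count at the end of each day 0..current_day."""
        return [len(self.alive_nodes(d)) for d in range(self.current_day + 1)]

    def snapshot(self, day: int) -> nx.Graph:
        """Static graph alive at the end of ``day`` (exact reconstruction)."""
        if day < 0 or day > self.current_day:
            raise ConfigurationError(f"day {day} outside [0, {self.current_day}]")
        g = nx.Graph()
        alive = {nid for nid, rec in self.nodes.items() if rec.alive_at(day)}
        g.add_nodes_from(alive)
        for (u, v), created in self.edges.items():
            if created <= day and u in alive and v in alive:
                g.add_edge(u, v)
        return g

    def snapshot_degrees(self, day: int) -> dict[str, int]:
        g = self.snapshot(day)
        return {n: int(d) for n, d in g.degree()}

    def birth_day(self, node_id: str) -> int:
        return self.nodes[node_id].birth_day

    def death_day(self, node_id: str) -> Optional[int]:
        return self.nodes[node_id].death_day


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Dot product of two unit vectors; raises on mismatch or zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ConfigurationError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ConfigurationError("zero vector has no cosine similarity")
    return float(u @ v / (nu * nv))


def _check_stream(stream: Stream) -> None:
    if not stream.records:
        raise StreamFormatError("stream is empty")
    dims = {r.embedding.shape[0] for r in stream.records}
    if len(dims) != 1:
        raise StreamFormatError("inconsistent embedding dimensions in stream")


def build_daily_networks(
    stream: Stream, config: SimilarityConfig = SimilarityConfig(DAILY_THRESHOLD)
) -> list[nx.Graph]:
    """One static graph per day; edge iff cosine similarity strictly above threshold."""
    _check_stream(stream)
    graphs: list[nx.Graph] = []
    for day in range(stream.n_days):
        recs = stream.records_on(day)
        g = nx.Graph(day=day)
        g.add_nodes_from(r.id for r in recs)
        if len(recs) >= 2:
            emb = np.stack([r.embedding for r in recs])
            sim = emb @ emb.T
            ii, jj = np.where(np.triu(sim > config.threshold, k=1))
            g.add_edges_from((recs[i].id, recs[j].id) for i, j in zip(ii, jj))
        graphs.append(g)
    return graphs


def _grow(
    stream: Stream,
    threshold: float,
    delta: Optional[int],
) -> TemporalGraph:
    """Shared growth loop for the cumulative formulations.

    Additions first (records in (day, id) order, edges to every alive node
    including earlier same-day arrivals), then — when ``delta`` is set — one
    simultaneous deletion sweep per day.
    """
    _check_stream(stream)
    if not stream.records_on(0):
        raise StreamFormatError("cumulative growth requires records on day 0")

    tg = TemporalGraph()
    alive_ids: list[str] = []
    alive_emb: list[np.ndarray] = []
    # day of the most recent link gain; birth_day - 1 when a node arrived bare
    last_gain: dict[str, int] = {}

    for day in range(stream.n_days):
        for rec in stream.records_on(day):
            tg.add_node(rec.id, day, embedding=rec.embedding)
            last_gain[rec.id] = day - 1
            if alive_ids:
                sims = np.stack(alive_emb) @ rec.embedding
                for idx in np.nonzero(sims > threshold)[0]:
                    other = alive_ids[int(idx)]
                    tg.add_edge(rec.id, other, day)
                    last_gain[other] = day
                    last_gain[rec.id] = day
            alive_ids.append(rec.id)
            alive_emb.append(rec.embedding)

        if delta is not None:
            doomed = [nid for nid in alive_ids if day - last_gain[nid] >= delta]
            if doomed:
                for nid in doomed:
                    tg.kill_node(nid, day)
                    del last_gain[nid]
                keep = [i for i, nid in enumerate(alive_ids) if nid not in set(doomed)]
                alive_ids = [alive_ids[i] for i in keep]
                alive_emb = [alive_emb[i] for i in keep]
        tg.finalize_day(day)
    return tg


def grow_cumulative(
    stream: Stream, config: SimilarityConfig = SimilarityConfig(CUMULATIVE_THRESHOLD)
) -> TemporalGraph:
    """Cumulative growth from the day-0 base network, no deletion."""
    return _grow(stream, config.threshold, delta=None)


def grow_with_deletion(
    stream: Stream,
    config: SimilarityConfig = SimilarityConfig(CUMULATIVE_THRESHOLD),
    deletion: DeletionConfig = DeletionConfig(),
) -> TemporalGraph:
    """Cumulative growth with the consecutive-no-new-link deletion rule.

    A node that gains no new edge for ``deletion.delta`` consecutive days is
    removed at the end of the day, together with its edges; a node arriving
    with zero edges starts its counter on its birth day.  Removal is a single
    simultaneous sweep computed after the day's additions.
    """
    return _grow(stream, config.threshold, delta=deletion.delta)


def snapshot(tg: TemporalGraph, day: int) -> nx.Graph:
    """Static graph alive at the end of ``day`` (see :meth:`TemporalGraph.snapshot`)."""
    return tg.snapshot(day)
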