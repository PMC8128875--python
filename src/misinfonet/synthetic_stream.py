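"""Synthetic record-stream generator with full ground truth.

Streams emulate a daily feed of short-text items: each record carries a
unit-norm embedding drawn around a topic center, synthetic tokens from the
topic vocabulary, and a heavy-tailed popularity count.  Topic activity
windows produce hard topic shifts; dispersion controls how tight each
embedding cluster is, which in turn controls the similarity-graph structure
every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, StreamFormatError

__all__ = [
    "TopicSpec",
    "LognormalPopularity",
    "ParetoPopularity",
    "StreamConfig",
    "MisinfoRecord",
    "Stream",
    "generate_stream",
    "sample_popularity",
    "ground_truth",
    "simulate_pa_growth",
]


@dataclass(frozen=True)
class LognormalPopularity:
    """Log-normal popularity model with parameters on the log scale."""

    mu: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("lognormal sigma must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full(n, np.exp(self.mu))
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class ParetoPopularity:
    """Pure power-law (Pareto) popularity model, density ~ x^-alpha above x_min."""

    alpha: float = 2.5
    x_min: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ConfigurationError("powerlaw alpha must be > 1")
        if self.x_min <= 0:
            raise ConfigurationError("powerlaw x_min must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return self.x_min * (1.0 - u) ** (-1.0 / (self.alpha - 1.0))


@dataclass
class TopicSpec:
    """One topic: an embedding center, a vocabulary, and an activity window."""

    topic_id: int
    center: np.ndarray
    vocabulary: Sequence[str]
    activity_window: tuple[int, int]
    arrival_rate: float = 5.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        norm = np.linalg.norm(self.center)
        if not np.isclose(norm, 1.0, atol=1e-6):
            if norm == 0:
                raise ConfigurationError("topic center must be nonzero")
            self.center = self.center / norm
        start, end = self.activity_window
        if start > end:
            raise ConfigurationError("activity_window start must be <= end")
        if self.arrival_rate < 0:
            raise ConfigurationError("arrival_rate must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")

    def active_on(self, day: int) -> bool:
        return self.activity_window[0] <= day <= self.activity_window[1]


@dataclass
class StreamConfig:
    n_days: int
    topics: list[TopicSpec]
    embedding_dim: int = 768
    popularity_model: LognormalPopularity | ParetoPopularity = field(
        default_factory=LognormalPopularity
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.embedding_dim < 2:
            raise ConfigurationError("embedding_dim must be >= 2")
        if not self.topics:
            raise ConfigurationError("at least one topic is required")
        for t in self.topics:
            if t.center.shape != (self.embedding_dim,):
                raise ConfigurationError(
                    f"topic {t.topic_id} center dimension {t.center.shape[0]} "
                    f"!= embedding_dim {self.embedding_dim}"
                )
        if not any(t.active_on(0) for t in self.topics):
            raise ConfigurationError("at least one topic must be active on day 0")


@dataclass
class MisinfoRecord:
    """One timestamped item of the stream."""

    id: str
    day: int
    embedding: np.ndarray
    tokens: Optional[list[str]] = None
    popularity: Optional[float] = None
    category: Optional[str] = None
    true_topic: Optional[int] = None


@dataclass
class Stream:
    records: list[MisinfoRecord]
    config: Optional[StreamConfig] = None

    @property
    def n_days(self) -> int:
        if self.config is not None:
            return self.config.n_days
        return max(r.day for r in self.records) + 1 if self.records else 0

    def records_on(self, day: int) -> list[MisinfoRecord]:
        return [r for r in self.records if r.day == day]

    def embedding_of(self, record_id: str) -> np.ndarray:
        for r in self.records:
            if r.id == record_id:
                return r.embedding
        raise KeyError(record_id)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_stream(config: StreamConfig) -> Stream:
    """Draw a full stream from ``config``; a pure function of the config.

    Per day and per active topic the record count is Poisson(arrival_rate);
    embeddings are ``normalize(center + dispersion * z)`` with isotropic
    Gaussian ``z``; tokens are vocabulary draws and popularity comes from the
    configured popularity model.  Records are sorted by ``(day, id)`` and ids
    encode the day, so the ordering is total and reproducible.
    """
    rng = np.random.default_rng(config.seed)
    records: list[MisinfoRecord] = []
    for day in range(config.n_days):
        seq = 0
        for topic in config.topics:
            if not topic.active_on(day):
                continue
            count = int(rng.poisson(topic.arrival_rate))
            if count == 0:
                continue
            pops = config.popularity_model.sample(count, rng)
            for i in range(count):
                if topic.dispersion == 0.0:
                    emb = topic.center.copy()
                else:
                    z = rng.standard_normal(config.embedding_dim)
                    emb = _unit(topic.center + topic.dispersion * z)
                n_tok = int(rng.integers(4, 10))
                vocab = list(topic.vocabulary)
                tokens = [vocab[j] for j in rng.integers(0, len(vocab), size=n_tok)]
                rec = MisinfoRecord(
                    id=f"r{day:04d}-{seq:05d}",
                    day=day,
                    embedding=emb,
                    tokens=tokens,
                    popularity=float(pops[i]),
                    true_topic=topic.topic_id,
                )
                records.append(rec)
                seq += 1
    records.sort(key=lambda r: (r.day, r.id))
    return Stream(records=records, config=config)


def sample_popularity(
    n: int,
    model: LognormalPopularity | ParetoPopularity,
    seed: int = 0,
) -> np.ndarray:
    """iid draws from the popularity model, deterministic under ``seed``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return model.sample(n, rng)


def ground_truth(stream: Stream) -> dict[int, dict]:
    """Exact per-day topic membership plus planted-hub record ids.

    Returns ``{day: {"topics": {topic_id: [record ids]},
    "hubs": {topic_id: id of the record nearest the topic center}}}``.
    Requires generator-produced streams (``true_topic`` populated).
    """
    if any(r.true_topic is None for r in stream.records):
        raise StreamFormatError("ground_truth requires true_topic on every record")
    if stream.config is None:
        raise StreamFormatError("ground_truth requires the generator config echo")
    centers = {t.topic_id: t.center for t in stream.config.topics}
    out: dict[int, dict] = {}
    for day in range(stream.n_days):
        topics: dict[int, list[str]] = {}
        for r in stream.records_on(day):
            topics.setdefault(r.true_topic, []).append(r.id)
        hubs: dict[int, str] = {}
        for tid, ids in topics.items():
            best = max(
                ids,
                key=lambda i: (float(stream.embedding_of(i) @ centers[tid]), i),
            )
            hubs[tid] = best
        out[day] = {"topics": topics, "hubs": hubs}
    return out


def simulate_pa_growth(
    n_nodes: int,
    m: int = 2,
    exponent: float = 1.0,
    fitness: Optional[np.ndarray] = None,
    seed: int = 0,
    m0: Optional[int] = None,
):
    """Simulate preferential-attachment growth as a temporal graph.

    One node arrives per day after an initial clique of ``m0`` (default
    ``m + 1``) day-0 nodes, and connects to ``m`` distinct existing nodes
    with probability proportional to ``k**exponent * fitness``.  Uniform
    attachment is ``exponent=0``; planted node fitness exercises the
    fit-get-richer estimators.  Returns the
    :class:`~misinfonet.netbuild.TemporalGraph`.
    """
    from .netbuild import TemporalGraph

    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if m0 is None:
        m0 = m + 1
    if m0 < m:
        raise ConfigurationError("m0 must be >= m")
    if n_nodes < m0 + 1:
        raise ConfigurationError("n_nodes must exceed the seed clique size")
    rng = np.random.default_rng(seed)
    if fitness is None:
        eta = np.ones(n_nodes)
    else:
        eta = np.asarray(fitness, dtype=float)
        if eta.shape != (n_nodes,):
            raise ConfigurationError("fitness must have length n_nodes")

    tg = TemporalGraph()
    ids = [f"n{i:06d}" for i in range(n_nodes)]
    deg = np.zeros(n_nodes)
    for i in range(m0):
        tg.add_node(ids[i], day=0)
    for i in range(m0):
        for j in range(i + 1, m0):
            tg.add_edge(ids[i], ids[j], day=0)
            deg[i] += 1
            deg[j] += 1
    tg.finalize_day(0)

    for i in range(m0, n_nodes):
        day = i - m0 + 1
        tg.add_node(ids[i], day=day)
        w = np.where(deg[:i] > 0, deg[:i], 0.0) ** exponent * eta[:i]
        # degree-0 nodes under exponent 0 still need positive weight
        if exponent == 0.0:
            w = np.ones(i) * eta[:i]
        total = w.sum()
        if total <= 0:
            w = np.ones(i)
            total = float(i)
        targets = rng.choice(i, size=min(m, i), replace=False, p=w / total)
        for t in targets:
            tg.add_edge(ids[i], ids[int(t)], day=day)
            deg[i] += 1
            deg[int(t)] += 1
        tg.finalize_day(day)
    return tg
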