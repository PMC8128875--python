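import numpy as np
import pytest

from misinfonet.synthetic_stream import (
    LognormalPopularity,
    MisinfoRecord,
    Stream,
    StreamConfig,
    TopicSpec,
    generate_stream,
)


def basis(dim: int, axis: int) -> np.ndarray:
    v = np.zeros(dim)
    v[axis] = 1.0
    return v


@pytest.fixture
def two_topic_stream() -> Stream:
    """Small 10-day stream with two well-separated active topics."""
    dim = 12
    topics = [
        TopicSpec(0, basis(dim, 0), ["apple", "banana", "cherry"], (0, 9), 4.0, 0.2),
        TopicSpec(1, basis(dim, 1), ["xray", "yankee", "zulu"], (0, 9), 4.0, 0.2),
    ]
    return generate_stream(StreamConfig(10, topics, dim, seed=17))


@pytest.fixture
def toy_deletion_stream() -> Stream:
    """Six hand-placed records whose deletion dynamics are hand-traceable.

    With threshold 0.8 and delta 3:
      day 0: a0-b0 edge; day 1: c1 joins both; days 2-3 quiet for them;
      a0, b0, c1 all die at end of day 4 (last gains on day 1).
      d2 arrives bare on day 2 (counter from day 2), rescued by e4 on day 4;
      f5 joins d2 and e4 on day 5.  Final alive set: {d2, e4, f5}.
    """
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.0, 1.0])
    recs = [
        MisinfoRecord("a0", 0, e1.copy()),
        MisinfoRecord("b0", 0, e1.copy()),
        MisinfoRecord("c1", 1, e1.copy()),
        MisinfoRecord("d2", 2, e2.copy()),
        MisinfoRecord("e4", 4, e2.copy()),
        MisinfoRecord("f5", 5, e2.copy()),
    ]
    cfg = StreamConfig(
        6, [TopicSpec(0, e1, ["t"], (0, 5))], 2,
        popularity_model=LognormalPopularity(), seed=0,
    )
    return Stream(recs, cfg)


def random_stream(seed: int, n_days: int = 8, dim: int = 10, rate: float = 3.0,
                  dispersion: float = 0.25) -> Stream:
    """Seeded random stream with two random-centered topics."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((2, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    topics = [
        TopicSpec(i, centers[i], [f"w{i}{j}" for j in range(5)], (0, n_days - 1),
                  rate, dispersion)
        for i in range(2)
    ]
    return generate_stream(StreamConfig(n_days, topics, dim, seed=seed))
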