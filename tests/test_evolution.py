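import math

import numpy as np
import pytest

from misinfonet.errors import (
    ConfigurationError,
    InsufficientHistoryError,
    UndefinedProfileError,
)
from misinfonet.evolution import (
    attachment_probability,
    detect_cycles,
    estimate_fitness,
    estimate_joint_pa_fitness,
    estimate_pa_function,
    fit_growth_exponent,
    survivors,
    tfidf_top_terms,
)
from misinfonet.netbuild import (
    DeletionConfig,
    SimilarityConfig,
    TemporalGraph,
    grow_cumulative,
    grow_with_deletion,
)
from misinfonet.synthetic_stream import (
    StreamConfig,
    TopicSpec,
    generate_stream,
    simulate_pa_growth,
)

from conftest import basis


def manual_graph(degree_pairs, day=1):
    """TemporalGraph with explicit day-0/1 structure: degree_pairs is a list
    of (node, [neighbours]) realised as day-0 nodes plus day-1 edges."""
    tg = TemporalGraph()
    for n, _ in degree_pairs:
        tg.add_node(n, 0)
    tg.finalize_day(0)
    seen = set()
    for n, nbrs in degree_pairs:
        for m in nbrs:
            key = tuple(sorted((n, m)))
            if key not in seen:
                tg.add_edge(n, m, day)
                seen.add(key)
    tg.finalize_day(day)
    return tg


class TestAttachmentProbability:
    def test_direct_formula(self):
        tg = manual_graph([("a", ["c"]), ("b", ["c"]), ("c", ["a", "b"])])
        prof = attachment_probability(tg, 1)
        assert prof.probabilities == {
            "a": pytest.approx(0.25),
            "b": pytest.approx(0.25),
            "c": pytest.approx(0.5),
        }

    def test_regular_graph_uniform(self):
        tg = manual_graph([("a", ["b", "c"]), ("b", ["a", "c"]), ("c", ["a", "b"])])
        prof = attachment_probability(tg, 1)
        assert all(p == pytest.approx(1 / 3) for p in prof.probabilities.values())

    def test_probabilities_sum_to_one(self):
        tg = simulate_pa_growth(60, m=2, seed=0)
        prof = attachment_probability(tg, tg.current_day)
        assert sum(prof.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_linear_slope_equals_inverse_total_degree(self):
        tg = simulate_pa_growth(80, m=2, seed=1)
        degs = tg.snapshot_degrees(tg.current_day)
        prof = attachment_probability(tg, tg.current_day)
        assert prof.slope == pytest.approx(1.0 / sum(degs.values()), rel=1e-6)
        assert prof.r2 == pytest.approx(1.0, abs=1e-9)

    def test_edgeless_snapshot_error(self):
        tg = TemporalGraph()
        tg.add_node("a", 0)
        tg.finalize_day(0)
        with pytest.raises(UndefinedProfileError):
            attachment_probability(tg, 0)


class TestPaFunction:
    def test_linear_pa_recovery(self):
        tg = simulate_pa_growth(800, m=2, exponent=1.0, seed=11)
        est = estimate_pa_function(tg, (1, tg.current_day))
        assert 0.8 <= est.alpha <= 1.2

    def test_uniform_attachment_recovery(self):
        tg = simulate_pa_growth(800, m=2, exponent=0.0, seed=12)
        est = estimate_pa_function(tg, (1, tg.current_day))
        assert -0.2 <= est.alpha <= 0.2

    def test_normalization_A1(self):
        tg = simulate_pa_growth(300, m=1, exponent=1.0, seed=13)
        est = estimate_pa_function(tg, (1, tg.current_day))
        assert est.A_k[1] == pytest.approx(1.0)

    def test_no_events_error(self):
        tg = TemporalGraph()
        for i, n in enumerate("abc"):
            tg.add_node(n, i)
            tg.finalize_day(i)
        with pytest.raises(ConfigurationError):
            estimate_pa_function(tg, (1, 2))


class TestFitness:
    def test_noiseless_power_history(self):
        ts = np.arange(1, 21)
        beta, offset, r2 = fit_growth_exponent(ts, 4.0 * ts**0.5)
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert offset == pytest.approx(math.log(4.0), abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_history_zero_beta(self):
        beta, _, _ = fit_growth_exponent(np.arange(1, 11), np.full(10, 7.0))
        assert beta == 0.0

    def test_short_history_error(self):
        with pytest.raises(InsufficientHistoryError):
            fit_growth_exponent([1, 2], [1, 2])

    def test_estimate_on_temporal_graph(self):
        tg = simulate_pa_growth(120, m=2, exponent=1.0, seed=3)
        nid = sorted(tg.nodes)[0]
        est = estimate_fitness(tg, nid, use_age=False)
        assert est.n_points >= 3
        assert np.isfinite(est.beta)

    def test_planted_fitness_spearman(self):
        from scipy.stats import spearmanr

        n = 500
        eta = np.where(np.random.default_rng(0).random(n) < 0.5, 1.0, 2.0)
        tg = simulate_pa_growth(n, m=40, exponent=1.0, fitness=eta, seed=21)
        ids = sorted(tg.nodes)
        betas, etas = [], []
        for i, nid in enumerate(ids):
            if len(tg.degree_history[nid]) < 20:
                continue
            betas.append(estimate_fitness(tg, nid, use_age=False).beta)
            etas.append(eta[i])
        assert spearmanr(etas, betas).statistic > 0.6


class TestJointPaFitness:
    def test_homogeneous_fitness_near_one(self):
        tg = simulate_pa_growth(400, m=3, exponent=1.0, seed=7)
        est, eta = estimate_joint_pa_fitness(tg, (1, tg.current_day))
        vals = np.array(list(eta.values()))
        assert ((vals > 0.5) & (vals < 2.0)).mean() >= 0.9
        assert vals.mean() == pytest.approx(1.0, abs=1e-6)

    def test_planted_fitness_separation(self):
        n = 400
        planted = np.where(np.random.default_rng(1).random(n) < 0.5, 1.0, 3.0)
        tg = simulate_pa_growth(n, m=3, exponent=1.0, fitness=planted, seed=8)
        _, eta = estimate_joint_pa_fitness(tg, (1, tg.current_day))
        ids = sorted(tg.nodes)
        hi = [eta[ids[i]] for i in range(n) if planted[i] == 3.0 and ids[i] in eta]
        lo = [eta[ids[i]] for i in range(n) if planted[i] == 1.0 and ids[i] in eta]
        assert np.mean(hi) > np.mean(lo)

    def test_single_day_range_error(self):
        tg = simulate_pa_growth(50, m=2, seed=2)
        with pytest.raises(ConfigurationError):
            estimate_joint_pa_fitness(tg, (1, 1))


class TestSurvivors:
    def test_no_deletion_all_survive(self, two_topic_stream):
        tg = grow_cumulative(two_topic_stream)
        day0 = {r.id for r in two_topic_stream.records_on(0)}
        assert survivors(tg, 0, tg.current_day) == day0

    def test_deleted_node_not_survivor(self, toy_deletion_stream):
        tg = grow_with_deletion(toy_deletion_stream)
        assert survivors(tg, 0, 3) == {"a0", "b0"}
        assert survivors(tg, 0, 4) == set()

    def test_nested_monotone(self, two_topic_stream):
        tg = grow_with_deletion(two_topic_stream, deletion=DeletionConfig(2))
        for d in range(1, tg.current_day):
            assert survivors(tg, 0, d + 1) <= survivors(tg, 0, d)

    def test_range_violation(self, toy_deletion_stream):
        tg = grow_with_deletion(toy_deletion_stream)
        with pytest.raises(ConfigurationError):
            survivors(tg, 3, 1)


class TestDetectCycles:
    def test_monotone_growth_no_events(self):
        tg = TemporalGraph()
        prev = None
        for d in range(6):
            nid = f"n{d}"
            tg.add_node(nid, d)
            if prev is not None:
                tg.add_edge(nid, prev, d)
            tg.finalize_day(d)
            prev = nid
        assert detect_cycles(tg) == []

    def test_topic_shift_produces_shrink(self):
        dim = 12
        topics = [
            TopicSpec(0, basis(dim, 0), ["a"], (0, 29), 8.0, 0.15),
            TopicSpec(1, basis(dim, 1), ["b"], (30, 39), 8.0, 0.15),
        ]
        s = generate_stream(StreamConfig(40, topics, dim, seed=11))
        tg = grow_with_deletion(s, SimilarityConfig(0.8), DeletionConfig(3))
        events = detect_cycles(tg)
        shrinks = [e for e in events if e.kind == "shrink"]
        assert shrinks and 30 <= shrinks[0].day <= 34

    def test_shrink_then_expand_order(self):
        tg = TemporalGraph()
        # day 0-1: grow to 4 nodes; day 2: mass death; days 3-5: regrow
        for i in range(4):
            tg.add_node(f"a{i}", 0)
        for i in range(1, 4):
            tg.add_edge("a0", f"a{i}", 0)
        tg.finalize_day(0)
        tg.finalize_day(1)
        for i in range(4):
            tg.kill_node(f"a{i}", 2)
        tg.add_node("b0", 2)
        tg.finalize_day(2)
        for d, n in ((3, "b1"), (4, "b2"), (5, "b3")):
            tg.add_node(n, d)
            tg.add_edge("b0", n, d)
            tg.finalize_day(d)
        kinds = [e.kind for e in detect_cycles(tg)]
        assert kinds == ["shrink", "expand"]


def brute_tfidf(docs, ngram_range=(1, 2)):
    """Independent reimplementation with Counter + math.log."""
    from collections import Counter

    grams = []
    for doc in docs:
        terms = []
        for n in range(ngram_range[0], ngram_range[1] + 1):
            for i in range(len(doc) - n + 1):
                terms.append(" ".join(doc[i : i + n]))
        grams.append(Counter(terms))
    n_docs = len(docs)
    df = Counter()
    for c in grams:
        df.update(c.keys())
    scores = {}
    for c in grams:
        for term, tf in c.items():
            idf = math.log((1 + n_docs) / (1 + df[term])) + 1.0
            scores[term] = scores.get(term, 0.0) + tf * idf
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


class TestTfidf:
    def test_two_document_hand_computation(self):
        idf_rare = math.log(3 / 2) + 1.0
        ranked = tfidf_top_terms([["a", "b"], ["a", "c"]])
        assert ranked[0] == ("a", pytest.approx(2.0))
        assert [t for t, _ in ranked] == ["a", "a b", "a c", "b", "c"]
        assert ranked[1][1] == pytest.approx(idf_rare)

    def test_single_document_frequency_order(self):
        ranked = tfidf_top_terms([["x", "x", "x", "y", "y", "z"]], ngram_range=(1, 1))
        assert [t for t, _ in ranked] == ["x", "y", "z"]

    def test_rarer_term_scores_higher(self):
        docs = [["common", "rare"], ["common"], ["common"]]
        scores = dict(tfidf_top_terms(docs, ngram_range=(1, 1)))
        assert scores["rare"] > scores["common"] / 3  # per-occurrence comparison

    def test_empty_corpus_error(self):
        with pytest.raises(ConfigurationError):
            tfidf_top_terms([[], []])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vocab = [f"w{i}" for i in range(8)]
        docs = [
            [vocab[j] for j in rng.integers(0, 8, size=rng.integers(1, 9))]
            for _ in range(int(rng.integers(2, 11)))
        ]
        got = tfidf_top_terms(docs, top_n=10_000)
        expected = brute_tfidf(docs)
        assert [t for t, _ in got] == [t for t, _ in expected]
        for (t1, s1), (t2, s2) in zip(got, expected):
            assert s1 == pytest.approx(s2, rel=1e-12)
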