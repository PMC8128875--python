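# misinfonet

Analysis pipeline for the temporal dynamics of similarity networks built
from streams of embedded short-text records (e.g. daily batches of
misinformation posts).  The package covers:

- **`synthetic_stream`** — a seeded generator of record streams with topic
  clusters in embedding space, activity windows (hard topic shifts),
  heavy-tailed popularity counts and full ground truth, plus a
  preferential-attachment growth simulator for estimator benchmarking.
- **`heavytail`** — power-law / log-normal tail fitting with KS-scan
  `x_min` selection, semi-parametric bootstrap plausibility (`p_KS`), and a
  signed log-likelihood-ratio comparison of the two families with a
  Vuong-type significance value.
- **`netbuild`** — three network formulations over a stream: per-day cosine
  similarity graphs (threshold 0.7), cumulative growth from a day-0 base
  network (threshold 0.8), and cumulative growth with a deletion rule that
  removes any node gaining no new link for `delta` (default 3) consecutive
  days.  The evolving formulations return a `TemporalGraph` with full
  provenance: birth/death days, edge creation days, cumulative-degree
  histories, and exact daily snapshots.
- **`centrality`** — degree, closeness, betweenness, and second-order
  centrality (standard deviation of random-walk return times), the latter
  computed both exactly via fundamental-matrix algebra and by seeded
  Monte-Carlo simulation; daily-mean time series and top-k ranking.
- **`evolution`** — per-day attachment probabilities `k_i / Σk_j`, the
  empirical preferential-attachment kernel `A_k` with log-linear exponent,
  per-node growth-exponent (fitness) fits, a joint alternating
  kernel/fitness estimator, survivor sets, shrink/expand cycle detection,
  and TF-IDF top-term extraction (unigrams + bigrams).
- **`predictor`** — labels each daily network's top-k central nodes,
  balances classes by upsampling, trains a small seeded MLP
  (3 × 32 rectifier units with dropout 0.5, softmax output, early stopping)
  on the embeddings alone, and evaluates rolling 1/5/10-day predictions
  (accuracy and AUROC, mean ± std over seeds).
- **`cli`** — a `misinfonet` command with `generate`, `validate-stream`,
  `fit-tail`, `build-net`, `centrality`, `evolution`, `predict`, and
  `run-all` subcommands; `run-all` writes all artifacts plus a manifest
  with content hashes for reproducibility.

## CLI quick start

```bash
cat > config.yaml <<'EOF'
n_days: 20
embedding_dim: 32
seed: 7
popularity: {family: lognormal, mu: 1.0, sigma: 1.0}
topics:
  - {topic_id: 0, center_seed: 1, vocabulary: [virus, cure, hoax],
     activity_window: [0, 19], arrival_rate: 12, dispersion: 0.2}
  - {topic_id: 1, center_seed: 2, vocabulary: [vote, poll, fraud],
     activity_window: [0, 19], arrival_rate: 12, dispersion: 0.2}
EOF
misinfonet run-all --config config.yaml --out-dir out --seed 3
```

Artifacts land under `out/`: the stream (JSON-Lines), tail-fit report,
network edge/node tables, centrality series, evolution tables, the
prediction report, and `manifest.json` with per-stage timings and content
hashes.

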