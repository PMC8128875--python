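"""Embedding-based prediction of future high-centrality nodes.

Every node of every daily network becomes a labelled example (1 iff it
ranks in the top-k of its day's chosen centrality).  After upsampling the
minority class, a small fully-connected network — three 32-unit rectifier
layers, each followed by dropout 0.5, softmax output, early stopping on a
held-out validation split — is trained on the embedding vectors alone and
evaluated on rolling 1/5/10-day horizons with strictly earlier training
days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from sklearn.metrics import roc_auc_score

from . import centrality as C
from .errors import ConfigurationError
from .synthetic_stream import Stream

__all__ = [
    "LabeledExample",
    "MlpConfig",
    "Mlp",
    "EvalReport",
    "build_dataset",
    "balance_upsample",
    "train",
    "rolling_evaluate",
]


@dataclass
class LabeledExample:
    record_id: str
    embedding: np.ndarray
    label: int
    day: int
    measure: str


@dataclass
class MlpConfig:
    hidden: tuple[int, ...] = (32, 32, 32)
    dropout: float = 0.5
    val_frac: float = 0.1
    patience: int = 10
    max_epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


@dataclass
class EvalReport:
    horizon: int
    measure: str
    accuracy_mean: float
    accuracy_std: float
    auroc_mean: float
    auroc_std: float
    balanced_accuracy_mean: float
    n_seeds: int
    per_block: list[dict] = field(default_factory=list)


class Mlp:
    """Minimal seeded MLP: ReLU hidden layers, inverted dropout, softmax out.

    Trained with Adam on cross-entropy; early stopping restores the weights
    of the best validation epoch.
    """

    def __init__(self, dim: int, config: MlpConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        sizes = [dim, *config.hidden, 2]
        self.W = [
            self.rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        acts = [x]
        masks = []
        h = x
        p = self.config.dropout
        for i, (w, bb) in enumerate(zip(self.W, self.b)):
            h = h @ w + bb
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
                if train and p > 0:
                    m = (self.rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
            acts.append(h)
        logits = acts[-1]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return acts, masks, probs

    def _step(self, x, y, adam_state, t):
        acts, masks, probs = self._forward(x, train=True)
        n = x.shape[0]
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads_w, grads_b = [], []
        for i in range(len(self.W) - 1, -1, -1):
            grads_w.insert(0, acts[i].T @ delta)
            grads_b.insert(0, delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.W[i].T
                delta[acts[i] <= 0] = 0.0
                if masks[i - 1] is not None:
                    delta *= masks[i - 1]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.config.lr
        for i, (gw, gb) in enumerate(zip(grads_w, grads_b)):
            for key, g, param in (("w", gw, self.W), ("b", gb, self.b)):
                m, v = adam_state[(key, i)]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                adam_state[(key, i)] = (m, v)
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                param[i] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _loss(self, x, y):
        _, _, probs = self._forward(x, train=False)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- public API --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Mlp":
        cfg = self.config
        n = X.shape[0]
        idx = self.rng.permutation(n)
        n_val = max(1, int(round(cfg.val_frac * n)))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]
        adam = {
            (key, i): (np.zeros_like(p), np.zeros_like(p))
            for key, params in (("w", self.W), ("b", self.b))
            for i, p in enumerate(params)
        }
        best_loss = np.inf
        best_weights = None
        stall = 0
        t = 0
        for _ in range(cfg.max_epochs):
            order = self.rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                t += 1
                self._step(Xtr[batch], ytr[batch], adam, t)
            vloss = self._loss(Xval, yval)
            if vloss < best_loss - 1e-6:
                best_loss = vloss
                best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of class 1."""
        _, _, probs = self._forward(np.asarray(X, dtype=float), train=False)
        return probs[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_dataset(
    daily_graphs: list[nx.Graph],
    stream: Stream,
    measure: str = "degree",
    k: int = 100,
) -> list[LabeledExample]:
    """Label every node of every daily network by its top-k centrality rank."""
    emb = {r.id: r.embedding for r in stream.records}
    examples: list[LabeledExample] = []
    for day, g in enumerate(daily_graphs):
        if g.number_of_nodes() < 1:
            continue
        vec = C.compute(g, measure)
        top = set(C.top_k(vec, k))
        for node in g.nodes:
            if node not in emb:
                raise ConfigurationError(f"graph node {node!r} missing from stream")
            examples.append(
                LabeledExample(node, emb[node], int(node in top), day, measure)
            )
    return examples


def balance_upsample(dataset: list[LabeledExample], seed: int = 0) -> list[LabeledExample]:
    """Resample the minority class with replacement until classes balance."""
    pos = [e for e in dataset if e.label == 1]
    neg = [e for e in dataset if e.label == 0]
    if not pos or not neg:
        raise ConfigurationError("both classes must be present")
    if len(pos) == len(neg):
        return list(dataset)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    extra_idx = rng.integers(0, len(minority), size=len(majority) - len(minority))
    return list(dataset) + [minority[i] for i in extra_idx]


def train(dataset: list[LabeledExample], config: MlpConfig = MlpConfig()) -> Mlp:
    if len(dataset) < 20:
        raise ConfigurationError("need at least 20 examples")
    dims = {e.embedding.shape[0] for e in dataset}
    if len(dims) != 1:
        raise ConfigurationError("inconsistent feature dimensions")
    X = np.stack([e.embedding for e in dataset]).astype(float)
    y = np.array([e.label for e in dataset], dtype=int)
    model = Mlp(X.shape[1], config)
    return model.fit(X, y)


# ---------------------------------------------------------------------------
# rolling evaluation
# ---------------------------------------------------------------------------

def rolling_evaluate(
    daily_graphs: list[nx.Graph],
    stream: Stream,
    measure: str = "degree",
    horizon: int = 1,
    k: int = 100,
    n_seeds: int = 5,
    config: Optional[MlpConfig] = None,
    base_seed: int = 0,
) -> EvalReport:
    """Rolling block prediction: train on all earlier days, score each block.

    Blocks are consecutive non-overlapping windows of ``horizon`` days
    starting at day ``horizon``; for each block and seed the model is
    trained on the balanced examples of all strictly earlier days and
    evaluated on the block's nodes at the natural class distribution (AUROC
    from class-1 probabilities; blocks with one class skip AUROC).
    """
    if horizon not in (1, 5, 10):
        raise ConfigurationError("horizon must be one of 1, 5, 10")
    n_days = len(daily_graphs)
    if n_days < horizon + 2:
        raise ConfigurationError("need at least horizon + 2 days of graphs")
    all_examples = build_dataset(daily_graphs, stream, measure, k)
    by_day: dict[int, list[LabeledExample]] = {}
    for e in all_examples:
        by_day.setdefault(e.day, []).append(e)

    cfg0 = config or MlpConfig()
    accs, aurocs, baccs = [], [], []
    per_block: list[dict] = []
    for s in range(n_seeds):
        seed = base_seed + 1000 * s
        for t in range(horizon, n_days, horizon):
            block_days = [d for d in range(t, min(t + horizon, n_days))]
            train_set = [e for d in range(t) for e in by_day.get(d, [])]
            test_set = [e for d in block_days for e in by_day.get(d, [])]
            if len(test_set) == 0 or len(train_set) < 20:
                continue
            labels = {e.label for e in train_set}
            if len(labels) < 2:
                continue
            balanced = balance_upsample(train_set, seed=seed)
            cfg = MlpConfig(**{**cfg0.__dict__, "seed": seed})
            model = train(balanced, cfg)
            # leakage guard: training days strictly precede the block
            assert max(e.day for e in train_set) < min(block_days)
            X = np.stack([e.embedding for e in test_set]).astype(float)
            y = np.array([e.label for e in test_set], dtype=int)
            probs = model.predict_proba(X)
            pred = (probs >= 0.5).astype(int)
            acc = float((pred == y).mean())
            accs.append(acc)
            entry = {"seed": s, "block_start": t, "accuracy": acc, "n": len(y)}
            if len(np.unique(y)) == 2:
                auroc = float(roc_auc_score(y, probs))
                aurocs.append(auroc)
                entry["auroc"] = auroc
                tpr = float((pred[y == 1] == 1).mean())
                tnr = float((pred[y == 0] == 0).mean())
                bacc = 0.5 * (tpr + tnr)
                baccs.append(bacc)
                entry["balanced_accuracy"] = bacc
            per_block.append(entry)
    if not accs:
        raise ConfigurationError("no evaluable blocks")
    return EvalReport(
        horizon=horizon,
        measure=measure,
        accuracy_mean=float(np.mean(accs)),
        accuracy_std=float(np.std(accs)),
        auroc_mean=float(np.mean(aurocs)) if aurocs else float("nan"),
        auroc_std=float(np.std(aurocs)) if aurocs else float("nan"),
        balanced_accuracy_mean=float(np.mean(baccs)) if baccs else float("nan"),
        n_seeds=n_seeds,
        per_block=per_block,
    )
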