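"""Multi-label disease→drug relation model, losses, relation score, metrics.

The network reads a multi-hot disease vector and predicts, per drug in the
clipped vocabulary, the probability that the drug belongs on the
prescription (independent sigmoids, multi-label).  Because almost every
target bit is zero, training uses the focal loss

    FL(p_t) = -α_t (1 - p_t)^γ log(p_t),   γ = 2 by default,

which down-weights the easy all-zero labels; γ = 0 and α = 0.5 reduce it to
half the plain multi-label binary cross-entropy.

The quantity the rest of the pipeline consumes is the *relation score*

    p = Σ_k y_k · y_gt_k / Σ_k y_k,

the fraction of the model's total predicted probability mass that lands on
the drugs actually prescribed — a 0–1 disease–prescription compatibility
measure that is invariant to rescaling the prediction vector.  Ranking
quality of the raw predictions is summarised by one-error (top-1 miss
rate) and coverage (mean depth to the worst-ranked true drug).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from ._nn import Adam, NetParams, bce_grad, focal_grad, sigmoid, EPS
from .encoding import EncodedSample

logger = logging.getLogger(__name__)


@dataclass
class RelationModelConfig:
    hidden_dim: int = 512
    refine_steps: int = 2
    gamma: float = 2.0
    alpha: float = 0.25
    loss: str = "focal"           # "focal" or "bce"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.loss not in ("focal", "bce"):
            raise ValueError("loss must be 'focal' or 'bce'")
        if self.refine_steps < 0:
            raise ValueError("refine_steps must be >= 0")


# ---------------------------------------------------------------------------
# losses (reference forms on probability vectors)


def multilabel_bce(probabilities: np.ndarray, targets: np.ndarray) -> float:
    """Summed binary cross-entropy over labels; inputs clamped to (0,1)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def focal_loss(probabilities: np.ndarray, targets: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Focal loss summed over labels: ``-α_t (1-p_t)^γ log(p_t)``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    pt = p * y + (1 - p) * (1 - y)
    at = alpha * y + (1 - alpha) * (1 - y)
    return float(-(at * (1 - pt) ** gamma * np.log(pt)).sum())


# ---------------------------------------------------------------------------
# relation score


def relation_score(predicted: np.ndarray, ground_truth: np.ndarray) -> float:
    """Share of predicted drug-probability mass on the prescribed drugs."""
    y = np.asarray(predicted, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    if y.shape != gt.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {gt.shape}")
    denom = y.sum()
    if denom <= 0:
        logger.warning("all-zero prediction vector; relation score defined as 0")
        return 0.0
    return float((y * gt).sum() / denom)


def relation_scores(predicted: np.ndarray, ground_truth: np.ndarray) -> np.ndarray:
    """Row-wise :func:`relation_score` for matrices."""
    y = np.asarray(predicted, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    denom = y.sum(axis=1)
    num = (y * gt).sum(axis=1)
    out = np.zeros(len(y))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


# ---------------------------------------------------------------------------
# multi-label ranking metrics


def one_error(score_matrix: np.ndarray, gt_matrix: np.ndarray) -> float:
    """Fraction of rows whose top-scored label (ties → lowest index) is false."""
    s = np.asarray(score_matrix, dtype=float)
    g = np.asarray(gt_matrix)
    if s.size == 0:
        raise ValueError("empty input")
    if (g.sum(axis=1) == 0).any():
        raise ValueError("every row needs at least one true label")
    top = np.argmax(s, axis=1)  # argmax takes the lowest index on ties
    return float(np.mean(g[np.arange(len(g)), top] == 0))


def coverage_metric(score_matrix: np.ndarray, gt_matrix: np.ndarray) -> float:
    """Mean (1-based rank of the worst-ranked true label) − 1, descending
    scores, ties broken toward the lower label index."""
    s = np.asarray(score_matrix, dtype=float)
    g = np.asarray(gt_matrix)
    if s.size == 0:
        raise ValueError("empty input")
    if (g.sum(axis=1) == 0).any():
        raise ValueError("every row needs at least one true label")
    n, m = s.shape
    total = 0.0
    idx = np.arange(m)
    for i in range(n):
        order = np.lexsort((idx, -s[i]))  # descending score, then lowest index
        rank = np.empty(m, dtype=int)
        rank[order] = np.arange(1, m + 1)
        total += rank[g[i].astype(bool)].max() - 1
    return total / n


# ---------------------------------------------------------------------------
# training


class RelationModel:
    """Trained handle: maps multi-hot disease vectors to per-drug probabilities."""

    def __init__(self, net: NetParams, config: RelationModelConfig,
                 loss_history: Optional[List[float]] = None):
        self.net = net
        self.config = config
        self.loss_history = loss_history or []

    @property
    def input_dim(self) -> int:
        return self.net.input_dim

    @property
    def output_dim(self) -> int:
        return self.net.output_dim

    def predict_drug_probabilities(self, disease_vecs: np.ndarray) -> np.ndarray:
        """Sigmoid drug probabilities for one vector or a batch."""
        x = np.asarray(disease_vecs, dtype=np.float32)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.net.input_dim:
            raise ValueError(f"expected input dim {self.net.input_dim}, got {x.shape[1]}")
        out = []
        for start in range(0, len(x), 1024):
            logits, _ = self.net.forward(x[start:start + 1024])
            out.append(sigmoid(logits))
        return out[0][0] if single and len(out) == 1 and len(out[0]) == 1 else np.vstack(out)

    def score_samples(self, samples: Sequence[EncodedSample]) -> np.ndarray:
        """Relation score per encoded sample (input: diseases, gt: drugs)."""
        kd, kr = self.net.input_dim, self.net.output_dim
        x = np.stack([s.disease_vec(kd) for s in samples])
        gt = np.stack([s.drug_vec(kr) for s in samples])
        probs = self.predict_drug_probabilities(x)
        return relation_scores(probs, gt)

    def save(self, path: Union[str, Path]) -> None:
        meta = dict(
            input_dim=self.net.input_dim, output_dim=self.net.output_dim,
            refine_steps=self.net.refine_steps, gamma=self.config.gamma,
            alpha=self.config.alpha, seed=self.config.seed,
        )
        np.savez(path, __meta__=np.array([json.dumps(meta)]),
                 __loss__=np.array(self.loss_history), **self.net.p)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RelationModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"][0]))
        cfg = RelationModelConfig(refine_steps=int(meta["refine_steps"]),
                                  gamma=float(meta["gamma"]), alpha=float(meta["alpha"]),
                                  seed=int(meta["seed"]))
        net = NetParams(int(meta["input_dim"]), int(meta["output_dim"]), 512,
                        int(meta["refine_steps"]), np.random.default_rng(0))
        for k in net.p:
            net.p[k] = data[k]
        return cls(net, cfg, list(data["__loss__"]))


def train_relation_model(samples: Sequence[EncodedSample], input_dim: int,
                         output_dim: int,
                         config: Optional[RelationModelConfig] = None) -> RelationModel:
    """Train the relation network on encoded samples; deterministic per seed."""
    config = config or RelationModelConfig()
    config.validate()
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples")
    for s in samples:
        if len(s.disease_idx) and s.disease_idx[-1] >= input_dim:
            raise ValueError(f"sample {s.claim_id} exceeds disease dim {input_dim}")
        if len(s.drug_idx) and s.drug_idx[-1] >= output_dim:
            raise ValueError(f"sample {s.claim_id} exceeds drug dim {output_dim}")

    rng = np.random.default_rng(config.seed)
    net = NetParams(input_dim, output_dim, config.hidden_dim, config.refine_steps, rng)
    opt = Adam(net.p, lr=config.learning_rate)

    x = np.zeros((len(samples), input_dim), dtype=np.float32)
    y = np.zeros((len(samples), output_dim), dtype=np.float32)
    for i, s in enumerate(samples):
        x[i, s.disease_idx] = 1.0
        y[i, s.drug_idx] = 1.0

    history: List[float] = []
    n = len(samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, cache = net.forward(x[idx], want_cache=True)
            if config.loss == "focal":
                loss, dlogits = focal_grad(logits, y[idx], config.alpha, config.gamma)
            else:
                loss, dlogits = bce_grad(logits, y[idx])
            grads = net.backward(dlogits, cache)
            opt.step(net.p, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, config.epochs, history[-1])
    return RelationModel(net, config, history)
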