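"""Anomaly scoring of normalized claim features.

Five scorers rank claims for analyst triage, higher score = more
anomalous:

* ``isolation_forest`` — expected-path-length anomaly score from an
  isolation forest (100 trees, 256-point subsamples by default);
* ``kmeans`` — Euclidean distance to the nearest of k cluster centroids;
* ``dbscan`` — density noise flag (noise points score 1, others 0; noise
  ties ordered by distance to the nearest core point);
* ``lof`` — the local outlier factor;
* ``traditional_rule`` — the pre-ML baseline: a weighted sum of per-column
  percentile ranks.

Tree/cluster/neighbour machinery is delegated to scikit-learn; this module
fixes the defaults, the score conventions, and deterministic tie-breaking
(final tie-break is always ``claim_id``), and adds a hand-rolled SMOTE
upsampler used to stress detectors on interpolated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN, KMeans
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

logger = logging.getLogger(__name__)

METHODS = ("isolation_forest", "kmeans", "dbscan", "lof", "traditional_rule")


@dataclass
class DetectorConfig:
    method: str = "isolation_forest"
    n_estimators: int = 100
    subsample: int = 256
    k_clusters: int = 8
    dbscan_eps: float = 0.5
    dbscan_min_pts: int = 5
    lof_neighbors: int = 20
    rule_weights: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class AnomalyRanking:
    """Claims ordered by non-increasing anomaly score."""

    table: pd.DataFrame  # columns: claim_id, score, label (may be 'unknown')

    @classmethod
    def from_scores(cls, claim_ids: Sequence[str], scores: np.ndarray,
                    labels: Optional[Sequence[str]] = None,
                    secondary: Optional[np.ndarray] = None) -> "AnomalyRanking":
        df = pd.DataFrame({
            "claim_id": list(claim_ids),
            "score": np.asarray(scores, dtype=float),
            "label": list(labels) if labels is not None else "unknown",
        })
        df["_sec"] = np.asarray(secondary, dtype=float) if secondary is not None else 0.0
        df = df.sort_values(["score", "_sec", "claim_id"],
                            ascending=[False, False, True], kind="mergesort")
        return cls(df.drop(columns="_sec").reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnomalyRanking":
        return cls(pd.read_csv(path, dtype={"claim_id": str}))


def _matrix(features: pd.DataFrame, columns: Optional[List[str]]) -> Tuple[np.ndarray, List[str]]:
    if columns is None:
        columns = [c for c in features.columns
                   if c not in ("claim_id", "label", "pattern")
                   and np.issubdtype(features[c].dtype, np.number)]
    return features[columns].to_numpy(dtype=float), columns


def detect(features: pd.DataFrame, config: DetectorConfig,
           columns: Optional[List[str]] = None) -> AnomalyRanking:
    """Score every claim in ``features`` with the configured detector."""
    config.validate()
    x, columns = _matrix(features, columns)
    n = len(x)
    if n == 0:
        raise ValueError("no claims to score")
    claim_ids = features["claim_id"].astype(str).tolist()
    labels = features["label"].tolist() if "label" in features else None
    secondary = None

    if config.method == "traditional_rule":
        return traditional_rule_score(features, config.rule_weights, columns=columns)
    if config.method == "isolation_forest":
        subsample = config.subsample
        if subsample > n:
            logger.warning("subsample %d > n=%d; reduced", subsample, n)
            subsample = n
        forest = IsolationForest(n_estimators=config.n_estimators,
                                 max_samples=subsample,
                                 random_state=config.seed)
        forest.fit(x)
        # -score_samples is the expected path-length anomaly score in (0,1)
        scores = -forest.score_samples(x)
    elif config.method == "kmeans":
        km = KMeans(n_clusters=min(config.k_clusters, n), n_init=10,
                    random_state=config.seed)
        km.fit(x)
        d = np.linalg.norm(x[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
        scores = d.min(axis=1)
    elif config.method == "dbscan":
        db = DBSCAN(eps=config.dbscan_eps, min_samples=config.dbscan_min_pts).fit(x)
        noise = db.labels_ == -1
        scores = noise.astype(float)
        if len(db.components_):
            nn = NearestNeighbors(n_neighbors=1).fit(db.components_)
            dist = nn.kneighbors(x)[0][:, 0]
        else:
            dist = np.zeros(n)
        secondary = dist
    elif config.method == "lof":
        k = min(config.lof_neighbors, n - 1)
        if k < 1:
            raise ValueError("LOF needs at least 2 samples")
        lof = LocalOutlierFactor(n_neighbors=k)
        lof.fit(x)
        scores = -lof.negative_outlier_factor_
    else:  # pragma: no cover - guarded by validate()
        raise AssertionError(config.method)
    return AnomalyRanking.from_scores(claim_ids, scores, labels, secondary)


def traditional_rule_score(features: pd.DataFrame,
                           rule_weights: Optional[Dict[str, float]] = None,
                           columns: Optional[List[str]] = None) -> AnomalyRanking:
    """Weighted sum of per-column percentile ranks — the rule-based baseline.

    With no explicit weights, every available feature column gets equal
    weight, which is how a scorecard with no model behind it behaves.
    """
    _, columns = _matrix(features, columns)
    if not rule_weights:
        rule_weights = {c: 1.0 / len(columns) for c in columns}
    missing = [c for c in rule_weights if c not in features.columns]
    if missing:
        raise ValueError(f"rule weights name missing column(s): {missing}")
    scores = np.zeros(len(features))
    for col, w in rule_weights.items():
        pct = rankdata(features[col].to_numpy(), method="average") / len(features)
        scores += w * pct
    labels = features["label"].tolist() if "label" in features else None
    return AnomalyRanking.from_scores(features["claim_id"].astype(str).tolist(),
                                      scores, labels)


def smote_upsample(x: np.ndarray, labels: Sequence, factor: int = 10,
                   k_neighbors: int = 5, seed: int = 0,
                   return_parents: bool = False):
    """Grow every class to ``factor ×`` its size by SMOTE interpolation.

    Synthetic points lie on segments between a class member and one of its
    ``k_neighbors`` same-class nearest neighbours, so the class ratio is
    preserved and the output has exactly ``factor × len(x)`` rows
    (originals first, synthetic rows after, grouped by class).

    With ``return_parents`` a third ``(n_out, 2)`` array is returned holding
    the two parent row indices (into the input) of every synthetic point;
    original rows carry their own index twice.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out_x = [x]
    out_y = [y]
    parents = [np.stack([np.arange(len(x))] * 2, axis=1)]
    for cls in pd.unique(y):
        idx = np.flatnonzero(y == cls)
        n_new = (factor - 1) * len(idx)
        if n_new == 0:
            continue
        xc = x[idx]
        if len(idx) == 1:
            logger.warning("class %r has a single sample; replicating with jitter", cls)
            jitter = rng.normal(0.0, 1e-6, size=(n_new, x.shape[1]))
            out_x.append(np.repeat(xc, n_new, axis=0) + jitter)
            out_y.append(np.repeat(y[idx], n_new))
            parents.append(np.full((n_new, 2), idx[0]))
            continue
        k = min(k_neighbors, len(idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(xc)
        neigh = nn.kneighbors(xc)[1][:, 1:]  # drop self
        base = rng.integers(0, len(idx), size=n_new)
        pick = neigh[base, rng.integers(0, k, size=n_new)]
        lam = rng.random(size=(n_new, 1))
        out_x.append(xc[base] + lam * (xc[pick] - xc[base]))
        out_y.append(np.full(n_new, cls, dtype=y.dtype))
        parents.append(np.stack([idx[base], idx[pick]], axis=1))
    result = np.vstack(out_x), np.concatenate(out_y)
    if return_parents:
        return result[0], result[1], np.vstack(parents)
    return result
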