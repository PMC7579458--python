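"""Detection-rate evaluation and detector comparison.

The triage metric is the *detection rate* (DR): the fraction of truly
abnormal claims among the top ``top_fraction`` (default 10%) of the
anomaly ranking — exactly what an auditor sees when they work down the
first page of the queue.  ``audit_windows`` reproduces the stratified
audit: count labelled-abnormal claims inside fixed-size windows placed at
chosen depths of the ranking.  ``compare_detectors`` runs several detector
configurations (optionally on a SMOTE-augmented copy of the features) and
reports mean ± sd DR across seeds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .outlier import AnomalyRanking, DetectorConfig, detect, smote_upsample

logger = logging.getLogger(__name__)


def detection_rate(ranking: AnomalyRanking, top_fraction: float = 0.10) -> float:
    """Abnormal share of the top ``⌈top_fraction·N⌉`` ranked claims."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = len(ranking)
    if n == 0:
        raise ValueError("empty ranking")
    labels = ranking.table["label"]
    if (labels == "unknown").any():
        raise ValueError("detection rate needs fully labelled rankings")
    k = math.ceil(top_fraction * n)
    return float((labels.iloc[:k] == "abnormal").sum() / k)


def audit_windows(ranking: AnomalyRanking, window: int = 500,
                  at_fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8)) -> pd.DataFrame:
    """Labelled-abnormal counts in ``window``-sized slices at ranking depths.

    For fraction ``f`` the slice covers ranks ``⌈fN⌉+1 … ⌈fN⌉+window``
    (truncated at the tail, with the actual size reported).
    """
    n = len(ranking)
    if n < window:
        raise ValueError(f"ranking of {n} claims shorter than window {window}")
    labels = ranking.table["label"].to_numpy()
    rows = []
    for f in at_fractions:
        start = math.ceil(f * n)
        stop = min(start + window, n)
        if stop - start < window:
            logger.warning("window at fraction %.2f truncated to %d rows", f, stop - start)
        rows.append({"fraction": f,
                     "abnormal_count": int((labels[start:stop] == "abnormal").sum()),
                     "window_size": stop - start})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Per-method DR table plus provenance of the run that produced it."""

    table: pd.DataFrame  # columns: method, dr_mean, dr_sd, n_seeds, status
    top_fraction: float
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "top_fraction": self.top_fraction,
            "provenance": self.provenance,
            "rows": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def compare_detectors(features: pd.DataFrame,
                      methods: Sequence[DetectorConfig],
                      top_fraction: float = 0.10,
                      n_seeds: int = 1,
                      columns: Optional[List[str]] = None,
                      smote_factor: Optional[int] = None) -> EvaluationReport:
    """DR per detector, mean ± sd over ``n_seeds`` reseedings.

    A failing method becomes a ``failed`` row; the comparison continues.
    With ``smote_factor`` the feature matrix is first blown up by SMOTE
    (class ratio preserved) and detectors run on the augmented set.
    """
    work = features
    if smote_factor and smote_factor > 1:
        num_cols = columns or [c for c in features.columns
                               if c not in ("claim_id", "label", "pattern")
                               and np.issubdtype(features[c].dtype, np.number)]
        x, y = smote_upsample(features[num_cols].to_numpy(dtype=float),
                              features["label"].to_numpy(), factor=smote_factor)
        work = pd.DataFrame(x, columns=num_cols)
        work["label"] = y
        work["claim_id"] = [f"A{i:07d}" for i in range(len(work))]

    rows = []
    for cfg in methods:
        drs = []
        status = "ok"
        for s in range(n_seeds):
            run_cfg = DetectorConfig(**{**cfg.__dict__, "seed": cfg.seed + s})
            try:
                ranking = detect(work, run_cfg, columns=columns)
                drs.append(detection_rate(ranking, top_fraction))
            except Exception as exc:  # a detector failure must not sink the report
                logger.error("method %s failed: %s", cfg.method, exc)
                status = f"failed: {exc}"
                break
        rows.append({
            "method": cfg.method,
            "dr_mean": float(np.mean(drs)) if drs else float("nan"),
            "dr_sd": float(np.std(drs)) if drs else float("nan"),
            "n_seeds": len(drs),
            "status": status,
        })
    return EvaluationReport(table=pd.DataFrame(rows), top_fraction=top_fraction)
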