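"""Per-claim engineered features for outlier detection.

Each claim becomes one named real vector spanning four blocks, mirroring
the way claims auditors slice a record:

* **fee** — the person's trailing-365-day totals and averages (amount,
  insurance-paid, self-paid, medicine cost), maximum self-pay, and the
  percentile rank of the current visit's amount in the corpus;
* **frequency** — visit count in the trailing year, mean gap in days
  between consecutive visits, and the number of distinct providers;
* **person** — age, sex, insurance scheme, a fund-balance proxy and a
  credit-score proxy (the latter two are synthesized person attributes:
  deterministic functions of the person's history and identity, since no
  administrative formula exists for them here);
* **treatment/derived** — the disease–prescription relation score, the
  largest single-drug line amount, item count, the insurance pay rate and
  the out-of-pocket rate (which sum to 1), and provider-type encoding.

History aggregates exclude the current claim from its own history; the
visit-gap feature uses the visit dates up to and including the current one.
A person seen only once has no gap — the global maximum gap is substituted
as an explicit sentinel.  Normalization is min-max to [0, 1], fitted on a
training split with out-of-range values clipped at apply time.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .claims_io import ClaimRecord, PROVIDER_TYPES

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    # fee block
    "total_amount", "amount_year", "insurance_paid_year", "self_paid_year",
    "medicine_cost_year", "avg_amount_year", "avg_self_pay_year",
    "avg_medicine_fee_year", "max_self_pay_year", "amount_rank_pct",
    # frequency block
    "visits_year", "avg_gap_days", "distinct_providers_year",
    # person block
    "age", "sex_enc", "insurance_type_enc", "fund_balance_proxy",
    "credit_score_proxy",
    # treatment block
    "relation_score", "max_single_drug_amount", "item_count",
    # derived block
    "insurance_pay_rate", "self_pay_rate", "provider_type_enc",
]


def _stable_unit(s: str, salt: str) -> float:
    """Deterministic pseudo-attribute in [0,1) from an opaque identifier."""
    h = hashlib.md5((salt + ":" + s).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


def engineer_features(records: Sequence[ClaimRecord],
                      relation_scores: Dict[str, float]) -> pd.DataFrame:
    """One feature row per claim (claims without a relation score are skipped).

    Returns a DataFrame with ``claim_id``, ``label``, ``pattern`` and the
    :data:`FEATURE_COLUMNS`.
    """
    rows = []
    for rec in records:
        if rec.claim_id not in relation_scores:
            continue
        medicine = sum(it.amount() for it in rec.items if it.item_type == "drug")
        max_drug = max((it.amount() for it in rec.items if it.item_type == "drug"),
                       default=0.0)
        total = rec.total_amount
        ins_rate = rec.insurance_paid / total if total > 0 else 0.0
        rows.append(dict(
            claim_id=rec.claim_id, person_id=rec.person_id,
            date=pd.Timestamp(rec.visit_date), provider_id=rec.provider_id,
            label=rec.label, pattern=rec.pattern or "",
            total_amount=total, insurance_paid=rec.insurance_paid,
            self_paid=rec.self_paid, medicine_cost=medicine,
            max_single_drug_amount=max_drug, item_count=len(rec.items),
            age=rec.age, sex_enc=1.0 if rec.sex == "F" else 0.0,
            insurance_type_enc=float(hash_code(rec.insurance_type)),
            provider_type_enc=float(PROVIDER_TYPES.index(rec.provider_type)),
            fund_balance_proxy=_stable_unit(rec.person_id, "balance"),
            credit_score_proxy=_stable_unit(rec.person_id, "credit"),
            relation_score=relation_scores[rec.claim_id],
            insurance_pay_rate=ins_rate, self_pay_rate=1.0 - ins_rate,
        ))
    if not rows:
        return pd.DataFrame(columns=["claim_id", "label", "pattern"] + FEATURE_COLUMNS)
    df = pd.DataFrame(rows).sort_values(["person_id", "date", "claim_id"])
    df = df.reset_index(drop=True)

    # corpus-level percentile rank of the visit amount
    df["amount_rank_pct"] = df["total_amount"].rank(pct=True, method="average")

    n = len(df)
    agg_cols = ["amount_year", "insurance_paid_year", "self_paid_year",
                "medicine_cost_year", "avg_amount_year", "avg_self_pay_year",
                "avg_medicine_fee_year", "max_self_pay_year", "visits_year",
                "avg_gap_days", "distinct_providers_year"]
    out = {c: np.zeros(n) for c in agg_cols}
    gap_missing = np.zeros(n, dtype=bool)

    for _, idx in df.groupby("person_id", sort=False).indices.items():
        idx = np.asarray(idx)
        dates = df["date"].values[idx]
        for j, i in enumerate(idx):
            cur = dates[j]
            window = (dates >= cur - np.timedelta64(365, "D")) & (dates <= cur)
            hist = idx[window & (idx != i)]  # history excludes the current claim
            if len(hist):
                out["amount_year"][i] = df["total_amount"].values[hist].sum()
                out["insurance_paid_year"][i] = df["insurance_paid"].values[hist].sum()
                out["self_paid_year"][i] = df["self_paid"].values[hist].sum()
                out["medicine_cost_year"][i] = df["medicine_cost"].values[hist].sum()
                out["avg_amount_year"][i] = df["total_amount"].values[hist].mean()
                out["avg_self_pay_year"][i] = df["self_paid"].values[hist].mean()
                out["avg_medicine_fee_year"][i] = df["medicine_cost"].values[hist].mean()
                out["max_self_pay_year"][i] = df["self_paid"].values[hist].max()
            out["visits_year"][i] = window.sum()  # includes the current visit
            prov = df["provider_id"].values[idx[window]]
            out["distinct_providers_year"][i] = len(set(prov))
            days = np.sort(dates[window])
            if len(days) >= 2:
                gaps = np.diff(days) / np.timedelta64(1, "D")
                out["avg_gap_days"][i] = gaps.mean()
            else:
                gap_missing[i] = True

    for c in agg_cols:
        df[c] = out[c]
    # sentinel: persons with a single visit get the global maximum gap
    max_gap = df.loc[~gap_missing, "avg_gap_days"].max() if (~gap_missing).any() else 365.0
    df.loc[gap_missing, "avg_gap_days"] = max_gap
    df["gap_sentinel"] = gap_missing.astype(float)

    keep = ["claim_id", "label", "pattern"] + FEATURE_COLUMNS + ["gap_sentinel"]
    return df[keep].sort_values("claim_id").reset_index(drop=True)


def hash_code(code: str) -> int:
    """Small stable integer encoding for a categorical code."""
    h = hashlib.md5(code.encode()).digest()
    return int.from_bytes(h[:2], "big") % 97


# ---------------------------------------------------------------------------
# mutual-information feature selection


def _mi_binned(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Plug-in MI (nats) between ``x`` discretized into equal-frequency bins
    and a discrete label ``y``."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) <= bins:
        bx = pd.factorize(x)[0]
    else:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
        bx = np.searchsorted(edges, x, side="right")
    by = pd.factorize(np.asarray(y))[0]
    joint = pd.crosstab(bx, by).to_numpy().astype(float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def select_features(features: pd.DataFrame, labels: Sequence,
                    n_keep: int = 20, bins: int = 10,
                    columns: Optional[List[str]] = None) -> List[str]:
    """The ``n_keep`` columns with the highest binned MI against the label.

    Deterministic: MI ties are broken by column order.
    """
    columns = columns or [c for c in FEATURE_COLUMNS if c in features.columns]
    y = np.asarray(labels)
    if len(y) != len(features):
        raise ValueError("labels must align with feature rows")
    if n_keep >= len(columns):
        if n_keep > len(columns):
            logger.warning("n_keep=%d exceeds %d available features; keeping all",
                           n_keep, len(columns))
        return list(columns)
    mi = {c: _mi_binned(features[c].to_numpy(), y, bins) for c in columns}
    order = sorted(range(len(columns)), key=lambda i: (-mi[columns[i]], i))
    return [columns[i] for i in order[:n_keep]]


# ---------------------------------------------------------------------------
# normalization


@dataclass
class MinMaxBounds:
    lo: pd.Series
    hi: pd.Series

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        out = features.copy()
        for c in self.lo.index:
            span = self.hi[c] - self.lo[c]
            if span <= 0:
                out[c] = 0.0
            else:
                out[c] = ((features[c] - self.lo[c]) / span).clip(0.0, 1.0)
        return out


def normalize_features(features: pd.DataFrame,
                       columns: Optional[List[str]] = None,
                       bounds: Optional[MinMaxBounds] = None,
                       method: str = "minmax") -> Tuple[pd.DataFrame, MinMaxBounds]:
    """Min-max scale ``columns`` into [0,1]; returns the fitted bounds.

    Fitted bounds can be re-applied to new data, where out-of-range values
    are clipped.  Constant columns map to 0 (warned).
    """
    if method != "minmax":
        raise ValueError("only minmax normalization is supported")
    columns = columns or [c for c in FEATURE_COLUMNS if c in features.columns]
    if bounds is None:
        lo = features[columns].min()
        hi = features[columns].max()
        for c in columns:
            if hi[c] <= lo[c]:
                logger.warning("constant feature %r mapped to 0", c)
        bounds = MinMaxBounds(lo=lo, hi=hi)
    return bounds.transform(features), bounds
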