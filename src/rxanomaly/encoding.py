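"""Top-K vocabularies, multi-hot claim encoding, and adjustment-factor resampling.

The modelling universe is clipped to the most frequent ``K_d`` diseases and
``K_r`` drugs in the corpus.  A claim whose every disease and drug falls
inside the vocabularies is encoded as a pair of multi-hot vectors — the
element-wise union of the one-hot codes of its concurrent diseases and of
its co-prescribed drugs; claims touching any out-of-vocabulary code are
*uncovered* and excluded from relation modelling.

The long disease tail is flattened before training with the adjustment
factor: disease ``d`` with ``c_d`` samples is resampled to
``round(min(target_mean / c_d, cap) · c_d)`` samples, the factor capped
(default 10×) so rare diseases are not over-inflated.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

from .claims_io import ClaimRecord

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`encode_record` for out-of-vocabulary claims.
UNCOVERED = "uncovered"


@dataclass
class Vocabulary:
    disease_index: Dict[str, int]
    drug_index: Dict[str, int]
    disease_counts: Dict[str, int]
    drug_counts: Dict[str, int]
    coverage: float  # fraction of source records fully inside both vocabularies

    @property
    def n_diseases(self) -> int:
        return len(self.disease_index)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "coverage": self.coverage,
            "diseases": [
                {"code": c, "index": i, "count": self.disease_counts.get(c, 0)}
                for c, i in sorted(self.disease_index.items(), key=lambda kv: kv[1])
            ],
            "drugs": [
                {"code": c, "index": i, "count": self.drug_counts.get(c, 0)}
                for c, i in sorted(self.drug_index.items(), key=lambda kv: kv[1])
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            disease_index={e["code"]: e["index"] for e in payload["diseases"]},
            drug_index={e["code"]: e["index"] for e in payload["drugs"]},
            disease_counts={e["code"]: e["count"] for e in payload["diseases"]},
            drug_counts={e["code"]: e["count"] for e in payload["drugs"]},
            coverage=payload["coverage"],
        )


@dataclass
class EncodedSample:
    """Multi-hot disease vector (model input) and drug vector (target)."""

    claim_id: str
    disease_idx: np.ndarray  # sorted indices of set bits
    drug_idx: np.ndarray

    def disease_vec(self, k: int) -> np.ndarray:
        v = np.zeros(k, dtype=np.float32)
        v[self.disease_idx] = 1.0
        return v

    def drug_vec(self, k: int) -> np.ndarray:
        v = np.zeros(k, dtype=np.float32)
        v[self.drug_idx] = 1.0
        return v


def _top_k(counts: Counter, k: int, what: str) -> Dict[str, int]:
    if k > len(counts):
        logger.warning("requested top-%d %s but corpus has %d distinct codes; keeping all",
                       k, what, len(counts))
        k = len(counts)
    # highest frequency first, ties by lexicographic code order
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return {code: i for i, (code, _) in enumerate(ranked)}


def build_vocabulary(records: Iterable[ClaimRecord], k_d: int, k_r: int) -> Vocabulary:
    """Top-``k_d``/-``k_r`` code maps by corpus frequency, plus coverage."""
    records = list(records)
    if not records:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    disease_counts: Counter = Counter()
    drug_counts: Counter = Counter()
    for rec in records:
        disease_counts.update(rec.all_diseases())
        drug_counts.update(set(rec.drug_codes()))
    disease_index = _top_k(disease_counts, k_d, "diseases")
    drug_index = _top_k(drug_counts, k_r, "drugs")
    covered = sum(
        1 for rec in records
        if all(d in disease_index for d in rec.all_diseases())
        and all(r in drug_index for r in rec.drug_codes())
    )
    return Vocabulary(
        disease_index=disease_index,
        drug_index=drug_index,
        disease_counts=dict(disease_counts),
        drug_counts=dict(drug_counts),
        coverage=covered / len(records),
    )


def encode_record(record: ClaimRecord, vocab: Vocabulary) -> Union[EncodedSample, str]:
    """Encode one claim, or return :data:`UNCOVERED` if any code is clipped."""
    diseases = record.all_diseases()
    drugs = sorted(set(record.drug_codes()))
    if not drugs:
        return UNCOVERED
    if any(d not in vocab.disease_index for d in diseases):
        return UNCOVERED
    if any(r not in vocab.drug_index for r in drugs):
        return UNCOVERED
    return EncodedSample(
        claim_id=record.claim_id,
        disease_idx=np.array(sorted(vocab.disease_index[d] for d in set(diseases)),
                             dtype=np.int64),
        drug_idx=np.array(sorted(vocab.drug_index[r] for r in drugs), dtype=np.int64),
    )


def encode_corpus(records: Iterable[ClaimRecord],
                  vocab: Vocabulary) -> Tuple[List[EncodedSample], int]:
    """Encode all coverable records; returns ``(samples, uncovered_count)``."""
    samples: List[EncodedSample] = []
    uncovered = 0
    for rec in records:
        enc = encode_record(rec, vocab)
        if enc == UNCOVERED:
            uncovered += 1
        else:
            samples.append(enc)
    return samples, uncovered


def resample_by_adjustment_factor(encoded: List[EncodedSample],
                                  target_mean: Optional[float] = None,
                                  cap: float = 10.0,
                                  seed: int = 0) -> List[EncodedSample]:
    """Flatten per-disease sample counts with the capped adjustment factor.

    Samples are grouped by their first (lowest-index, i.e. most common)
    disease bit as the primary-disease proxy; disease ``d`` with ``c_d``
    samples contributes ``round(min(target_mean / c_d, cap) · c_d)``
    output samples — downsampled without replacement when the factor is
    below 1, upsampled with replacement above 1.  ``target_mean`` defaults
    to the mean group size.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    groups: Dict[int, List[EncodedSample]] = defaultdict(list)
    for s in encoded:
        groups[int(s.disease_idx[0])].append(s)
    if not groups:
        return []
    if target_mean is None:
        target_mean = len(encoded) / len(groups)
    if target_mean < 1:
        raise ValueError("target_mean must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[EncodedSample] = []
    for key in sorted(groups):
        group = groups[key]
        c = len(group)
        factor = min(target_mean / c, cap)
        n_out = int(round(factor * c))
        if n_out == c:
            out.extend(group)
        elif n_out < c:
            idx = rng.choice(c, size=n_out, replace=False)
            out.extend(group[i] for i in sorted(idx))
        else:
            out.extend(group)
            idx = rng.choice(c, size=n_out - c, replace=True)
            out.extend(group[i] for i in idx)
    return out
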