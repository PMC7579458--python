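"""Claim data model and tabular I/O.

One :class:`ClaimRecord` is one outpatient treatment visit: who was treated,
for what diseases, which items (drugs, tests, services) were billed, and how
the fee split between the insurance fund and the patient.  Records travel as
CSV (one row per claim, list-valued fields embedded as JSON arrays in a
single cell) or as JSON-lines; both formats round-trip exactly.

Fee fields are cents-precision: the additivity invariant
``insurance_paid + self_paid == total_amount`` is enforced with a 0.01
tolerance and violating rows are rejected at read time rather than repaired.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

logger = logging.getLogger(__name__)

CURRENCY_TOL = 0.01

PROVIDER_TYPES = ("public_hospital", "private_hospital", "pharmacy")
SEXES = ("M", "F")
LABELS = ("normal", "abnormal", "unknown")
ITEM_TYPES = ("drug", "test", "service")

#: The six abuse/fraud pattern tags a synthetic abnormal record may carry.
PATTERNS = (
    "dosage_abuse",
    "duplicate_test",
    "unrelated_drugs",
    "unrelated_service",
    "similar_effects_abuse",
    "excessive_frequency",
)

_CSV_COLUMNS = [
    "claim_id", "person_id", "visit_date", "provider_id", "provider_type",
    "primary_disease", "secondary_diseases", "items", "total_amount",
    "insurance_paid", "self_paid", "age", "sex", "insurance_type",
    "label", "pattern",
]


@dataclass(frozen=True)
class PrescriptionItem:
    """One billed line item on a claim."""

    drug_code: str
    quantity: int
    unit_price: float
    item_type: str = "drug"

    def amount(self) -> float:
        return round(self.quantity * self.unit_price, 2)


@dataclass
class ClaimRecord:
    """One outpatient visit with fees, diseases and prescribed items."""

    claim_id: str
    person_id: str
    visit_date: str  # ISO-8601 date
    provider_id: str
    provider_type: str
    primary_disease: str
    secondary_diseases: List[str]
    items: List[PrescriptionItem]
    total_amount: float
    insurance_paid: float
    self_paid: float
    age: float
    sex: str
    insurance_type: str
    label: str = "unknown"
    pattern: Optional[str] = None

    def validate(self) -> List[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if abs(self.insurance_paid + self.self_paid - self.total_amount) > CURRENCY_TOL:
            problems.append("fee additivity violated")
        if not self.items:
            problems.append("empty items")
        if self.primary_disease in self.secondary_diseases:
            problems.append("primary disease repeated in secondary list")
        if self.provider_type not in PROVIDER_TYPES:
            problems.append(f"unknown provider_type {self.provider_type!r}")
        if self.sex not in SEXES:
            problems.append(f"unknown sex {self.sex!r}")
        if self.label not in LABELS:
            problems.append(f"unknown label {self.label!r}")
        if self.pattern is not None and self.pattern not in PATTERNS:
            problems.append(f"unknown pattern {self.pattern!r}")
        return problems

    def all_diseases(self) -> List[str]:
        return [self.primary_disease] + list(self.secondary_diseases)

    def drug_codes(self) -> List[str]:
        return [it.drug_code for it in self.items if it.item_type == "drug"]


class SchemaError(ValueError):
    """A mandatory column or key is missing from an input file."""


def _item_to_dict(item: PrescriptionItem) -> dict:
    return dataclasses.asdict(item)


def _record_to_dict(rec: ClaimRecord) -> dict:
    d = dataclasses.asdict(rec)
    d["items"] = [_item_to_dict(it) for it in rec.items]
    return d


def _record_from_dict(d: dict) -> ClaimRecord:
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in d]  # pattern optional
    if missing:
        raise SchemaError(f"missing mandatory field(s): {', '.join(missing)}")
    items = [
        PrescriptionItem(
            drug_code=str(it["drug_code"]),
            quantity=int(it["quantity"]),
            unit_price=float(it["unit_price"]),
            item_type=str(it.get("item_type", "drug")),
        )
        for it in d["items"]
    ]
    pattern = d.get("pattern")
    if pattern in ("", None):
        pattern = None
    return ClaimRecord(
        claim_id=str(d["claim_id"]),
        person_id=str(d["person_id"]),
        visit_date=str(d["visit_date"]),
        provider_id=str(d["provider_id"]),
        provider_type=str(d["provider_type"]),
        primary_disease=str(d["primary_disease"]),
        secondary_diseases=[str(s) for s in d["secondary_diseases"]],
        items=items,
        total_amount=float(d["total_amount"]),
        insurance_paid=float(d["insurance_paid"]),
        self_paid=float(d["self_paid"]),
        age=float(d["age"]),
        sex=str(d["sex"]),
        insurance_type=str(d["insurance_type"]),
        label=str(d.get("label", "unknown")),
        pattern=pattern,
    )


def read_claims(path: str | Path, format: str = "jsonl") -> Tuple[List[ClaimRecord], int]:
    """Read claims from ``path``; returns ``(records, rejected_count)``.

    Rows that fail to parse or violate a record invariant are rejected and
    counted, never fatal.  A missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    path = Path(path)
    records: List[ClaimRecord] = []
    rejected = 0
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _CSV_COLUMNS[:-1] if c not in header]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
            for row in reader:
                try:
                    row = dict(row)
                    row["secondary_diseases"] = json.loads(row["secondary_diseases"])
                    row["items"] = json.loads(row["items"])
                    rec = _record_from_dict(row)
                except (ValueError, KeyError, TypeError) as exc:
                    logger.warning("rejected row: %s", exc)
                    rejected += 1
                    continue
                if rec.validate():
                    rejected += 1
                else:
                    records.append(rec)
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = _record_from_dict(json.loads(line))
                except SchemaError:
                    raise
                except (ValueError, KeyError, TypeError) as exc:
                    logger.warning("rejected line: %s", exc)
                    rejected += 1
                    continue
                if rec.validate():
                    rejected += 1
                else:
                    records.append(rec)
    else:
        raise ValueError(f"unknown format {format!r}")
    if rejected:
        logger.info("read %d records, rejected %d", len(records), rejected)
    return records, rejected


def write_claims(records: Iterable[ClaimRecord], path: str | Path, format: str = "jsonl") -> None:
    """Write records so that :func:`read_claims` recovers them exactly."""
    path = Path(path)
    records = list(records)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for rec in records:
                d = _record_to_dict(rec)
                d["secondary_diseases"] = json.dumps(d["secondary_diseases"])
                d["items"] = json.dumps(d["items"])
                d["pattern"] = d["pattern"] or ""
                writer.writerow(d)
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_dict(rec), sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def clean_claims(records: Iterable[ClaimRecord]) -> Tuple[List[ClaimRecord], int]:
    """Drop records with missing disease codes, empty items, or negative fees.

    Never raises on content; returns ``(kept, dropped_count)`` with
    ``len(kept) + dropped == len(input)``.
    """
    kept: List[ClaimRecord] = []
    dropped = 0
    for rec in records:
        bad = (
            not rec.primary_disease
            or not rec.items
            or rec.total_amount < 0
            or rec.insurance_paid < 0
            or rec.self_paid < 0
        )
        if bad:
            dropped += 1
        else:
            kept.append(rec)
    return kept, dropped
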