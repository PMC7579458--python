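"""Shared fixtures: handcrafted claim fixtures, a small synthetic world,
and one session-scoped benchmark pipeline run reused by the heavier tests."""

from __future__ import annotations

import numpy as np
import pytest

from rxanomaly.claims_io import ClaimRecord, PrescriptionItem
from rxanomaly.pipeline import RunConfig, run_pipeline
from rxanomaly.synthetic import GeneratorConfig, build_compatibility, generate_claims


def make_record(claim_id="C1", person_id="P1", visit_date="2019-03-05",
                primary="D0001", secondary=(), drugs=(("R0001", 2, 10.0),),
                total=None, insurance=None, label="normal", pattern=None,
                provider_type="public_hospital", item_type="drug") -> ClaimRecord:
    items = [PrescriptionItem(code, qty, price, item_type) for code, qty, price in drugs]
    amount = round(sum(it.amount() for it in items), 2) if total is None else total
    ins = round(amount * 0.7, 2) if insurance is None else insurance
    return ClaimRecord(
        claim_id=claim_id, person_id=person_id, visit_date=visit_date,
        provider_id="H001", provider_type=provider_type,
        primary_disease=primary, secondary_diseases=list(secondary),
        items=items, total_amount=amount, insurance_paid=ins,
        self_paid=round(amount - ins, 2), age=40.0, sex="F",
        insurance_type="urban_employee", label=label, pattern=pattern,
    )


@pytest.fixture(scope="session")
def small_world():
    """A compact generated corpus with all six abuse patterns present."""
    cfg = GeneratorConfig(n_records=1200, n_diseases=30, n_drugs=60,
                          drugs_per_disease=5, seed=42)
    model = build_compatibility(cfg)
    records = generate_claims(cfg, model)
    return cfg, model, records


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """One default-scale pipeline run (10,000 claims, 10% anomalies)."""
    out = tmp_path_factory.mktemp("bench")
    cfg = RunConfig(seed=101, out_dir=str(out))
    report, artifacts = run_pipeline(cfg)
    return cfg, report, artifacts
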