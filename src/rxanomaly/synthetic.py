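"""Seeded synthetic outpatient-claims generator with injected abuse patterns.

The generator emulates the statistical structure a provincial claims
database exhibits without shipping any real data:

* a long-tailed disease frequency law — the most common disease is
  ``zipf_ratio`` (default 120) times more frequent than the rank-
  ``n_diseases`` disease, via a power law ``freq(r) ∝ r^(-s)`` whose
  exponent is fixed by the endpoint ratio;
* disease-conditional drug choice: every disease has a fixed compatible
  drug pool and normal visits prescribe only from it;
* concurrent (comorbid) diseases overlaying extra compatible drugs;
* log-normal per-drug unit prices, visit fees averaging ``mean_amount``
  (default 300 currency units) for normal claims;
* an exact share ``anomaly_rate`` of abnormal claims whose mean fee runs
  ``abnormal_amount_multiplier`` (default 5×) the normal mean, each
  realising one of six abuse patterns:

  1. ``dosage_abuse`` — the quantity of one high-priced compatible drug
     inflated at least five-fold;
  2. ``duplicate_test`` — the same test billed ≥ 3 times in one visit;
  3. ``unrelated_drugs`` — at least one drug from outside the disease's
     compatible pool;
  4. ``unrelated_service`` — a service incompatible with the disease;
  5. ``similar_effects_abuse`` — several same-pool drugs at full dosage
     each;
  6. ``excessive_frequency`` — one person visiting ~twice a day over a
     short window, collecting drugs each time.

Patterns are mutually exclusive per record and every abnormal record
carries its pattern tag, so downstream evaluation can attribute detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .claims_io import ClaimRecord, PrescriptionItem, PATTERNS

DEFAULT_PATTERN_MIX: Dict[str, float] = {p: 1.0 / len(PATTERNS) for p in PATTERNS}

_INSURANCE_TYPES = ("urban_employee", "urban_resident", "rural_cooperative")
# Beta(a, b) parameters of the insurance pay-rate distribution per scheme.
_PAY_RATE_BETA = {
    "urban_employee": (8.0, 2.0),
    "urban_resident": (5.0, 3.0),
    "rural_cooperative": (4.0, 4.0),
}

_N_TESTS = 50
_N_SERVICES = 50
_SERVICES_PER_DISEASE = 5

# Price geometry: log-normal sigma and the medians that make a normal visit
# average ~mean_amount at the default mix of item counts (see docs/methods.md).
_PRICE_SIGMA = 0.6
_DRUG_PRICE_MEAN = 59.0
_TEST_PRICE_MEAN = 30.0
_SERVICE_PRICE_MEAN = 40.0
_BASELINE_MEAN_AMOUNT = 300.0


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic claims world.

    Defaults encode the study conditions: 10% anomaly prevalence, a 120:1
    head-to-tail disease frequency ratio over 1000 diseases, 300-unit mean
    outpatient fee and abnormal claims averaging five times that.
    """

    n_records: int = 10_000
    n_diseases: int = 1000
    n_drugs: int = 1000
    zipf_ratio: float = 120.0
    mean_amount: float = 300.0
    abnormal_amount_multiplier: float = 5.0
    anomaly_rate: float = 0.10
    pattern_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    comorbidity_rate: float = 0.25
    drugs_per_disease: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1 or self.n_diseases < 1 or self.n_drugs < 1:
            raise ConfigError("n_records, n_diseases, n_drugs must be >= 1")
        if self.drugs_per_disease < 1 or self.drugs_per_disease > self.n_drugs:
            raise ConfigError("drugs_per_disease must be in [1, n_drugs]")
        if not 0.0 <= self.anomaly_rate <= 0.5:
            raise ConfigError("anomaly_rate must lie in [0, 0.5]")
        if self.zipf_ratio < 1.0:
            raise ConfigError("zipf_ratio must be >= 1")
        unknown = set(self.pattern_mix) - set(PATTERNS)
        if unknown:
            raise ConfigError(f"unknown pattern(s) in pattern_mix: {sorted(unknown)}")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("pattern_mix weights must sum to 1")


@dataclass
class CompatibilityModel:
    """The generative disease→drug world the relation model must recover."""

    disease_codes: List[str]
    drug_codes: List[str]
    disease_freq: np.ndarray          # probability over diseases, rank order
    compat: Dict[str, np.ndarray]     # disease code -> array of compatible drug codes
    compat_probs: Dict[str, np.ndarray]  # per-drug draw probabilities within the pool
    drug_price: Dict[str, float]
    test_codes: List[str]
    test_price: Dict[str, float]
    service_codes: List[str]
    service_price: Dict[str, float]
    compat_services: Dict[str, np.ndarray]

    def compatible_set(self, disease: str) -> set:
        return set(self.compat[disease])

    def incompatible_drug_fraction(self, record: ClaimRecord) -> float:
        """Fraction of a record's drugs outside every claimed disease's pool."""
        allowed: set = set()
        for d in record.all_diseases():
            if d in self.compat:
                allowed |= self.compatible_set(d)
        drugs = record.drug_codes()
        if not drugs:
            return 0.0
        return sum(1 for r in drugs if r not in allowed) / len(drugs)


def _power_law(n: int, ratio: float) -> np.ndarray:
    """Rank-frequency law with freq(1)/freq(n) == ratio exactly."""
    if n == 1:
        return np.array([1.0])
    s = math.log(ratio) / math.log(n)
    f = np.arange(1, n + 1, dtype=float) ** (-s)
    return f / f.sum()


def build_compatibility(config: GeneratorConfig) -> CompatibilityModel:
    """Build the deterministic disease/drug world for ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_diseases)))
    disease_codes = [f"D{i:0{width}d}" for i in range(1, config.n_diseases + 1)]
    rwidth = max(4, len(str(config.n_drugs)))
    drug_codes = [f"R{i:0{rwidth}d}" for i in range(1, config.n_drugs + 1)]

    disease_freq = _power_law(config.n_diseases, config.zipf_ratio)

    price_scale = config.mean_amount / _BASELINE_MEAN_AMOUNT
    mu = math.log(_DRUG_PRICE_MEAN) - _PRICE_SIGMA**2 / 2
    prices = np.round(rng.lognormal(mu, _PRICE_SIGMA, size=config.n_drugs) * price_scale, 2)
    prices = np.maximum(prices, 0.5)
    drug_price = dict(zip(drug_codes, prices.tolist()))

    # Drug popularity skew: widely stocked drugs appear in many pools.
    drug_pop = _power_law(config.n_drugs, min(50.0, config.zipf_ratio))
    compat: Dict[str, np.ndarray] = {}
    compat_probs: Dict[str, np.ndarray] = {}
    for code in disease_codes:
        k = min(config.drugs_per_disease, config.n_drugs)
        pool_idx = rng.choice(config.n_drugs, size=k, replace=False, p=drug_pop)
        pool = np.array([drug_codes[i] for i in sorted(pool_idx)])
        w = rng.dirichlet(np.full(len(pool), 2.0))
        compat[code] = pool
        compat_probs[code] = w

    test_codes = [f"T{i:04d}" for i in range(1, _N_TESTS + 1)]
    tmu = math.log(_TEST_PRICE_MEAN) - _PRICE_SIGMA**2 / 2
    test_price = {
        c: float(max(0.5, round(rng.lognormal(tmu, _PRICE_SIGMA) * price_scale, 2)))
        for c in test_codes
    }
    service_codes = [f"S{i:04d}" for i in range(1, _N_SERVICES + 1)]
    smu = math.log(_SERVICE_PRICE_MEAN) - _PRICE_SIGMA**2 / 2
    service_price = {
        c: float(max(0.5, round(rng.lognormal(smu, _PRICE_SIGMA) * price_scale, 2)))
        for c in service_codes
    }
    compat_services = {
        code: rng.choice(np.array(service_codes), size=_SERVICES_PER_DISEASE, replace=False)
        for code in disease_codes
    }
    return CompatibilityModel(
        disease_codes=disease_codes,
        drug_codes=drug_codes,
        disease_freq=disease_freq,
        compat=compat,
        compat_probs=compat_probs,
        drug_price=drug_price,
        test_codes=test_codes,
        test_price=test_price,
        service_codes=service_codes,
        service_price=service_price,
        compat_services=compat_services,
    )


# ---------------------------------------------------------------------------
# record construction helpers


def _draw_diseases(model: CompatibilityModel, rng: np.random.Generator,
                   comorbidity_rate: float) -> Tuple[str, List[str]]:
    n = len(model.disease_codes)
    primary = model.disease_codes[rng.choice(n, p=model.disease_freq)]
    secondary: List[str] = []
    if n > 1 and rng.random() < comorbidity_rate:
        extra = 1 + (rng.random() < 0.2)
        for _ in range(extra):
            d = model.disease_codes[rng.choice(n, p=model.disease_freq)]
            if d != primary and d not in secondary:
                secondary.append(d)
    return primary, secondary


def _normal_items(model: CompatibilityModel, rng: np.random.Generator,
                  diseases: Sequence[str]) -> List[PrescriptionItem]:
    items: List[PrescriptionItem] = []
    for d in diseases:
        pool, probs = model.compat[d], model.compat_probs[d]
        n_draw = int(rng.integers(1, min(3, len(pool)) + 1))
        idx = rng.choice(len(pool), size=n_draw, replace=False, p=probs)
        for i in idx:
            code = str(pool[i])
            items.append(PrescriptionItem(code, int(rng.integers(1, 4)),
                                          model.drug_price[code], "drug"))
    if rng.random() < 0.3:
        t = model.test_codes[rng.integers(len(model.test_codes))]
        items.append(PrescriptionItem(t, 1, model.test_price[t], "test"))
    if rng.random() < 0.2:
        d0 = diseases[0]
        s = str(rng.choice(model.compat_services[d0]))
        items.append(PrescriptionItem(s, 1, model.service_price[s], "service"))
    return items


def _finalize(items: List[PrescriptionItem], rng: np.random.Generator,
              insurance_type: str) -> Tuple[float, float, float]:
    total = round(sum(it.amount() for it in items), 2)
    a, b = _PAY_RATE_BETA[insurance_type]
    rate = rng.beta(a, b)
    insurance_paid = round(total * rate, 2)
    self_paid = round(total - insurance_paid, 2)
    return total, insurance_paid, self_paid


class _People:
    """Pool of synthetic insured persons with stable demographics."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._attrs: Dict[str, Tuple[float, str, str]] = {}
        self._n = 0

    def new(self) -> str:
        self._n += 1
        pid = f"P{self._n:06d}"
        age = float(np.clip(round(self.rng.normal(46.0, 18.0), 1), 0.0, 99.0))
        sex = "M" if self.rng.random() < 0.5 else "F"
        ins = _INSURANCE_TYPES[self.rng.choice(3, p=[0.5, 0.3, 0.2])]
        self._attrs[pid] = (age, sex, ins)
        return pid

    def attrs(self, pid: str) -> Tuple[float, str, str]:
        return self._attrs[pid]


def _provider(rng: np.random.Generator, abnormal: bool) -> Tuple[str, str]:
    # Abuse concentrates in pharmacies and private hospitals.
    p = [0.45, 0.30, 0.25] if abnormal else [0.80, 0.12, 0.08]
    kind = ("public_hospital", "private_hospital", "pharmacy")[rng.choice(3, p=p)]
    prefix = {"public_hospital": "H", "private_hospital": "V", "pharmacy": "Y"}[kind]
    return f"{prefix}{rng.integers(1, 31):03d}", kind


def _date(day: int) -> str:
    # days counted from 2019-01-01; keep a simple 28-day month calendar
    month, rem = divmod(day % 336, 28)
    return f"2019-{month + 1:02d}-{rem + 1:02d}"


def _apply_pattern(pattern: str, items: List[PrescriptionItem], diseases: Sequence[str],
                   model: CompatibilityModel, rng: np.random.Generator,
                   target: float) -> List[PrescriptionItem]:
    """Realise one abuse pattern, sizing the abusive lines toward ``target``."""
    base = sum(it.amount() for it in items)
    delta = max(target - base, 10.0)
    allowed: set = set()
    for d in diseases:
        allowed |= model.compatible_set(d)
    out = list(items)

    if pattern == "dosage_abuse":
        # inflate the priciest compatible drug at least five-fold
        drug_items = [i for i, it in enumerate(out) if it.item_type == "drug"]
        j = max(drug_items, key=lambda i: out[i].unit_price)
        it = out[j]
        qty = max(int(math.ceil(delta / it.unit_price)), 5 * it.quantity)
        out[j] = PrescriptionItem(it.drug_code, qty, it.unit_price, "drug")
    elif pattern == "duplicate_test":
        k = int(rng.integers(3, 6))
        t = model.test_codes[rng.integers(len(model.test_codes))]
        price = max(0.5, round(delta / k, 2))
        out.extend(PrescriptionItem(t, 1, price, "test") for _ in range(k))
    elif pattern == "unrelated_drugs":
        # the prescription is dominated by off-indication drugs: compatible
        # drug lines are replaced, not merely supplemented
        outside = [c for c in model.drug_codes if c not in allowed]
        if not outside:  # degenerate world: every drug compatible
            outside = list(model.drug_codes)
        out = [it for it in out if it.item_type != "drug"]
        delta = max(target - sum(it.amount() for it in out), 10.0)
        prices = np.array([model.drug_price[c] for c in outside])
        # abuse prefers high-priced drugs: bias the draw toward the top decile
        w = np.where(prices >= np.quantile(prices, 0.9), 5.0, 1.0)
        w = w / w.sum()
        n_extra = int(rng.integers(1, 3))
        picks = rng.choice(len(outside), size=min(n_extra, len(outside)),
                           replace=False, p=w)
        share = delta / len(picks)
        for i in picks:
            code = outside[i]
            price = model.drug_price[code]
            qty = max(1, int(round(share / price)))
            out.append(PrescriptionItem(code, qty, price, "drug"))
    elif pattern == "unrelated_service":
        d0 = diseases[0]
        compatible = set(model.compat_services[d0])
        others = [s for s in model.service_codes if s not in compatible]
        s = others[rng.integers(len(others))] if others else model.service_codes[0]
        price = max(0.5, round(delta, 2))
        out.append(PrescriptionItem(s, 1, price, "service"))
    elif pattern == "similar_effects_abuse":
        d0 = diseases[0]
        pool = model.compat[d0]
        n_extra = min(int(rng.integers(2, 5)), len(pool))
        idx = rng.choice(len(pool), size=n_extra, replace=False)
        share = delta / n_extra
        for i in idx:
            code = str(pool[i])
            price = model.drug_price[code]
            qty = max(3, int(round(share / price)))
            out.append(PrescriptionItem(code, qty, price, "drug"))
    else:  # excessive_frequency visits are sized per-visit by the caller
        drug_items = [i for i, it in enumerate(out) if it.item_type == "drug"]
        j = drug_items[0]
        it = out[j]
        qty = max(int(math.ceil(delta / it.unit_price)), 2 * it.quantity)
        out[j] = PrescriptionItem(it.drug_code, qty, it.unit_price, "drug")
    return out


def generate_claims(config: GeneratorConfig,
                    model: Optional[CompatibilityModel] = None) -> List[ClaimRecord]:
    """Generate ``config.n_records`` claims; exactly ``round(n × anomaly_rate)``
    are labelled abnormal and tagged with an abuse pattern."""
    config.validate()
    if model is None:
        model = build_compatibility(config)
    rng = np.random.default_rng(config.seed + 1)
    people = _People(rng)

    n_abn = int(round(config.n_records * config.anomaly_rate))
    n_norm = config.n_records - n_abn

    records: List[ClaimRecord] = []
    claim_no = 0

    def next_id() -> str:
        nonlocal claim_no
        claim_no += 1
        return f"C{claim_no:07d}"

    # --- normal visits, persons with 1..20 visits each -----------------
    while len(records) < n_norm:
        pid = people.new()
        age, sex, ins = people.attrs(pid)
        n_visits = min(int(rng.integers(1, 21)), n_norm - len(records))
        days = np.sort(rng.choice(336, size=n_visits, replace=False))
        for day in days:
            primary, secondary = _draw_diseases(model, rng, config.comorbidity_rate)
            items = _normal_items(model, rng, [primary] + secondary)
            provider_id, provider_type = _provider(rng, abnormal=False)
            total, ins_paid, self_paid = _finalize(items, rng, ins)
            records.append(ClaimRecord(
                claim_id=next_id(), person_id=pid, visit_date=_date(int(day)),
                provider_id=provider_id, provider_type=provider_type,
                primary_disease=primary, secondary_diseases=secondary,
                items=items, total_amount=total, insurance_paid=ins_paid,
                self_paid=self_paid, age=age, sex=sex, insurance_type=ins,
                label="normal",
            ))

    normal_mean = (sum(r.total_amount for r in records) / len(records)
                   if records else config.mean_amount)
    target_mean = config.abnormal_amount_multiplier * normal_mean

    # --- abnormal visits -------------------------------------------------
    # Allocate the exact abnormal quota across patterns by largest remainder,
    # so pattern_mix governs the share of *records* (a pattern-6 burst spends
    # several records of its own pattern's quota).
    pattern_names = [p for p in config.pattern_mix if config.pattern_mix[p] > 0]
    raw = np.array([config.pattern_mix[p] for p in pattern_names]) * n_abn
    quota = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - quota))[: n_abn - quota.sum()]:
        quota[i] += 1

    # Fee inflation is concentrated in the billing-driven patterns; an
    # off-indication prescription (pattern 3) is fee-wise unremarkable
    # (~1.5× a normal visit), so the remaining patterns carry enough extra
    # to keep the *overall* abnormal mean at the configured multiplier.
    mult = config.abnormal_amount_multiplier
    q3 = sum(int(q) for p, q in zip(pattern_names, quota) if p == "unrelated_drugs")
    q_other = n_abn - q3
    if q_other > 0:
        mean3 = min(1.5, mult) * normal_mean
        mean_other = (mult * n_abn - min(1.5, mult) * q3) / q_other * normal_mean
    else:
        mean3 = mult * normal_mean
        mean_other = mult * normal_mean

    def draw_target(pattern: str) -> float:
        # Gamma(shape 6) around the pattern's target keeps fees plausible.
        mean = mean3 if pattern == "unrelated_drugs" else mean_other
        return float(rng.gamma(6.0, mean / 6.0))

    for pattern, n_quota in zip(pattern_names, quota):
        remaining = int(n_quota)
        while remaining > 0:
            if pattern == "excessive_frequency":
                n_visits = int(min(remaining, rng.integers(6, 11)))
                pid = people.new()
                age, sex, ins = people.attrs(pid)
                start = int(rng.integers(0, 330))
                primary, _ = _draw_diseases(model, rng, 0.0)
                for v in range(n_visits):
                    day = start + v // 2  # two visits a day
                    items = _normal_items(model, rng, [primary])
                    items = _apply_pattern(pattern, items, [primary], model, rng,
                                           draw_target(pattern))
                    provider_id, provider_type = _provider(rng, abnormal=True)
                    total, ins_paid, self_paid = _finalize(items, rng, ins)
                    records.append(ClaimRecord(
                        claim_id=next_id(), person_id=pid, visit_date=_date(day),
                        provider_id=provider_id, provider_type=provider_type,
                        primary_disease=primary, secondary_diseases=[],
                        items=items, total_amount=total, insurance_paid=ins_paid,
                        self_paid=self_paid, age=age, sex=sex, insurance_type=ins,
                        label="abnormal", pattern=pattern,
                    ))
                remaining -= n_visits
            else:
                pid = people.new()
                age, sex, ins = people.attrs(pid)
                day = int(rng.integers(0, 336))
                primary, secondary = _draw_diseases(model, rng, config.comorbidity_rate)
                diseases = [primary] + secondary
                items = _normal_items(model, rng, diseases)
                items = _apply_pattern(pattern, items, diseases, model, rng, draw_target(pattern))
                provider_id, provider_type = _provider(rng, abnormal=True)
                total, ins_paid, self_paid = _finalize(items, rng, ins)
                records.append(ClaimRecord(
                    claim_id=next_id(), person_id=pid, visit_date=_date(day),
                    provider_id=provider_id, provider_type=provider_type,
                    primary_disease=primary, secondary_diseases=secondary,
                    items=items, total_amount=total, insurance_paid=ins_paid,
                    self_paid=self_paid, age=age, sex=sex, insurance_type=ins,
                    label="abnormal", pattern=pattern,
                ))
                remaining -= 1

    return records
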