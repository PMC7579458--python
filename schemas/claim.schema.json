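{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ClaimRecord",
 "description": "One outpatient treatment visit as exchanged in JSON-lines claim files; in the CSV dialect the list-valued fields (secondary_diseases, items) are embedded as JSON arrays inside a single quoted cell.",
 "type": "object",
 "required": [
  "claim_id", "person_id", "visit_date", "provider_id", "provider_type",
  "primary_disease", "secondary_diseases", "items", "total_amount",
  "insurance_paid", "self_paid", "age", "sex", "insurance_type", "label"
 ],
 "properties": {
  "claim_id": {"type": "string"},
  "person_id": {"type": "string"},
  "visit_date": {"type": "string", "format": "date"},
  "provider_id": {"type": "string"},
  "provider_type": {"enum": ["public_hospital", "private_hospital", "pharmacy"]},
  "primary_disease": {"type": "string"},
  "secondary_diseases": {"type": "array", "items": {"type": "string"}},
  "items": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["drug_code", "quantity", "unit_price"],
    "properties": {
     "drug_code": {"type": "string"},
     "quantity": {"type": "integer", "minimum": 1},
     "unit_price": {"type": "number", "minimum": 0},
     "item_type": {"enum": ["drug", "test", "service"], "default": "drug"}
    }
   }
  },
  "total_amount": {"type": "number", "minimum": 0,
                   "description": "equals insurance_paid + self_paid within 0.01"},
  "insurance_paid": {"type": "number", "minimum": 0},
  "self_paid": {"type": "number", "minimum": 0},
  "age": {"type": "number", "minimum": 0},
  "sex": {"enum": ["M", "F"]},
  "insurance_type": {"type": "string"},
  "label": {"enum": ["normal", "abnormal", "unknown"], "default": "unknown"},
  "pattern": {
   "description": "synthetic provenance tag; absent/null on real or normal records",
   "enum": ["dosage_abuse", "duplicate_test", "unrelated_drugs",
            "unrelated_service", "similar_effects_abuse",
            "excessive_frequency", null]
  }
 }
}
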