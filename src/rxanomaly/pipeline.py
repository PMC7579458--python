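"""End-to-end reproducible run: generate → clean → encode → train → score
→ featurize → select → normalize → detect → evaluate.

A single root seed deterministically derives every stage's seed (hash of
``(root_seed, stage_name)``), so one integer reproduces the whole run.  All
intermediate artifacts are written to the output directory together with a
manifest recording the config hash, stage seeds and record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import claims_io, encoding, evaluation, features as feat, outlier, synthetic
from .relation_model import RelationModel, RelationModelConfig, train_relation_model

logger = logging.getLogger(__name__)

STAGES = ("generate", "resample", "train", "select", "detect")


def stage_seed(root_seed: int, stage: str) -> int:
    """Independent per-stage seed stream derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    # The benchmark pipeline trains with the plain cross-entropy objective:
    # at CPU-scale step budgets it reaches the concentrated-probability
    # regime the relation score needs, which the focal variant approaches
    # only with far more steps (docs/methods.md discusses the trade-off).
    model: RelationModelConfig = field(default_factory=lambda: RelationModelConfig(
        loss="bce", epochs=8, learning_rate=3e-3))
    detector: outlier.DetectorConfig = field(default_factory=outlier.DetectorConfig)
    k_d: int = 1000
    k_r: int = 1000
    n_select: int = 20
    label_slice: int = 1000   # labelled records used for feature selection
    top_fraction: float = 0.10
    seed: int = 0
    out_dir: str = "rxanomaly_run"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Tuple[evaluation.EvaluationReport, Dict[str, Path]]:
    """Run all stages; returns the report and the artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    manifest: Dict[str, object] = {
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "counts": {},
        "timings_s": {},
    }

    def _stage(name):
        t0 = time.time()

        def done(**counts):
            manifest["timings_s"][name] = round(time.time() - t0, 3)
            manifest["counts"].update(counts)
            logger.info("stage %-10s %6.2fs %s", name, time.time() - t0, counts)
        return done

    # 1. generate ---------------------------------------------------------
    done = _stage("generate")
    gen_cfg = dataclasses.replace(config.generator, seed=stage_seed(config.seed, "generate"))
    model_world = synthetic.build_compatibility(gen_cfg)
    records = synthetic.generate_claims(gen_cfg, model_world)
    artifacts["claims"] = out / "claims.jsonl"
    claims_io.write_claims(records, artifacts["claims"], "jsonl")
    done(generated=len(records))

    # 2. clean ------------------------------------------------------------
    done = _stage("clean")
    records, dropped = claims_io.clean_claims(records)
    done(cleaned=len(records), dropped=dropped)

    # 3. vocabulary + encoding -------------------------------------------
    done = _stage("encode")
    vocab = encoding.build_vocabulary(records, config.k_d, config.k_r)
    artifacts["vocab"] = out / "vocab.json"
    vocab.to_json(artifacts["vocab"])
    samples, uncovered = encoding.encode_corpus(records, vocab)
    by_id = {r.claim_id: r for r in records}
    done(encoded=len(samples), uncovered=uncovered, coverage=round(vocab.coverage, 4))

    # 4. resample for training -------------------------------------------
    done = _stage("resample")
    train_samples = encoding.resample_by_adjustment_factor(
        samples, seed=stage_seed(config.seed, "resample"))
    done(train_samples=len(train_samples))

    # 5. train the relation model ----------------------------------------
    done = _stage("train")
    model_cfg = dataclasses.replace(config.model, seed=stage_seed(config.seed, "train"))
    model = train_relation_model(train_samples, vocab.n_diseases, vocab.n_drugs, model_cfg)
    artifacts["model"] = out / "model.npz"
    model.save(artifacts["model"])
    done(epochs=model_cfg.epochs, final_loss=round(model.loss_history[-1], 6))

    # 6. relation scores --------------------------------------------------
    done = _stage("score")
    scores = model.score_samples(samples)
    score_map = {s.claim_id: float(v) for s, v in zip(samples, scores)}
    artifacts["scores"] = out / "scores.csv"
    with open(artifacts["scores"], "w") as fh:
        fh.write("claim_id,relation_score\n")
        for cid in sorted(score_map):
            fh.write(f"{cid},{score_map[cid]:.6f}\n")
    done(scored=len(score_map))

    # 7. features ---------------------------------------------------------
    done = _stage("featurize")
    covered_records = [by_id[s.claim_id] for s in samples]
    fdf = feat.engineer_features(covered_records, score_map)
    artifacts["features"] = out / "features.csv"
    fdf.to_csv(artifacts["features"], index=False)
    done(feature_rows=len(fdf))

    # 8. select + normalize ----------------------------------------------
    done = _stage("select")
    rng = np.random.default_rng(stage_seed(config.seed, "select"))
    slice_idx = rng.choice(len(fdf), size=min(config.label_slice, len(fdf)), replace=False)
    labelled = fdf.iloc[slice_idx]
    selected = feat.select_features(labelled, (labelled["label"] == "abnormal").astype(int),
                                    n_keep=config.n_select)
    normalized, _ = feat.normalize_features(fdf, columns=selected)
    done(selected_features=len(selected))

    # 9. detect -----------------------------------------------------------
    done = _stage("detect")
    det_cfg = dataclasses.replace(config.detector, seed=stage_seed(config.seed, "detect"))
    ranking = outlier.detect(normalized, det_cfg, columns=selected)
    artifacts["ranking"] = out / "ranking.csv"
    ranking.to_csv(artifacts["ranking"])
    done(ranked=len(ranking))

    # 10. evaluate --------------------------------------------------------
    done = _stage("evaluate")
    labels = ranking.table["label"]
    if (labels == "abnormal").sum() == 0:
        logger.warning("no abnormal claims in the run; detection rate reported as 0")
        dr = 0.0
    else:
        dr = evaluation.detection_rate(ranking, config.top_fraction)
    report = evaluation.EvaluationReport(
        table=pd.DataFrame([{
            "method": det_cfg.method, "dr_mean": dr, "dr_sd": 0.0,
            "n_seeds": 1, "status": "ok",
        }]),
        top_fraction=config.top_fraction,
        provenance={"config_hash": manifest["config_hash"], "seed": config.seed,
                    "selected_features": selected},
    )
    artifacts["report"] = out / "report.json"
    report.to_json(artifacts["report"])
    done(detection_rate=round(dr, 4))

    artifacts["manifest"] = out / "manifest.json"
    with open(artifacts["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return report, artifacts
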