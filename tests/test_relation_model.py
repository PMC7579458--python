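"""Losses, relation score, ranking metrics, and network training behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxanomaly.claims_io import read_claims
from rxanomaly.encoding import (EncodedSample, Vocabulary, build_vocabulary,
                                encode_corpus)
from rxanomaly.relation_model import (RelationModel, RelationModelConfig,
                                      coverage_metric, focal_loss,
                                      multilabel_bce, one_error,
                                      relation_score, train_relation_model)
from rxanomaly.synthetic import GeneratorConfig, generate_claims

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_relation(y, gt):
    num = sum(a * b for a, b in zip(y, gt))
    den = sum(y)
    return num / den if den > 0 else 0.0


def brute_one_error(s, g):
    miss = 0
    for row_s, row_g in zip(s, g):
        best = max(range(len(row_s)), key=lambda j: (row_s[j], -j))
        miss += row_g[best] == 0
    return miss / len(s)


def brute_coverage(s, g):
    total = 0
    for row_s, row_g in zip(s, g):
        order = sorted(range(len(row_s)), key=lambda j: (-row_s[j], j))
        pos = {j: r for r, j in enumerate(order, start=1)}
        total += max(pos[j] for j in range(len(row_g)) if row_g[j]) - 1
    return total / len(s)


# ---------------------------------------------------------------------------
# losses


def test_bce_closed_forms():
    assert multilabel_bce([0.5], [1.0]) == pytest.approx(math.log(2), abs=1e-9)
    # perfect prediction at the clamp boundary
    assert multilabel_bce([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-5)
    with pytest.raises(ValueError):
        multilabel_bce([0.5, 0.5], [1.0])


def test_bce_symmetric_under_label_flip():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.01, 0.99, size=12)
    y = (rng.random(12) < 0.5).astype(float)
    assert multilabel_bce(p, y) == pytest.approx(multilabel_bce(1 - p, 1 - y), abs=1e-12)


def test_focal_single_label_closed_form():
    expected = 0.25 * (1 - 0.9) ** 2 * (-math.log(0.9))
    assert focal_loss([0.9], [1.0], alpha=0.25, gamma=2.0) == pytest.approx(
        expected, abs=1e-12)


def test_focal_reduces_to_half_bce_at_gamma_zero():
    rng = np.random.default_rng(1)
    for _ in range(50):
        m = rng.integers(1, 30)
        p = rng.uniform(1e-6, 1 - 1e-6, size=m)
        y = (rng.random(m) < 0.3).astype(float)
        assert focal_loss(p, y, alpha=0.5, gamma=0.0) == pytest.approx(
            0.5 * multilabel_bce(p, y), abs=1e-9)


def test_focal_vanishes_as_pt_approaches_one():
    losses = [focal_loss([p], [1.0], 0.25, 2.0) for p in (0.5, 0.9, 0.99, 0.999)]
    assert losses == sorted(losses, reverse=True)
    assert losses[-1] < 1e-6
    with pytest.raises(ValueError):
        focal_loss([0.5], [1.0], alpha=0.25, gamma=-1.0)


# ---------------------------------------------------------------------------
# relation score


def test_relation_score_identities():
    # predictions supported only on ground-truth drugs
    assert relation_score([0.7, 0.0, 0.3, 0.0], [1, 0, 1, 0]) == pytest.approx(1.0)
    # uniform predictions → m_gt / m
    assert relation_score([0.25] * 4, [1, 0, 1, 0]) == pytest.approx(0.5)
    assert relation_score([0.5, 0.3, 0.1, 0.1], [1, 0, 1, 0]) == pytest.approx(0.6)
    # all-zero prediction vector is defined as 0
    assert relation_score([0.0, 0.0], [1, 0]) == 0.0


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30), st.data())
def test_relation_score_matches_brute_force_and_is_scale_invariant(y, data):
    gt = data.draw(st.lists(st.booleans(), min_size=len(y), max_size=len(y)))
    gt = [float(b) for b in gt]
    got = relation_score(y, gt)
    assert got == pytest.approx(brute_relation(y, gt), abs=1e-12)
    c = data.draw(st.floats(0.1, 50.0))
    if sum(y) > 0:
        assert relation_score([c * v for v in y], gt) == pytest.approx(got, rel=1e-9)


# ---------------------------------------------------------------------------
# ranking metrics


def test_one_error_boundary_cases():
    s = np.array([[0.9, 0.1], [0.2, 0.8]])
    assert one_error(s, np.array([[1, 0], [0, 1]])) == 0.0
    assert one_error(s, np.array([[0, 1], [1, 0]])) == 1.0
    s4 = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.6, 0.2, 0.2], [0.2, 0.3, 0.5]])
    g4 = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [1, 1, 0]])  # last row misses
    assert one_error(s4, g4) == pytest.approx(0.25)


def test_coverage_handcrafted_rows():
    # single true label ranked first → coverage 0
    assert coverage_metric(np.array([[0.9, 0.1]]), np.array([[1, 0]])) == 0.0
    # true labels at ranks 1 and 4 of 5 → contributes 3
    s = np.array([[0.9, 0.5, 0.4, 0.3, 0.1]])
    g = np.array([[1, 0, 0, 1, 0]])
    assert coverage_metric(s, g) == 3.0
    # an always-last noise label leaves other labels' coverage unchanged
    s2 = np.hstack([s, [[-1.0]]])
    g2 = np.hstack([g, [[0]]])
    assert coverage_metric(s2, g2) == 3.0


def test_ranking_metrics_match_brute_force_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n, m = rng.integers(1, 20), rng.integers(2, 15)
        s = rng.random((n, m)).round(2)  # rounding forces score ties
        g = np.zeros((n, m), dtype=int)
        for i in range(n):
            g[i, rng.choice(m, size=rng.integers(1, m), replace=False)] = 1
        assert one_error(s, g) == pytest.approx(brute_one_error(s, g), abs=1e-12)
        assert coverage_metric(s, g) == pytest.approx(brute_coverage(s, g), abs=1e-12)


# ---------------------------------------------------------------------------
# training


def _toy_samples():
    """Deterministic 2-disease → drug mapping: d0→r0, d1→{r1,r2}."""
    samples = []
    for i in range(40):
        samples.append(EncodedSample(f"a{i}", np.array([0]), np.array([0])))
        samples.append(EncodedSample(f"b{i}", np.array([1]), np.array([1, 2])))
    return samples


def test_toy_corpus_recovers_the_generative_mapping():
    cfg = RelationModelConfig(epochs=200, batch_size=80, refine_steps=1,
                              learning_rate=3e-3, seed=0)
    model = train_relation_model(_toy_samples(), 2, 3, cfg)
    p0 = model.predict_drug_probabilities(np.array([1.0, 0.0], dtype=np.float32))
    p1 = model.predict_drug_probabilities(np.array([0.0, 1.0], dtype=np.float32))
    assert p0[0] > max(p0[1], p0[2])
    assert min(p1[1], p1[2]) > p1[0]
    # training loss decreases over epochs
    assert model.loss_history[-1] < model.loss_history[0]


def test_retraining_same_seed_reproduces_final_loss():
    cfg = RelationModelConfig(epochs=20, batch_size=80, seed=4)
    a = train_relation_model(_toy_samples(), 2, 3, cfg)
    b = train_relation_model(_toy_samples(), 2, 3, cfg)
    assert a.loss_history[-1] == pytest.approx(b.loss_history[-1], rel=1e-6)


def test_refinement_steps_do_not_change_output_shape():
    for steps in (0, 2):
        cfg = RelationModelConfig(epochs=1, refine_steps=steps, batch_size=80, seed=0)
        model = train_relation_model(_toy_samples(), 2, 3, cfg)
        out = model.predict_drug_probabilities(np.eye(2, dtype=np.float32))
        assert out.shape == (2, 3)
        assert ((out > 0) & (out < 1)).all()


def test_dimension_mismatch_fails_before_training():
    bad = [EncodedSample("x", np.array([5]), np.array([0]))]
    with pytest.raises(ValueError, match="disease dim"):
        train_relation_model(bad, 2, 3, RelationModelConfig(epochs=1))


def test_model_round_trips_through_checkpoint(tmp_path):
    cfg = RelationModelConfig(epochs=5, batch_size=80, seed=1)
    model = train_relation_model(_toy_samples(), 2, 3, cfg)
    model.save(tmp_path / "m.npz")
    back = RelationModel.load(tmp_path / "m.npz")
    x = np.eye(2, dtype=np.float32)
    assert np.allclose(back.predict_drug_probabilities(x),
                       model.predict_drug_probabilities(x))


def test_pattern_separation_grows_with_training():
    """Unrelated-drug claims score below normals, increasingly so with epochs."""
    gen = GeneratorConfig(n_records=3000, n_diseases=30, n_drugs=60,
                          drugs_per_disease=5, anomaly_rate=0.10,
                          pattern_mix={"unrelated_drugs": 1.0}, seed=13)
    records = generate_claims(gen)
    vocab = build_vocabulary(records, 30, 60)
    samples, _ = encode_corpus(records, vocab)
    pattern = {r.claim_id: r.pattern for r in records}
    gaps = []
    for epochs in (1, 4, 10):
        cfg = RelationModelConfig(epochs=epochs, loss="bce", learning_rate=3e-3, seed=0)
        model = train_relation_model(samples, vocab.n_diseases, vocab.n_drugs, cfg)
        sc = model.score_samples(samples)
        p3 = np.array([v for s, v in zip(samples, sc) if pattern[s.claim_id]])
        normal = np.array([v for s, v in zip(samples, sc) if not pattern[s.claim_id]])
        gaps.append(normal.mean() - p3.mean())
    assert gaps == sorted(gaps)
    assert gaps[-1] > 0


def test_relation_score_dwarfs_mean_label_probability(benchmark_run):
    """The trained model concentrates probability mass: the mean relation
    score is ≥ 50× the mean per-drug probability (the diffuse-background
    regime would make both comparable)."""
    _, _, artifacts = benchmark_run
    model = RelationModel.load(artifacts["model"])
    vocab = Vocabulary.from_json(artifacts["vocab"])
    records, _ = read_claims(artifacts["claims"], "jsonl")
    samples, _ = encode_corpus(records, vocab)
    subset = samples[:1500]
    x = np.stack([s.disease_vec(vocab.n_diseases) for s in subset])
    mean_prob = model.predict_drug_probabilities(x).mean()
    scores = pd.read_csv(artifacts["scores"])["relation_score"]
    assert scores.mean() >= 50 * mean_prob
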