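"""Detection rate, audit windows, detector comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from rxanomaly.evaluation import (audit_windows, compare_detectors,
                                  detection_rate)
from rxanomaly.outlier import AnomalyRanking, DetectorConfig


def _ranking(labels, scores=None):
    n = len(labels)
    scores = np.arange(n, 0, -1, dtype=float) if scores is None else scores
    return AnomalyRanking.from_scores([f"C{i:05d}" for i in range(n)], scores, labels)


def brute_dr(labels, top_fraction):
    k = math.ceil(top_fraction * len(labels))
    return sum(1 for l in labels[:k] if l == "abnormal") / k


def test_perfect_ranking_gives_dr_one():
    labels = ["abnormal"] * 100 + ["normal"] * 900
    assert detection_rate(_ranking(labels), 0.10) == 1.0


def test_tiny_ranking_window_rounds_up():
    labels = ["abnormal", "normal", "abnormal"] + ["normal"] * 7
    assert detection_rate(_ranking(labels), 0.1) == 1.0  # top-1 window


def test_detection_rate_matches_brute_force_on_random_rankings():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(10, 200))
        labels = ["abnormal" if rng.random() < 0.2 else "normal" for _ in range(n)]
        f = float(rng.uniform(0.05, 1.0))
        assert detection_rate(_ranking(labels), f) == pytest.approx(
            brute_dr(labels, f), abs=1e-12)


def test_random_ranking_dr_matches_prevalence_in_expectation():
    """Hypergeometric expectation: E[DR] equals the anomaly prevalence."""
    rng = np.random.default_rng(42)
    base = np.array(["abnormal"] * 100 + ["normal"] * 900)
    drs = []
    for _ in range(200):
        drs.append(detection_rate(_ranking(rng.permutation(base)), 0.10))
    assert np.mean(drs) == pytest.approx(0.10, abs=0.02)


def test_top_fraction_bounds_are_enforced():
    labels = ["abnormal"] * 5 + ["normal"] * 5
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            detection_rate(_ranking(labels), bad)


def test_unlabelled_ranking_is_rejected():
    r = AnomalyRanking.from_scores(["A", "B"], np.array([2.0, 1.0]))
    with pytest.raises(ValueError, match="labelled"):
        detection_rate(r)


# ---------------------------------------------------------------------------
# audit windows


def test_audit_windows_on_perfect_ranking():
    labels = ["abnormal"] * 200 + ["normal"] * 1800
    table = audit_windows(_ranking(labels), window=500, at_fractions=[0.0, 0.8])
    head, tail = table.iloc[0], table.iloc[1]
    assert head["abnormal_count"] == 200  # min(window, total abnormal)
    assert tail["abnormal_count"] == 0
    assert head["window_size"] == 500


def test_audit_windows_match_a_direct_scan():
    rng = np.random.default_rng(3)
    labels = ["abnormal" if rng.random() < 0.1 else "normal" for _ in range(2000)]
    table = audit_windows(_ranking(labels), window=500,
                          at_fractions=[0.0, 0.2, 0.4, 0.6, 0.8])
    for _, row in table.iterrows():
        start = math.ceil(row["fraction"] * 2000)
        expect = sum(1 for l in labels[start:start + 500] if l == "abnormal")
        assert row["abnormal_count"] == expect
    # disjoint windows cannot exceed the total abnormal count
    disjoint = audit_windows(_ranking(labels), window=400,
                             at_fractions=[0.0, 0.2, 0.4, 0.6, 0.8])
    assert disjoint["abnormal_count"].sum() <= labels.count("abnormal")


def test_audit_tail_window_truncates_with_reported_size():
    labels = ["normal"] * 600
    table = audit_windows(_ranking(labels), window=500, at_fractions=[0.5])
    assert table.iloc[0]["window_size"] == 300


# ---------------------------------------------------------------------------
# compare_detectors


def _separable_features(n_out=10, n_in=90, seed=0):
    rng = np.random.default_rng(seed)
    # scattered singleton outliers far from a tight cluster at the origin
    outliers = np.stack([3.0 + np.arange(n_out), 3.0 + 2 * np.arange(n_out)], axis=1)
    x = np.vstack([rng.normal(0, 0.05, (n_in, 2)), outliers[:n_out]])
    df = pd.DataFrame(x, columns=["f1", "f2"])
    df["claim_id"] = [f"C{i:03d}" for i in range(n_in + n_out)]
    df["label"] = ["normal"] * n_in + ["abnormal"] * n_out
    return df


def test_single_method_report_has_one_row():
    df = _separable_features()
    report = compare_detectors(df, [DetectorConfig(method="traditional_rule")])
    assert len(report.table) == 1
    assert report.table.iloc[0]["status"] == "ok"


def test_separable_toy_gives_dr_one_for_every_method():
    df = _separable_features()
    methods = [DetectorConfig(method=m, k_clusters=1, lof_neighbors=10,
                              dbscan_eps=0.5, dbscan_min_pts=5, seed=0)
               for m in ("isolation_forest", "kmeans", "lof", "dbscan")]
    report = compare_detectors(df, methods, top_fraction=0.10)
    assert (report.table["dr_mean"] == 1.0).all()


def test_identical_configs_give_identical_rows():
    df = _separable_features()
    cfg = DetectorConfig(method="isolation_forest", seed=7)
    report = compare_detectors(df, [cfg, cfg], top_fraction=0.10, n_seeds=2)
    a, b = report.table.iloc[0], report.table.iloc[1]
    assert a["dr_mean"] == b["dr_mean"] and a["dr_sd"] == b["dr_sd"]


def test_failing_method_becomes_failed_row_and_comparison_continues():
    df = _separable_features(n_out=1, n_in=0, seed=1)  # single row: LOF must fail
    report = compare_detectors(df, [DetectorConfig(method="lof"),
                                    DetectorConfig(method="traditional_rule")])
    assert report.table.iloc[0]["status"].startswith("failed")
    assert report.table.iloc[1]["status"] == "ok"


def test_smote_factor_blows_up_the_evaluation_set():
    df = _separable_features()
    report = compare_detectors(df, [DetectorConfig(method="kmeans", k_clusters=1)],
                               top_fraction=0.10, smote_factor=10)
    assert report.table.iloc[0]["dr_mean"] == 1.0
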