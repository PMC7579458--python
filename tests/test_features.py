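"""Feature engineering, mutual-information selection, normalization."""

import numpy as np
import pandas as pd
import pytest

from rxanomaly.features import (FEATURE_COLUMNS, _mi_binned, engineer_features,
                                normalize_features, select_features)

from conftest import make_record


def test_average_gap_over_three_visits():
    # visits on days 0, 10, 30 → gaps 10 and 20 → mean 15 at the last claim
    recs = [make_record(claim_id="V0", visit_date="2019-01-01"),
            make_record(claim_id="V1", visit_date="2019-01-11"),
            make_record(claim_id="V2", visit_date="2019-01-31")]
    scores = {r.claim_id: 0.5 for r in recs}
    fdf = engineer_features(recs, scores).set_index("claim_id")
    assert fdf.loc["V2", "avg_gap_days"] == pytest.approx(15.0)
    assert fdf.loc["V2", "visits_year"] == 3
    # history excludes the current claim from fee aggregates
    assert fdf.loc["V2", "amount_year"] == pytest.approx(2 * recs[0].total_amount)


def test_single_visit_person_gets_sentinel_gap():
    recs = [make_record(claim_id="L1", person_id="lone", visit_date="2019-06-01"),
            make_record(claim_id="M1", person_id="many", visit_date="2019-01-01"),
            make_record(claim_id="M2", person_id="many", visit_date="2019-01-08")]
    fdf = engineer_features(recs, {r.claim_id: 0.1 for r in recs}).set_index("claim_id")
    assert fdf.loc["M2", "avg_gap_days"] == 7.0
    assert fdf.loc["L1", "avg_gap_days"] == 7.0  # global max as sentinel
    assert fdf.loc["L1", "gap_sentinel"] == 1.0


def test_pay_rate_boundary_and_complement():
    full = make_record(claim_id="F", insurance=20.0)  # insurance covers all
    none = make_record(claim_id="N", insurance=0.0)
    fdf = engineer_features([full, none], {"F": 0.2, "N": 0.2}).set_index("claim_id")
    assert fdf.loc["F", "insurance_pay_rate"] == 1.0
    assert fdf.loc["F", "self_pay_rate"] == 0.0
    assert fdf.loc["N", "insurance_pay_rate"] == 0.0
    rates = fdf["insurance_pay_rate"] + fdf["self_pay_rate"]
    assert np.allclose(rates, 1.0, atol=1e-6)


def test_feature_engineering_is_pure(small_world):
    _, _, records = small_world
    scores = {r.claim_id: 0.3 for r in records}
    a = engineer_features(records, scores)
    b = engineer_features(records, scores)
    pd.testing.assert_frame_equal(a, b)
    assert set(FEATURE_COLUMNS) <= set(a.columns)


def test_records_without_scores_are_excluded(small_world):
    _, _, records = small_world
    scores = {r.claim_id: 0.3 for r in records[:50]}
    fdf = engineer_features(records, scores)
    assert len(fdf) == 50


# ---------------------------------------------------------------------------
# mutual-information selection


def _mi_frame(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    label = (rng.random(n) < 0.3).astype(int)
    return pd.DataFrame({
        "copy_of_label": label.astype(float),
        "correlated": label + rng.normal(0, 0.5, n),
        "noise": rng.random(n),
    }), label


def test_label_copy_is_selected_first():
    df, label = _mi_frame()
    cols = ["copy_of_label", "correlated", "noise"]
    assert select_features(df, label, n_keep=1, columns=cols) == ["copy_of_label"]


def test_noise_feature_scores_below_correlated_features():
    df, label = _mi_frame()
    assert _mi_binned(df["noise"].to_numpy(), label) < _mi_binned(
        df["correlated"].to_numpy(), label)
    assert select_features(df, label, n_keep=2,
                           columns=["copy_of_label", "correlated", "noise"]) == [
        "copy_of_label", "correlated"]


def test_selection_matches_brute_force_contingency_mi():
    """The selector's ordering equals MI computed from raw contingency tables."""
    df, label = _mi_frame(seed=3)
    cols = list(df.columns)

    def brute(x, y, bins=10):
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
        bx = np.searchsorted(edges, x, side="right")
        mi = 0.0
        n = len(x)
        for b in np.unique(bx):
            for c in np.unique(y):
                pxy = ((bx == b) & (y == c)).sum() / n
                if pxy > 0:
                    mi += pxy * np.log(pxy / ((bx == b).mean() * (y == c).mean()))
        return mi

    for c in cols:
        x = df[c].to_numpy()
        if len(np.unique(x)) > 10:
            assert _mi_binned(x, label) == pytest.approx(brute(x, label), abs=1e-12)


def test_n_keep_equal_to_total_is_identity():
    df, label = _mi_frame()
    cols = list(df.columns)
    assert select_features(df, label, n_keep=3, columns=cols) == cols
    assert select_features(df, label, n_keep=10, columns=cols) == cols  # keep-all, warned


# ---------------------------------------------------------------------------
# normalization


def test_minmax_maps_and_clips():
    train = pd.DataFrame({"f": [0.0, 10.0, 5.0]})
    normed, bounds = normalize_features(train, columns=["f"])
    assert normed["f"].tolist() == [0.0, 1.0, 0.5]
    applied = bounds.transform(pd.DataFrame({"f": [12.0, -3.0]}))
    assert applied["f"].tolist() == [1.0, 0.0]


def test_constant_feature_maps_to_zero():
    df = pd.DataFrame({"f": [4.0, 4.0, 4.0]})
    normed, _ = normalize_features(df, columns=["f"])
    assert (normed["f"] == 0.0).all()


def test_normalization_is_idempotent_on_train_split():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"a": rng.random(50) * 7, "b": rng.normal(size=50)})
    once, _ = normalize_features(df, columns=["a", "b"])
    twice, _ = normalize_features(once, columns=["a", "b"])
    pd.testing.assert_frame_equal(once, twice)
    assert once[["a", "b"]].min().min() >= 0.0
    assert once[["a", "b"]].max().max() <= 1.0
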