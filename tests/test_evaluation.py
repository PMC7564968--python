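import numpy as np
import pandas as pd
import pytest

from invarscope import (InvalidArgumentError, UndefinedValueError,
                        layer_preference_percentages, permutation_threshold,
                        prediction_accuracy, topk_accuracy_comparison,
                        voxel_attribution)


@pytest.mark.parametrize("pred,actual,expected", [
    ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 1.0),
    ((1.0, 2.0, 3.0), (-1.0, -2.0, -3.0), -1.0),
    ((1.0, 2.0, 3.0), (1.0, 2.0, 4.0), 0.9820),  # 3/sqrt(2*42/9)
])
def test_prediction_accuracy_values(pred, actual, expected):
    assert prediction_accuracy(np.array(pred), np.array(actual)) \
        == pytest.approx(expected, abs=5e-5)


def test_prediction_accuracy_degenerate_cases():
    with pytest.raises(UndefinedValueError):
        prediction_accuracy(np.array([1.0, 2.0, 3.0]), np.ones(3))
    assert prediction_accuracy(np.ones(3), np.array([1.0, 2.0, 3.0])) == 0.0
    with pytest.raises(InvalidArgumentError):
        prediction_accuracy(np.ones(2), np.ones(2))


def test_permutation_threshold_properties():
    # median of a symmetric null is ~0
    mid = permutation_threshold(n_test=120, alpha=0.5, n_perm=20000, seed=3)
    assert abs(mid) < 0.02
    # more test images -> tighter null -> lower threshold
    t120 = permutation_threshold(120, 0.001, 20000, seed=4)
    t480 = permutation_threshold(480, 0.001, 20000, seed=4)
    assert t480 < t120
    with pytest.raises(InvalidArgumentError):
        permutation_threshold(2, 0.001, 20000, seed=0)
    with pytest.raises(InvalidArgumentError):
        permutation_threshold(120, 0.001, 500, seed=0)
    with pytest.warns(UserWarning):
        permutation_threshold(120, 0.0001, 20000, seed=0)


def _table(rows):
    return pd.DataFrame(rows, columns=["voxel_id", "roi", "model_kind",
                                       "trained_on", "selected_layer",
                                       "pearson_r"])


def test_layer_preferences_degenerate_histograms():
    tab = _table([(f"v{i}", "V1", "linear", "original", 1, 0.9)
                  for i in range(5)])
    prefs, hist = layer_preference_percentages(tab, {1, 2, 7, 8}, 0.27)
    assert prefs["percent_strong"].iloc[0] == 100.0
    prefs_full, _ = layer_preference_percentages(tab, set(range(1, 9)), 0.27)
    assert prefs_full["percent_strong"].iloc[0] == 100.0
    assert hist["count"].sum() == 5


def test_layer_preferences_missing_roi_reported_as_nan():
    tab = _table([("v0", "V1", "linear", "original", 3, 0.1)])
    prefs, _ = layer_preference_percentages(tab, {1, 2}, threshold=0.27)
    assert prefs["n_accurate"].iloc[0] == 0
    assert np.isnan(prefs["percent_strong"].iloc[0])


def test_layer_preferences_match_direct_tally():
    rng = np.random.default_rng(8)
    layers = rng.integers(1, 9, size=200)
    rs = rng.uniform(-0.2, 0.9, size=200)
    rois = rng.choice(["V1", "LO"], size=200)
    tab = _table(list(zip([f"v{i}" for i in range(200)], rois,
                          ["linear"] * 200, ["original"] * 200, layers, rs)))
    strong = {1, 2, 7, 8}
    prefs, _ = layer_preference_percentages(tab, strong, threshold=0.27)
    for _, row in prefs.iterrows():
        mask = (rois == row["roi"]) & (rs > 0.27)
        expected = 100.0 * np.isin(layers[mask], list(strong)).mean()
        assert row["percent_strong"] == pytest.approx(expected)


def test_topk_identity_and_constant_shift():
    base = _table([(f"v{i}", "V1", "linear", "original", 1, 0.5 + 0.001 * i)
                   for i in range(20)])
    same = topk_accuracy_comparison(base, base, k=10)
    assert same["mean_drop"].iloc[0] == 0.0
    shifted = base.copy()
    shifted["pearson_r"] -= 0.1
    drop = topk_accuracy_comparison(base, shifted, k=10)
    assert drop["mean_drop"].iloc[0] == pytest.approx(0.1)
    assert bool(drop["degenerate"].iloc[0])  # zero-variance difference
    with pytest.raises(InvalidArgumentError):
        topk_accuracy_comparison(base, shifted, k=1)
    with pytest.raises(InvalidArgumentError):
        topk_accuracy_comparison(base, shifted.iloc[:5], k=5)


def _attribution_tables(rs: dict):
    tables = {}
    n = len(next(iter(rs.values())))
    for key, vals in rs.items():
        kind, on = key
        tables[key] = _table([(f"v{i}", "V1" if i < n // 2 else "LO", kind,
                               on, 1, vals[i]) for i in range(n)])
    return tables


def test_attribution_all_below_threshold():
    tabs = _attribution_tables({("linear", "original"): [0.1, 0.2],
                                ("linear", "augmented"): [0.15, 0.1]})
    summary = voxel_attribution(tabs, threshold=0.27)
    assert (summary.two_model["fraction_accurate"] == 0.0).all()
    assert summary.four_model is None


def test_attribution_single_voxel_bookkeeping():
    tabs = _attribution_tables({("linear", "original"): [0.4, 0.0],
                                ("linear", "augmented"): [0.5, 0.0]})
    summary = voxel_attribution(tabs, threshold=0.27)
    v1 = summary.two_model.set_index("roi").loc["V1"]
    assert v1["fraction_better_augmented"] == 1.0  # 1 of the 1 V1 voxel
    assert v1["fraction_better_original"] == 0.0


def test_attribution_matches_bruteforce_and_partitions():
    rng = np.random.default_rng(9)
    n = 120
    rs = {key: rng.uniform(-0.3, 0.9, size=n)
          for key in [("linear", "original"), ("linear", "augmented"),
                      ("tl", "original"), ("tl", "augmented")]}
    tabs = _attribution_tables(rs)
    summary = voxel_attribution(tabs, threshold=0.27)
    # partition identities hold exactly on the integer counts
    tm = summary.two_model
    assert (tm["n_better_original"] + tm["n_better_augmented"]
            == tm["n_accurate"]).all()
    fm = summary.four_model
    count_cols = [c for c in fm.columns if c.startswith("n_best_")]
    assert (fm[count_cols].sum(axis=1) == fm["n_accurate"]).all()
    four_cols = [c for c in fm.columns if c.startswith("fraction_best_")]
    assert np.allclose(fm[four_cols].sum(axis=1), fm["fraction_accurate"],
                       atol=1e-12)
    # brute-force per-voxel argmax oracle (four-model view)
    order = [("linear", "original"), ("linear", "augmented"),
             ("tl", "original"), ("tl", "augmented")]
    rois = np.array(["V1" if i < n // 2 else "LO" for i in range(n)])
    for roi in ("V1", "LO"):
        idx = np.flatnonzero(rois == roi)
        counts = dict.fromkeys(order, 0)
        for i in idx:
            vals = [rs[key][i] for key in order]
            if max(vals) > 0.27:
                counts[order[int(np.argmax(vals))]] += 1
        row = fm.set_index("roi").loc[roi]
        for key in order:
            expected = counts[key] / idx.size
            assert row[f"fraction_best_{key[0]}_{key[1]}"] \
                == pytest.approx(expected, abs=1e-15)


def test_attribution_rejects_mismatched_voxel_sets():
    tabs = _attribution_tables({("linear", "original"): [0.4, 0.0],
                                ("linear", "augmented"): [0.5, 0.0]})
    tabs[("linear", "augmented")] = tabs[("linear", "augmented")].iloc[:1]
    with pytest.raises(InvalidArgumentError):
        voxel_attribution(tabs, threshold=0.27)
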