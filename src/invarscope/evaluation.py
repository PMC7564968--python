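"""Evaluation statistics for encoding-model comparisons.

Covers: per-voxel prediction accuracy (Pearson r on test images), the
permutation-null significance threshold for declaring a voxel "accurately
predicted", layer-preference percentages split by a strong-invariance layer
group, top-K before/after accuracy comparisons with paired t-tests, and the
attribution of accurately predicted voxels to the model that predicts them
best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import EncodingFit
from .errors import InvalidArgumentError, UndefinedValueError
from ._rng import derive_rng

#: Layers whose features stay most similar under augmentation (conv ends,
#: fc tail) — the "strong invariance" group used for preference splits.
STRONG_INVARIANCE_LAYERS = frozenset({1, 2, 7, 8})


def prediction_accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Sample Pearson correlation between predicted and actual responses."""
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    actual = np.asarray(actual, dtype=np.float64).ravel()
    if predicted.size != actual.size:
        raise InvalidArgumentError("length mismatch")
    if predicted.size < 3:
        raise InvalidArgumentError("need at least 3 test images")
    if np.std(actual) == 0:
        raise UndefinedValueError("accuracy undefined for constant actual response")
    if np.std(predicted) == 0:
        return 0.0  # degenerate constant prediction
    r = np.corrcoef(predicted, actual)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def permutation_threshold(n_test: int = 120, alpha: float = 0.001,
                          n_perm: int = 100_000, seed: int = 0) -> float:
    """Permutation-null (1 - alpha) quantile of Pearson r at ``n_test`` images.

    One standard-normal prediction vector is held fixed; the null is built
    from Pearson correlations against ``n_perm`` random permutations of a
    standard-normal response vector. Accuracies above the returned value
    occur with probability ~alpha under the no-association null.
    """
    if n_test < 3:
        raise InvalidArgumentError("n_test must be at least 3")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    if n_perm < 1000:
        raise InvalidArgumentError("need at least 1000 permutations")
    if alpha * n_perm < 10:
        import warnings
        warnings.warn("alpha * n_perm < 10: null quantile is unstable",
                      stacklevel=2)
    rng = derive_rng(seed, "perm-threshold")
    pred = rng.standard_normal(n_test)
    resp = rng.standard_normal(n_test)
    perms = rng.permuted(np.broadcast_to(resp, (n_perm, n_test)).copy(), axis=1)
    pc = (pred - pred.mean()) / pred.std()
    rc = perms - perms.mean(axis=1, keepdims=True)
    rc /= rc.std(axis=1, keepdims=True)
    null_r = rc @ pc / n_test
    return float(np.quantile(null_r, 1.0 - alpha))


def accuracy_table(fit: EncodingFit) -> pd.DataFrame:
    """Long-format per-voxel accuracy rows for one fitted model variant."""
    return pd.DataFrame({
        "voxel_id": fit.voxel_ids,
        "roi": fit.rois,
        "model_kind": fit.model_kind,
        "trained_on": fit.trained_on,
        "selected_layer": fit.selected_layer,
        "pearson_r": fit.accuracy,
    })


def layer_preference_percentages(table: pd.DataFrame,
                                 strong_group: frozenset[int] | set[int]
                                 = STRONG_INVARIANCE_LAYERS,
                                 threshold: float = 0.27,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of accurate voxels whose selected layer is strongly invariant.

    Returns (percentages, histogram): percentages has one row per
    (roi, model_kind, trained_on) with ``percent_strong`` (NaN — reported as
    missing, never 0 — where an ROI has no accurate voxel); histogram counts
    selected layers among accurate voxels.
    """
    if not set(strong_group) <= set(range(1, 9)):
        raise InvalidArgumentError("strong_group must be a subset of layers 1..8")
    accurate = table[table["pearson_r"] > threshold]
    group_cols = ["roi", "model_kind", "trained_on"]
    rows = []
    for keys, sub in table.groupby(group_cols, sort=False):
        acc = accurate[(accurate[group_cols] == keys).all(axis=1)]
        percent = (100.0 * acc["selected_layer"].isin(strong_group).mean()
                   if len(acc) else np.nan)
        rows.append(dict(zip(group_cols, keys),
                         n_accurate=len(acc), percent_strong=percent))
    hist = (accurate.groupby(group_cols + ["selected_layer"])
            .size().rename("count").reset_index())
    return pd.DataFrame(rows), hist


def topk_accuracy_comparison(orig: pd.DataFrame, aug: pd.DataFrame,
                             k: int = 200) -> pd.DataFrame:
    """Top-k (by original-model accuracy, per ROI) before/after comparison.

    Per ROI: mean and variance of both models' accuracies on the top set, the
    mean drop (original - augmented), and a paired two-sided t-test. A
    zero-variance difference is flagged degenerate instead of a t statistic.
    """
    if k < 2:
        raise InvalidArgumentError("k must be at least 2")
    o = orig.set_index("voxel_id")
    a = aug.set_index("voxel_id")
    if set(o.index) != set(a.index):
        raise InvalidArgumentError("voxel universes differ between tables")
    a = a.loc[o.index]
    rows = []
    for roi, sub in o.groupby("roi", sort=False):
        top = sub.sort_values("pearson_r", ascending=False).head(min(k, len(sub)))
        r_o = top["pearson_r"].to_numpy()
        r_a = a.loc[top.index, "pearson_r"].to_numpy()
        diff = r_o - r_a
        degenerate = bool(np.std(diff) == 0)
        if degenerate:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_rel(r_o, r_a)
        rows.append({
            "roi": roi, "n_top": len(top),
            "mean_original": float(r_o.mean()),
            "var_original": float(r_o.var(ddof=1)),
            "mean_augmented": float(r_a.mean()),
            "var_augmented": float(r_a.var(ddof=1)),
            "mean_drop": float(diff.mean()),
            "t_statistic": float(t_stat) if not degenerate else np.nan,
            "p_value": float(p) if not degenerate else np.nan,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


@dataclass
class AttributionSummary:
    """Per-ROI attribution of accurate voxels to their best-predicting model.

    ``two_model`` has one row per (roi, model_kind): the fraction of the
    ROI's voxels accurately predicted by that family (max of original /
    augmented r above threshold) split by which variant predicts better
    (ties to original). ``four_model`` (present only when both families are
    supplied) assigns each accurate voxel to its argmax model among
    (linear, aug-linear, tl, aug-tl), ties broken in that order. All
    fractions are over all voxels of the ROI, so the partition identities
    fraction_better_original + fraction_better_augmented = fraction_accurate
    and sum(four_way) = fraction_accurate hold exactly.
    """

    two_model: pd.DataFrame
    four_model: pd.DataFrame | None


_FOUR_WAY_ORDER = (("linear", "original"), ("linear", "augmented"),
                   ("tl", "original"), ("tl", "augmented"))


def voxel_attribution(tables: dict[tuple[str, str], pd.DataFrame],
                      threshold: float = 0.27) -> AttributionSummary:
    """Attribute accurate voxels to models; see AttributionSummary."""
    if not tables:
        raise InvalidArgumentError("no accuracy tables given")
    ref = next(iter(tables.values()))
    universe = list(ref["voxel_id"])
    rois = ref.set_index("voxel_id")["roi"]
    acc = {}
    for key, tab in tables.items():
        if set(tab["voxel_id"]) != set(universe):
            raise InvalidArgumentError("voxel sets differ across tables")
        acc[key] = tab.set_index("voxel_id")["pearson_r"].loc[universe].to_numpy()
    roi_arr = rois.loc[universe].to_numpy()

    families = sorted({k[0] for k in tables})
    two_rows = []
    for family in families:
        if (family, "original") not in tables or (family, "augmented") not in tables:
            continue
        r_o, r_a = acc[(family, "original")], acc[(family, "augmented")]
        accurate = np.maximum(r_o, r_a) > threshold
        better_aug = accurate & (r_a > r_o)  # ties attributed to original
        for roi in dict.fromkeys(roi_arr):
            mask = roi_arr == roi
            n = int(mask.sum())
            n_acc = int(accurate[mask].sum())
            n_aug = int(better_aug[mask].sum())
            two_rows.append({
                "roi": roi, "model_kind": family, "n_voxels": n,
                "n_accurate": n_acc,
                "n_better_original": n_acc - n_aug,
                "n_better_augmented": n_aug,
                "fraction_accurate": n_acc / n,
                "fraction_better_original": (n_acc - n_aug) / n,
                "fraction_better_augmented": n_aug / n,
            })
    two_model = pd.DataFrame(two_rows)

    four_model = None
    if all(key in tables for key in _FOUR_WAY_ORDER):
        stacked = np.stack([acc[key] for key in _FOUR_WAY_ORDER])
        accurate = stacked.max(axis=0) > threshold
        winner = np.argmax(stacked, axis=0)  # first max -> declared tie order
        four_rows = []
        for roi in dict.fromkeys(roi_arr):
            mask = roi_arr == roi
            n = int(mask.sum())
            row = {"roi": roi, "n_voxels": n,
                   "n_accurate": int(accurate[mask].sum()),
                   "fraction_accurate": float(accurate[mask].sum() / n)}
            for w, key in enumerate(_FOUR_WAY_ORDER):
                n_best = int((accurate & (winner == w))[mask].sum())
                row[f"n_best_{key[0]}_{key[1]}"] = n_best
                row[f"fraction_best_{key[0]}_{key[1]}"] = n_best / n
            four_rows.append(row)
        four_model = pd.DataFrame(four_rows)
    return AttributionSummary(two_model=two_model, four_model=four_model)
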