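"""Voxel-wise encoding models over hierarchical layer features.

Two model families map a layer's (standardized) features to voxel responses:

* ``linear`` — per-voxel L1-penalized least squares ("sparse linear
  regression"), with the penalty chosen per voxel from a grid by Pearson r on
  an inner validation split and the model refit on the full training set;
* ``tl`` — a per-ROI network of two rectified-linear hidden layers trained by
  mini-batch gradient descent on mean-squared error with early stopping (the
  "transfer learning" readout).

One model is fit per extractor layer; per voxel, the layer whose model best
predicts the held-out test responses (Pearson r, ties broken toward the
shallower layer) is selected, replicating the published selection rule.
``selection="validation"`` instead selects on the inner validation split,
avoiding the test set.

Augmented fits train on the augmented library only, every variant labeled
with its original's response; feature standardization statistics always come
from the original training set so model variants share a feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.neural_network import MLPRegressor

from .augmentation import AugmentedStimulusSet
from .errors import InvalidArgumentError, TrainingFailureError
from .features import FeatureExtractor, LayerFeatureMatrix, extract_multi
from .stimuli import StimulusSet
from .voxels import VoxelResponseSet
from ._rng import derive_int_seed, derive_rng


@dataclass
class EncodingConfig:
    model_kind: str = "linear"  # "linear" | "tl"
    penalty_grid: tuple[float, ...] = (0.3, 0.1, 0.03, 0.01)  # descending
    hidden_widths: tuple[int, int] = (64, 32)
    max_epochs: int = 400
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 25
    inner_val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("linear", "tl"):
            raise InvalidArgumentError(f"unknown model_kind {self.model_kind!r}")
        if not self.penalty_grid or any(a <= 0 for a in self.penalty_grid):
            raise InvalidArgumentError("penalty grid must be nonempty and positive")
        if not 0.0 < self.inner_val_fraction < 1.0:
            raise InvalidArgumentError("inner_val_fraction must lie in (0, 1)")


@dataclass
class FeatureScaler:
    """Per-dimension standardization fit on the original training features."""

    mean: np.ndarray
    scale: np.ndarray  # constant columns get scale 1 (centered to zero)

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale


def _pearson_columns(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; constant predictions score 0 (degenerate)."""
    pc = pred - pred.mean(axis=0)
    ac = actual - actual.mean(axis=0)
    ps = np.sqrt((pc**2).sum(axis=0))
    asd = np.sqrt((ac**2).sum(axis=0))
    denom = ps * asd
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * ac).sum(axis=0) / denom
    r[denom == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _inner_split(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed shuffled order under seed; validation = last floor(fraction*n)."""
    order = derive_rng(seed, "inner-split").permutation(n)
    n_val = int(np.floor(fraction * n))
    if n_val < 1 or n_val >= n:
        raise InvalidArgumentError("inner validation split is empty or full")
    return order[: n - n_val], order[n - n_val:]


def _align_responses(features: LayerFeatureMatrix,
                     responses: VoxelResponseSet) -> np.ndarray:
    """(n_images, n_voxels) response block aligned to feature rows by id."""
    return responses.columns_for(features.image_ids).T


@dataclass
class LinearLayerFit:
    layer_index: int
    weights: np.ndarray  # (n_voxels, n_features) in standardized feature space
    intercepts: np.ndarray
    chosen_penalty: np.ndarray
    scaler: FeatureScaler
    degenerate: np.ndarray  # all-constant training response

    def predict(self, features: LayerFeatureMatrix) -> np.ndarray:
        x = self.scaler.transform(features.matrix)
        return x @ self.weights.T + self.intercepts


def fit_linear_layer(features_train: LayerFeatureMatrix,
                     responses_train: VoxelResponseSet | np.ndarray,
                     config: EncodingConfig,
                     scaler: FeatureScaler | None = None) -> LinearLayerFit:
    """L1-penalized per-voxel readout of one layer's features.

    All voxels are fit jointly per penalty (shared Gram matrix); the penalty
    is selected per voxel by Pearson r on the inner validation split and each
    penalty group is refit on the full training set.
    """
    if isinstance(responses_train, VoxelResponseSet):
        y = _align_responses(features_train, responses_train)
    else:
        y = np.asarray(responses_train, dtype=np.float64)
        if y.shape[0] != features_train.matrix.shape[0]:
            raise InvalidArgumentError("responses misaligned with feature rows")
    if scaler is None:
        scaler = FeatureScaler.fit(features_train.matrix)
    x = scaler.transform(features_train.matrix)
    n, n_vox = y.shape[0], y.shape[1]
    degenerate = (y.max(axis=0) - y.min(axis=0)) == 0.0  # exactly constant

    grid = tuple(sorted(config.penalty_grid, reverse=True))
    inner_idx, val_idx = _inner_split(n, config.inner_val_fraction, config.seed)
    xi, yi = x[inner_idx], y[:, :][inner_idx]
    xv, yv = x[val_idx], y[val_idx]

    val_scores = np.full((len(grid), n_vox), -np.inf)
    for g, alpha in enumerate(grid):
        model = Lasso(alpha=alpha, precompute=True, max_iter=2000, tol=1e-3)
        model.fit(xi, yi)
        coef = np.atleast_2d(model.coef_)
        pred = xv @ coef.T + np.atleast_1d(model.intercept_)
        r = _pearson_columns(pred, yv)
        # Constant predictions (everything shrunk away) rank below any real r.
        const = pred.std(axis=0) == 0.0
        r[const] = -np.inf
        val_scores[g] = r

    best = np.argmax(val_scores, axis=0)  # ties -> larger penalty (sparser)
    all_const = ~np.isfinite(val_scores).any(axis=0)
    best[all_const] = 0

    weights = np.zeros((n_vox, x.shape[1]))
    intercepts = np.zeros(n_vox)
    chosen = np.array([grid[g] for g in best])
    for g, alpha in enumerate(grid):
        cols = np.flatnonzero((best == g) & ~degenerate)
        if cols.size == 0:
            continue
        model = Lasso(alpha=alpha, precompute=True, max_iter=2000, tol=1e-3)
        model.fit(x, y[:, cols])
        weights[cols] = np.atleast_2d(model.coef_)
        intercepts[cols] = np.atleast_1d(model.intercept_)
    if not (np.isfinite(weights).all() and np.isfinite(intercepts).all()):
        raise TrainingFailureError(
            f"linear fit produced non-finite parameters at layer "
            f"{features_train.layer_index}")
    return LinearLayerFit(layer_index=features_train.layer_index,
                          weights=weights, intercepts=intercepts,
                          chosen_penalty=chosen, scaler=scaler,
                          degenerate=degenerate)


@dataclass
class TLRoiFit:
    roi: str
    voxel_columns: np.ndarray  # columns of the response block this net maps to
    network: MLPRegressor


@dataclass
class TLLayerFit:
    layer_index: int
    roi_fits: list[TLRoiFit]
    n_voxels: int
    scaler: FeatureScaler

    def predict(self, features: LayerFeatureMatrix) -> np.ndarray:
        x = self.scaler.transform(features.matrix)
        out = np.zeros((x.shape[0], self.n_voxels))
        for rf in self.roi_fits:
            pred = rf.network.predict(x)
            out[:, rf.voxel_columns] = pred.reshape(x.shape[0], -1)
        return out


def fit_tl_layer(features_train: LayerFeatureMatrix,
                 responses_train: VoxelResponseSet | np.ndarray,
                 roi: str | None, config: EncodingConfig,
                 scaler: FeatureScaler | None = None,
                 rois: np.ndarray | None = None) -> TLLayerFit:
    """Two-hidden-layer rectified-linear readout, one shared network per ROI.

    ``roi=None`` fits every ROI present in ``rois`` (or in the response set's
    labels); training is deterministic given the config seed.
    """
    if isinstance(responses_train, VoxelResponseSet):
        y = _align_responses(features_train, responses_train)
        rois = responses_train.rois
    else:
        y = np.asarray(responses_train, dtype=np.float64)
        if rois is None:
            rois = np.array(["all"] * y.shape[1], dtype=object)
    if scaler is None:
        scaler = FeatureScaler.fit(features_train.matrix)
    x = scaler.transform(features_train.matrix)

    roi_names = [roi] if roi is not None else list(dict.fromkeys(rois))
    roi_fits: list[TLRoiFit] = []
    for name in roi_names:
        cols = np.flatnonzero(rois == name)
        if cols.size == 0:
            raise InvalidArgumentError(f"ROI {name!r} has no voxels")
        target = y[:, cols]
        net = MLPRegressor(
            hidden_layer_sizes=tuple(config.hidden_widths),
            activation="relu", solver="adam",
            batch_size=min(config.batch_size, x.shape[0]),
            learning_rate_init=config.learning_rate,
            max_iter=config.max_epochs,
            early_stopping=True,
            validation_fraction=config.inner_val_fraction,
            n_iter_no_change=config.early_stop_patience,
            random_state=derive_int_seed(config.seed, "tl", str(name),
                                         features_train.layer_index),
        )
        target_fit = target.ravel() if target.shape[1] == 1 else target
        net.fit(x, target_fit)
        if not np.isfinite(net.loss_) or not all(
                np.isfinite(c).all() for c in net.coefs_):
            raise TrainingFailureError(
                f"TL training diverged at layer {features_train.layer_index}, "
                f"ROI {name}")
        roi_fits.append(TLRoiFit(roi=str(name), voxel_columns=cols, network=net))
    return TLLayerFit(layer_index=features_train.layer_index, roi_fits=roi_fits,
                      n_voxels=y.shape[1], scaler=scaler)


def select_best_layer(per_layer_fits: dict[int, LinearLayerFit | TLLayerFit],
                      features_test: dict[int, LayerFeatureMatrix],
                      responses_test: VoxelResponseSet | np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per voxel: argmax-r layer over the fitted layers, ties to shallower.

    Returns (selected_layer, accuracy) arrays over voxels; accuracy is the
    Pearson r of the selected layer's model on the test images.
    """
    layers = sorted(per_layer_fits)
    first = features_test[layers[0]]
    if isinstance(responses_test, VoxelResponseSet):
        actual = responses_test.columns_for(first.image_ids).T
    else:
        actual = np.asarray(responses_test, dtype=np.float64)
    if actual.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 test images for Pearson r")
    rs = np.stack([
        _pearson_columns(per_layer_fits[l].predict(features_test[l]), actual)
        for l in layers])
    best = np.argmax(rs, axis=0)  # first occurrence -> shallowest layer
    n_vox = actual.shape[1]
    return np.array(layers)[best], rs[best, np.arange(n_vox)]


@dataclass
class EncodingFit:
    """One fitted model variant (family x training library)."""

    model_kind: str
    trained_on: str  # "original" | "augmented"
    voxel_ids: list[str]
    rois: np.ndarray
    layers: tuple[int, ...]
    per_layer: dict[int, LinearLayerFit | TLLayerFit]
    selected_layer: np.ndarray
    accuracy: np.ndarray
    per_layer_accuracy: np.ndarray = field(default=None)  # (L, V) test r


def _augmented_training_table(augmented: AugmentedStimulusSet,
                              responses: VoxelResponseSet,
                              ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Variant pixels + per-variant copied responses (originals excluded)."""
    pix, ids, cols = [], [], []
    order = {iid: j for j, iid in enumerate(responses.image_ids)}
    for iid, entries in augmented.variants.items():
        if iid not in order:
            raise InvalidArgumentError(
                f"augmented variant's original {iid!r} has no training response")
        for p, rec in entries:
            pix.append(p)
            ids.append(f"{iid}~aug{rec.aug_index}")
            cols.append(order[iid])
    if not pix:
        raise InvalidArgumentError("augmented set has no variants")
    y = responses.data[:, cols].T  # (n_variants, n_voxels)
    return np.stack(pix), ids, y


def fit_encoding_model(extractor: FeatureExtractor, stimuli: StimulusSet,
                       responses: VoxelResponseSet, config: EncodingConfig,
                       augmented: AugmentedStimulusSet | None = None,
                       layers: tuple[int, ...] | None = None,
                       selection: str = "test") -> EncodingFit:
    """Fit one model family across layers and select the best layer per voxel.

    With ``augmented`` given, training rows are the augmented variants only,
    each labeled with its original's response; standardization statistics
    still come from the original training features.
    """
    if layers is None:
        layers = tuple(li.index for li in extractor.layers)
    if selection not in ("test", "validation"):
        raise InvalidArgumentError(f"unknown selection rule {selection!r}")
    train = stimuli.train_set()
    test = stimuli.test_set()
    if len(train) == 0 or len(test) == 0:
        raise InvalidArgumentError("need nonempty train and test splits")

    feats_train = extract_multi(extractor, train.pixels, train.image_ids, layers)
    feats_test = extract_multi(extractor, test.pixels, test.image_ids, layers)
    scalers = {l: FeatureScaler.fit(feats_train[l].matrix) for l in layers}

    if augmented is None:
        fit_feats = feats_train
        fit_y = {l: _align_responses(feats_train[l], responses) for l in layers}
        trained_on = "original"
    else:
        pix, ids, y_aug = _augmented_training_table(augmented, responses)
        aug_feats = extract_multi(extractor, pix, ids, layers)
        fit_feats = aug_feats
        fit_y = {l: y_aug for l in layers}
        trained_on = "augmented"

    per_layer: dict[int, LinearLayerFit | TLLayerFit] = {}
    for l in layers:
        if config.model_kind == "linear":
            per_layer[l] = fit_linear_layer(fit_feats[l], fit_y[l], config,
                                            scaler=scalers[l])
        else:
            per_layer[l] = fit_tl_layer(fit_feats[l], fit_y[l], None, config,
                                        scaler=scalers[l], rois=responses.rois)

    if selection == "test":
        sel_feats, sel_resp = feats_test, responses
    else:
        _, val_idx = _inner_split(len(train), config.inner_val_fraction,
                                  config.seed)
        val_ids = [train.image_ids[i] for i in val_idx]
        sel_feats = {
            l: LayerFeatureMatrix(l, feats_train[l].kind,
                                  feats_train[l].matrix[val_idx], val_ids)
            for l in layers}
        sel_resp = responses
    selected, _sel_r = select_best_layer(per_layer, sel_feats, sel_resp)

    # Test accuracy is always reported on the held-out test images.
    actual_test = responses.columns_for(feats_test[layers[0]].image_ids).T
    rs = np.stack([_pearson_columns(per_layer[l].predict(feats_test[l]),
                                    actual_test) for l in layers])
    layer_pos = {l: i for i, l in enumerate(layers)}
    accuracy = rs[[layer_pos[l] for l in selected], np.arange(rs.shape[1])]
    return EncodingFit(model_kind=config.model_kind, trained_on=trained_on,
                       voxel_ids=list(responses.voxel_ids), rois=responses.rois,
                       layers=tuple(layers), per_layer=per_layer,
                       selected_layer=selected, accuracy=accuracy,
                       per_layer_accuracy=rs)


def fit_augmented(extractor: FeatureExtractor, stimuli: StimulusSet,
                  augmented: AugmentedStimulusSet, responses: VoxelResponseSet,
                  config: EncodingConfig, layers: tuple[int, ...] | None = None,
                  selection: str = "test") -> EncodingFit:
    """Augmented-library fit: label-copied variants, same fit/selection path."""
    return fit_encoding_model(extractor, stimuli, responses, config,
                              augmented=augmented, layers=layers,
                              selection=selection)
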