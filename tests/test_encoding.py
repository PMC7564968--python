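import numpy as np
import pytest

from invarscope import (EncodingConfig, InvalidArgumentError, fit_augmented,
                        fit_encoding_model, fit_linear_layer, fit_tl_layer,
                        generate_voxels, select_best_layer)
from invarscope.encoding import FeatureScaler, _inner_split
from invarscope.features import LayerFeatureMatrix, extract_multi
from tests.conftest import identity_augmented


@pytest.fixture(scope="module")
def linear_dataset(toy_extractor, encoding_stimuli):
    """Equivariant (pure linear-readout) voxels, low noise."""
    return generate_voxels(toy_extractor, encoding_stimuli, n_per_roi=4,
                           invariant_fraction=0.0, sparsity=5, noise_sd=0.0,
                           ensemble_k=2, seed=21)


@pytest.fixture(scope="module")
def lin_config():
    return EncodingConfig(model_kind="linear", seed=5)


def test_noiseless_recovery_is_near_perfect(toy_extractor, encoding_stimuli,
                                            linear_dataset, lin_config):
    fit = fit_encoding_model(toy_extractor, encoding_stimuli,
                             linear_dataset.responses, lin_config)
    assert np.all(fit.accuracy >= 0.999)
    true_layer = np.array([s.assigned_layer for s in linear_dataset.voxel_specs])
    assert (fit.selected_layer == true_layer).mean() >= 0.8


def test_permuted_responses_score_near_zero(toy_extractor, encoding_stimuli,
                                            lin_config):
    ds = generate_voxels(toy_extractor, encoding_stimuli, n_per_roi=10,
                         invariant_fraction=0.0, sparsity=5, noise_sd=0.0,
                         ensemble_k=2, seed=22)
    rng = np.random.default_rng(0)
    shuffled = ds.responses
    shuffled.data = rng.permuted(shuffled.data, axis=1)
    fit = fit_encoding_model(toy_extractor, encoding_stimuli, shuffled,
                             lin_config, layers=(3,))
    assert abs(fit.accuracy.mean()) < 0.05


def test_constant_feature_columns_get_zero_weight(lin_config):
    rng = np.random.default_rng(1)
    x = rng.normal(size=(60, 10))
    x[:, 3] = 2.5  # constant column
    y = (x[:, :2] @ np.array([1.0, -1.0]))[:, None]
    feats = LayerFeatureMatrix(1, "conv", x, [f"i{k}" for k in range(60)])
    fit = fit_linear_layer(feats, y, lin_config)
    assert fit.weights[0, 3] == 0.0


def test_predictions_affine_in_features(lin_config):
    """Doubling a feature column while halving its weight (and adjusting the
    scaler) leaves predictions unchanged."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=(50, 6))
    y = (x @ rng.normal(size=6))[:, None]
    feats = LayerFeatureMatrix(1, "conv", x, [f"i{k}" for k in range(50)])
    fit = fit_linear_layer(feats, y, lin_config)
    pred = fit.predict(feats)
    x2 = x.copy()
    x2[:, 0] *= 2.0
    fit.scaler.mean[0] *= 2.0
    fit.scaler.scale[0] *= 2.0
    pred2 = fit.predict(LayerFeatureMatrix(1, "conv", x2,
                                           [f"i{k}" for k in range(50)]))
    assert np.allclose(pred, pred2, atol=1e-12)


def test_degenerate_constant_voxel_flagged(lin_config):
    rng = np.random.default_rng(3)
    x = rng.normal(size=(40, 5))
    y = np.column_stack([x[:, 0], np.full(40, 1.7)])
    feats = LayerFeatureMatrix(1, "conv", x, [f"i{k}" for k in range(40)])
    fit = fit_linear_layer(feats, y, lin_config)
    assert fit.degenerate.tolist() == [False, True]
    assert np.all(fit.weights[1] == 0.0)


def test_select_best_layer_tiebreak_and_consistency(lin_config):
    rng = np.random.default_rng(4)
    n = 20
    ids = [f"i{k}" for k in range(n)]
    actual = rng.normal(size=(n, 2))

    class _ConstFit:
        def predict(self, features):
            return np.ones((features.matrix.shape[0], 2))

    feats = {l: LayerFeatureMatrix(l, "conv", rng.normal(size=(n, 3)), ids)
             for l in (1, 2, 3)}
    sel, acc = select_best_layer({l: _ConstFit() for l in (1, 2, 3)},
                                 feats, actual)
    assert np.all(sel == 1)  # exact ties resolve to the shallowest layer
    assert np.all(acc == 0.0)  # constant predictions are degenerate
    with pytest.raises(InvalidArgumentError):
        short = {l: LayerFeatureMatrix(l, "conv", rng.normal(size=(2, 3)),
                                       ["a", "b"]) for l in (1, 2, 3)}
        select_best_layer({l: _ConstFit() for l in (1, 2, 3)}, short,
                          actual[:2])


def test_misaligned_image_ids_rejected(toy_extractor, encoding_stimuli,
                                       linear_dataset, lin_config):
    feats = extract_multi(toy_extractor, encoding_stimuli.pixels[:10],
                          ["bogus_%d" % k for k in range(10)], (1,))[1]
    with pytest.raises(InvalidArgumentError):
        fit_linear_layer(feats, linear_dataset.responses, lin_config)


def test_identity_augmented_fit_equals_original(toy_extractor,
                                                encoding_stimuli,
                                                linear_dataset, lin_config):
    """n_aug=1 with identity transforms trains on identical data."""
    augmented = identity_augmented(encoding_stimuli)
    orig = fit_encoding_model(toy_extractor, encoding_stimuli,
                              linear_dataset.responses, lin_config,
                              layers=(4,))
    aug = fit_augmented(toy_extractor, encoding_stimuli, augmented,
                        linear_dataset.responses, lin_config, layers=(4,))
    assert aug.trained_on == "augmented"
    assert np.max(np.abs(orig.accuracy - aug.accuracy)) < 1e-6


def test_augmented_design_row_count(toy_extractor, small_stimuli, lin_config):
    from invarscope import augment_library
    from invarscope.encoding import _augmented_training_table
    ds = generate_voxels(toy_extractor, small_stimuli, n_per_roi=2,
                         invariant_fraction=0.0, sparsity=3, noise_sd=0.0,
                         ensemble_k=2, seed=9)
    lib = augment_library(small_stimuli, n_aug=3, seed=10)
    pix, ids, y = _augmented_training_table(lib, ds.responses)
    n_train = len(small_stimuli.train_set())
    assert pix.shape[0] == len(ids) == y.shape[0] == n_train * 3


def test_inner_split_is_fixed_shuffle(lin_config):
    tr, val = _inner_split(10, 0.2, seed=5)
    tr2, val2 = _inner_split(10, 0.2, seed=5)
    assert np.array_equal(tr, tr2) and np.array_equal(val, val2)
    assert len(val) == 2 and len(set(tr) | set(val)) == 10


# -- TL (two-hidden-layer nonlinear readout) -------------------------------


@pytest.fixture(scope="module")
def tl_config():
    return EncodingConfig(model_kind="tl", hidden_widths=(192, 96),
                          max_epochs=1000, learning_rate=2e-3,
                          early_stop_patience=80, seed=5)


def test_tl_close_to_linear_on_linear_voxels(toy_extractor, encoding_stimuli,
                                             tl_config, lin_config):
    """On purely linear voxels the nonlinear readout should approach the
    linear model (its hidden layers can embed an identity map)."""
    ds = generate_voxels(toy_extractor, encoding_stimuli, n_per_roi=8,
                         layer_map={"A": {8: 1.0}}, invariant_fraction=0.0,
                         sparsity=5, noise_sd=0.05, ensemble_k=2, seed=42)
    flin = fit_encoding_model(toy_extractor, encoding_stimuli, ds.responses,
                              lin_config, layers=(8,))
    ftl = fit_encoding_model(toy_extractor, encoding_stimuli, ds.responses,
                             tl_config, layers=(8,))
    assert np.max(flin.accuracy - ftl.accuracy) < 0.05


def test_tl_determinism(toy_extractor, encoding_stimuli, tl_config):
    ds = generate_voxels(toy_extractor, encoding_stimuli, n_per_roi=3,
                         layer_map={"A": {7: 1.0}}, invariant_fraction=0.0,
                         sparsity=4, noise_sd=0.1, ensemble_k=2, seed=43)
    feats = extract_multi(toy_extractor,
                          encoding_stimuli.train_set().pixels,
                          encoding_stimuli.train_set().image_ids, (7,))[7]
    a = fit_tl_layer(feats, ds.responses, None, tl_config)
    b = fit_tl_layer(feats, ds.responses, None, tl_config)
    for ca, cb in zip(a.roi_fits[0].network.coefs_, b.roi_fits[0].network.coefs_):
        assert np.array_equal(ca, cb)


def test_tl_single_voxel_roi(toy_extractor, encoding_stimuli, tl_config):
    ds = generate_voxels(toy_extractor, encoding_stimuli, n_per_roi=1,
                         layer_map={"solo": {8: 1.0}}, invariant_fraction=0.0,
                         sparsity=3, noise_sd=0.1, ensemble_k=2, seed=44)
    feats = extract_multi(toy_extractor,
                          encoding_stimuli.train_set().pixels,
                          encoding_stimuli.train_set().image_ids, (8,))[8]
    fit = fit_tl_layer(feats, ds.responses, None, tl_config)
    pred = fit.predict(feats)
    assert pred.shape == (feats.matrix.shape[0], 1)
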