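import numpy as np
import pytest

from invarscope import InvalidArgumentError, generate_voxels
from invarscope.features import extract_multi
from invarscope.voxels import _ensemble_mean_features
from invarscope._rng import derive_int_seed


@pytest.fixture(scope="module")
def dataset(toy_extractor, small_stimuli):
    return generate_voxels(toy_extractor, small_stimuli, n_per_roi=4,
                           invariant_fraction=0.5, sparsity=5, noise_sd=0.1,
                           ensemble_k=3, seed=13)


def test_shapes_and_roi_labels(dataset, small_stimuli):
    resp = dataset.responses
    assert resp.data.shape == (len(dataset.voxel_specs), len(small_stimuli))
    assert list(resp.image_ids) == list(small_stimuli.image_ids)
    assert len(dataset.voxel_specs) == 5 * 4
    for spec in dataset.voxel_specs:
        assert spec.weight_values.size >= 1
        assert 1 <= spec.assigned_layer <= 8


def test_invariant_count_follows_rounding_rule(toy_extractor, small_stimuli):
    ds = generate_voxels(toy_extractor, small_stimuli, n_per_roi=4,
                         invariant_fraction=0.5, sparsity=3, noise_sd=0.0,
                         ensemble_k=2, seed=3)
    by_roi = {}
    for spec in ds.voxel_specs:
        by_roi.setdefault(spec.roi, []).append(spec.invariance_class)
    for roi, classes in by_roi.items():
        assert classes.count("invariant") == 2  # ceil(0.5 * 4)
        # deterministic rule: the first drawn voxels are the invariant ones
        assert classes == ["invariant", "invariant", "equivariant",
                           "equivariant"]


def test_seed_determinism(toy_extractor, small_stimuli):
    a = generate_voxels(toy_extractor, small_stimuli, n_per_roi=2,
                        invariant_fraction=0.5, sparsity=3, noise_sd=0.2,
                        ensemble_k=2, seed=5)
    b = generate_voxels(toy_extractor, small_stimuli, n_per_roi=2,
                        invariant_fraction=0.5, sparsity=3, noise_sd=0.2,
                        ensemble_k=2, seed=5)
    assert np.array_equal(a.responses.data, b.responses.data)


def test_zero_noise_equivariant_matches_stored_readout(toy_extractor,
                                                       small_stimuli):
    ds = generate_voxels(toy_extractor, small_stimuli, n_per_roi=3,
                         invariant_fraction=0.0, sparsity=4, noise_sd=0.0,
                         ensemble_k=2, seed=8)
    layers = tuple(sorted({s.assigned_layer for s in ds.voxel_specs}))
    feats = extract_multi(toy_extractor, small_stimuli.pixels,
                          small_stimuli.image_ids, layers)
    for i, spec in enumerate(ds.voxel_specs):
        readout = feats[spec.assigned_layer].matrix[:, spec.weight_indices] \
            @ spec.weight_values
        r = np.corrcoef(ds.responses.data[i], readout)[0, 1]
        assert r > 1.0 - 1e-10


def test_zero_noise_invariant_matches_ensemble_readout(toy_extractor,
                                                       small_stimuli):
    """An invariant voxel's noiseless response is its readout of the
    ensemble-averaged features, identical for all variants by construction."""
    seed = 8
    ds = generate_voxels(toy_extractor, small_stimuli, n_per_roi=2,
                         invariant_fraction=1.0, sparsity=4, noise_sd=0.0,
                         ensemble_k=3, seed=seed)
    layers = tuple(sorted({s.assigned_layer for s in ds.voxel_specs}))
    averaged = _ensemble_mean_features(
        toy_extractor, small_stimuli, layers, ensemble_k=3,
        seed=derive_int_seed(seed, "ens-seed"))
    for i, spec in enumerate(ds.voxel_specs):
        readout = averaged[spec.assigned_layer][:, spec.weight_indices] \
            @ spec.weight_values
        r = np.corrcoef(ds.responses.data[i], readout)[0, 1]
        assert r > 1.0 - 1e-10


def test_train_split_standardization(dataset, small_stimuli):
    train = small_stimuli.splits == "train"
    data = dataset.responses.data
    assert np.allclose(data[:, train].mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(data[:, train].std(axis=1), 1.0, atol=1e-9)


def test_invalid_arguments(toy_extractor, small_stimuli):
    with pytest.raises(InvalidArgumentError):
        generate_voxels(toy_extractor, small_stimuli,
                        layer_map={"V1": {9: 1.0}}, seed=0)
    with pytest.raises(InvalidArgumentError):
        generate_voxels(toy_extractor, small_stimuli, sparsity=0, seed=0)
    with pytest.raises(InvalidArgumentError):
        generate_voxels(toy_extractor, small_stimuli, noise_sd=-0.1, seed=0)
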