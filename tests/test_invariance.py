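import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invarscope import (InvalidArgumentError, UndefinedValueError,
                        conv_fc_trend_report, cosine_similarity,
                        layer_similarity_profile, mann_kendall_trend)
from invarscope.invariance import SimilarityDistribution
from tests.conftest import brute_force_mk_s, identity_augmented


@pytest.mark.parametrize("a,b,expected", [
    ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 1.0),
    ((1.0, 0.0), (0.0, 1.0), 0.0),
    ((1.0, 2.0, 2.0), (2.0, 1.0, 2.0), 8.0 / 9.0),
])
def test_cosine_similarity_values(a, b, expected):
    assert cosine_similarity(np.array(a), np.array(b)) == pytest.approx(
        expected, abs=1e-12)


def test_cosine_similarity_errors():
    with pytest.raises(UndefinedValueError):
        cosine_similarity(np.zeros(3), np.ones(3))
    with pytest.raises(InvalidArgumentError):
        cosine_similarity(np.ones(3), np.ones(4))


@pytest.mark.parametrize("seq,expected_s,direction", [
    ([1, 2, 3, 4, 5], 10, "increasing"),
    ([5, 4, 3, 2, 1], -10, "decreasing"),
    ([2, 2, 2, 2], 0, "none"),
])
def test_mann_kendall_examples(seq, expected_s, direction):
    res = mann_kendall_trend(seq)
    assert res.S == expected_s
    assert res.direction == direction
    assert 0.0 <= res.p_two_sided <= 1.0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=3), min_size=3, max_size=9))
def test_mann_kendall_matches_bruteforce_oracle(seq):
    res = mann_kendall_trend(seq)
    assert res.S == brute_force_mk_s(seq)
    assert abs(res.S) <= len(seq) * (len(seq) - 1) // 2


def test_mann_kendall_too_short():
    with pytest.raises(InvalidArgumentError):
        mann_kendall_trend([1.0, 2.0])


def _fake_profiles(means):
    return [SimilarityDistribution(layer_index=i + 1,
                                   kind="conv" if i < 5 else "fc",
                                   per_image_means=np.full(4, m))
            for i, m in enumerate(means)]


def test_conv_fc_trend_report_directions():
    falling_then_rising = [0.9, 0.8, 0.7, 0.6, 0.5, 0.7, 0.8, 0.9]
    trends = conv_fc_trend_report(_fake_profiles(falling_then_rising),
                                  fc_layers=(6, 7, 8))
    assert trends["conv"].direction == "decreasing"
    assert trends["fc"].direction == "increasing"
    flat = conv_fc_trend_report(_fake_profiles([0.5] * 8))
    assert flat["conv"].direction == "none" and flat["fc"].direction == "none"
    with pytest.raises(InvalidArgumentError):
        conv_fc_trend_report(_fake_profiles([0.5] * 4))


def test_identity_variants_give_similarity_one(toy_extractor, small_stimuli):
    augmented = identity_augmented(small_stimuli)
    profiles = layer_similarity_profile(toy_extractor, small_stimuli, augmented)
    for p in profiles:
        assert np.allclose(p.per_image_means, 1.0, atol=1e-12)


def test_profile_shape_and_rectified_range(toy_extractor, small_stimuli,
                                           small_augmented):
    profiles = layer_similarity_profile(toy_extractor, small_stimuli,
                                        small_augmented)
    n_train = len(small_stimuli.train_set())
    assert len(profiles) == toy_extractor.n_layers
    for p in profiles:
        assert p.per_image_means.shape == (n_train,)
        # rectified features are nonnegative, so similarities sit in [0, 1]
        assert np.all(p.per_image_means >= 0.0)
        assert np.all(p.per_image_means <= 1.0)
        q1, q3 = p.quartiles
        assert q1 <= p.median <= q3


def test_matched_exceeds_mismatched_pairing(toy_extractor, small_stimuli,
                                            small_augmented):
    matched = layer_similarity_profile(toy_extractor, small_stimuli,
                                       small_augmented, matched=True)
    crossed = layer_similarity_profile(toy_extractor, small_stimuli,
                                       small_augmented, matched=False)
    # Strictness is asserted over the convolutional layers; at the deepest
    # fully connected stages of the frozen random extractor all images
    # collapse onto a dominant direction and the two pairings nearly tie.
    for pm, pc in zip(matched, crossed):
        if pm.kind == "conv":
            assert pm.mean > pc.mean
    assert matched[0].mean > crossed[0].mean + 1e-3  # layer 1, frozen margin
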