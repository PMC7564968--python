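import numpy as np
import pytest

from invarscope import (augment_library, build_toy_extractor,
                        generate_stimuli)

# Desk-scale extractor shared across tests: 32x32 input keeps every layer's
# feature dimension at or below 1024 so fits run in seconds.
EX_SIZE = 32
EX_CONV = (4, 6, 8, 8, 8)
EX_FC = (64, 48, 32)


@pytest.fixture(scope="session")
def toy_extractor():
    return build_toy_extractor(EX_SIZE, EX_CONV, EX_FC, seed=7)


@pytest.fixture(scope="session")
def small_stimuli():
    return generate_stimuli(12, 4, EX_SIZE, seed=1)


@pytest.fixture(scope="session")
def small_augmented(small_stimuli):
    return augment_library(small_stimuli, n_aug=4, seed=2)


@pytest.fixture(scope="session")
def encoding_stimuli():
    """Mid-size stimulus set shared by the slower encoding tests."""
    return generate_stimuli(150, 30, EX_SIZE, seed=11)


def identity_augmented(stimuli, split="train"):
    """An AugmentedStimulusSet whose single variant per image is the original."""
    from invarscope.augmentation import (AugmentationRecord,
                                         AugmentedStimulusSet)
    subset = stimuli.subset(split)
    size = subset.image_size
    variants = {}
    for i, iid in enumerate(subset.image_ids):
        rec = AugmentationRecord(original_id=iid, aug_index=0,
                                 crop_box=(0, 0, size, size),
                                 flip_mode="none", rng_seed=0)
        variants[iid] = [(subset.pixels[i].copy(), rec)]
    return AugmentedStimulusSet(originals=subset, variants=variants)


def brute_force_mk_s(seq) -> int:
    """O(n^2) pair-count oracle for the Mann-Kendall S statistic."""
    seq = np.asarray(seq, dtype=float)
    s = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            s += int(np.sign(seq[j] - seq[i]))
    return s
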