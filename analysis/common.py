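"""Shared study conditions and paths for the numbered analysis scripts.

The analysis runs at desk scale: 400 training / 60 test images at 32x32,
an 8-layer frozen extractor whose feature dimensions stay at or below 1024,
five ventral-stream ROIs of 40 synthetic voxels each, and an invariant-voxel
fraction rising from 0.2 (V1) to 0.8 (LO). Every script derives its
randomness from SEED.
"""

from pathlib import Path

from invarscope import EncodingConfig, build_toy_extractor
from invarscope._rng import derive_int_seed

SEED = 7

RESULTS = Path(__file__).resolve().parent.parent / "results"
# Bulky intermediates (image libraries, HDF5 matrices) live outside the
# tracked tree; only small summary tables go under results/.
DATA = Path(__file__).resolve().parent.parent / "scratch" / "analysis_data"

# stimulus library (desk-scale stand-in for 1750/120 at 128x128+)
N_TRAIN, N_TEST, IMAGE_SIZE = 400, 60, 32

# frozen extractor: 5 conv + 3 fc
CONV_WIDTHS = (4, 6, 8, 8, 8)
FC_WIDTHS = (64, 48, 32)

# augmentation
N_AUG = 10

# synthetic voxels
ROI_ORDER = ("V1", "V2", "V3", "V4", "LO")
INVARIANT_FRACTIONS = dict(zip(ROI_ORDER, (0.2, 0.35, 0.5, 0.65, 0.8)))
N_PER_ROI = 40
SPARSITY = 10
NOISE_SD = 0.2
ENSEMBLE_K = 10

# evaluation
ALPHA = 0.001
N_PERM = 100_000
TOP_K = 200
STRONG_GROUP = frozenset({1, 2, 7, 8})

LINEAR_CONFIG = EncodingConfig(model_kind="linear", seed=SEED)
TL_CONFIG = EncodingConfig(model_kind="tl", hidden_widths=(64, 32),
                           max_epochs=200, batch_size=128,
                           learning_rate=2e-3, early_stop_patience=15,
                           seed=SEED)


def extractor():
    return build_toy_extractor(IMAGE_SIZE, CONV_WIDTHS, FC_WIDTHS,
                               seed=derive_int_seed(SEED, "extractor"))
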