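"""Generate the synthetic stimulus library and voxel populations.

Writes stimuli (PNG + sidecar) and voxel responses with ground truth
(HDF5 + CSV) under results/data/ and prints the population composition.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from invarscope import generate_stimuli, generate_voxels
from invarscope import io as iomod
from invarscope._rng import derive_int_seed


def main() -> None:
    stimuli = generate_stimuli(common.N_TRAIN, common.N_TEST,
                               common.IMAGE_SIZE,
                               seed=derive_int_seed(common.SEED, "stimuli"))
    print(f"stimuli: {len(stimuli.train_set())} train / "
          f"{len(stimuli.test_set())} test at "
          f"{common.IMAGE_SIZE}x{common.IMAGE_SIZE}")

    dataset = generate_voxels(
        common.extractor(), stimuli, n_per_roi=common.N_PER_ROI,
        invariant_fraction=common.INVARIANT_FRACTIONS,
        sparsity=common.SPARSITY, noise_sd=common.NOISE_SD,
        ensemble_k=common.ENSEMBLE_K,
        seed=derive_int_seed(common.SEED, "voxels"))

    by_roi = Counter((s.roi, s.invariance_class) for s in dataset.voxel_specs)
    print(f"voxels: {len(dataset.voxel_specs)} total, "
          f"noise sd {common.NOISE_SD} (relative to unit signal)")
    for roi in common.ROI_ORDER:
        inv = by_roi[(roi, "invariant")]
        eq = by_roi[(roi, "equivariant")]
        print(f"  {roi}: {inv} invariant + {eq} equivariant "
              f"(invariant fraction {common.INVARIANT_FRACTIONS[roi]:.2f})")

    iomod.write_stimuli(stimuli, common.DATA / "stimuli")
    iomod.write_responses(dataset.responses, common.DATA / "responses.h5",
                          voxel_specs=dataset.voxel_specs)
    iomod.write_responses_csv(dataset.responses, common.DATA / "responses.csv")
    print(f"wrote {common.DATA}/stimuli, responses.h5, responses.csv")


if __name__ == "__main__":
    main()
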