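"""Build the augmented training library: 10 crop-rescale-flip variants per
training image, every crop preserving the main body. Writes variant PNGs and
the transform manifest under results/data/augmented/."""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from invarscope import augment_library
from invarscope import io as iomod
from invarscope._rng import derive_int_seed


def main() -> None:
    stimuli = iomod.read_stimuli(common.DATA / "stimuli")
    library = augment_library(stimuli, n_aug=common.N_AUG,
                              seed=derive_int_seed(common.SEED, "augment"))
    n_train = len(stimuli.train_set())
    print(f"augmented library: {n_train} originals x {common.N_AUG} = "
          f"{library.n_variants} variants")
    flips = Counter(rec.flip_mode for rec in library.records())
    total = sum(flips.values())
    print("flip mix: " + ", ".join(f"{m}={flips[m]/total:.3f}"
                                   for m in ("none", "horizontal",
                                             "vertical", "both")))
    iomod.write_augmented(library, common.DATA / "augmented")
    print(f"wrote {common.DATA}/augmented (PNGs + manifest.csv)")


if __name__ == "__main__":
    main()
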