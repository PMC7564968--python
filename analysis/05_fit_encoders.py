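"""Fit the four encoding-model variants (linear / TL x original / augmented).

Each variant fits one model per extractor layer and selects, per voxel, the
layer whose model best predicts the held-out test responses. Augmented
variants train on the label-copied augmented library only. Writes per-voxel
accuracy tables to results/accuracy_<model>_<library>.csv."""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from invarscope import fit_encoding_model
from invarscope import io as iomod
from invarscope.evaluation import accuracy_table


def main() -> None:
    stimuli = iomod.read_stimuli(common.DATA / "stimuli")
    responses = iomod.read_responses(common.DATA / "responses.h5")
    library = iomod.read_augmented(common.DATA / "augmented",
                                   stimuli.train_set())
    extractor = common.extractor()
    common.RESULTS.mkdir(parents=True, exist_ok=True)

    variants = [("linear", common.LINEAR_CONFIG, None),
                ("linear", common.LINEAR_CONFIG, library),
                ("tl", common.TL_CONFIG, None),
                ("tl", common.TL_CONFIG, library)]
    for kind, config, augmented in variants:
        trained_on = "original" if augmented is None else "augmented"
        t0 = time.perf_counter()
        fit = fit_encoding_model(extractor, stimuli, responses, config,
                                 augmented=augmented)
        table = accuracy_table(fit)
        name = f"accuracy_{kind}_{trained_on}.csv"
        table.to_csv(common.RESULTS / name, index=False)
        by_roi = table.groupby("roi")["pearson_r"].mean()
        summary = ", ".join(f"{roi}={by_roi[roi]:.3f}"
                            for roi in common.ROI_ORDER)
        print(f"{kind}/{trained_on}: mean test r by ROI: {summary} "
              f"({time.perf_counter() - t0:.0f}s) -> {name}")


if __name__ == "__main__":
    main()
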