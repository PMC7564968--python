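"""Extract the frozen 8-layer feature hierarchy for the original stimuli and
persist it to results/data/features.h5."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from invarscope import extract_multi
from invarscope import io as iomod


def main() -> None:
    stimuli = iomod.read_stimuli(common.DATA / "stimuli")
    extractor = common.extractor()
    feats = extract_multi(extractor, stimuli.pixels, stimuli.image_ids)
    for li in extractor.layers:
        print(f"layer {li.index} ({li.kind}): "
              f"{feats[li.index].matrix.shape[0]} images x "
              f"{li.output_dim} features")
    iomod.write_features(feats, common.DATA / "features.h5")
    print(f"wrote {common.DATA}/features.h5")


if __name__ == "__main__":
    main()
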