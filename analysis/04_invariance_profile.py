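"""Layer-wise representation-invariance profile of the frozen extractor.

For each layer, the cosine similarity between each original's features and
its 10 augmented variants' features is averaged per image; the layer trend
is tested with the Mann-Kendall statistic over the conv prefix and the fc
suffix. Writes results/invariance_report.csv."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from invarscope import conv_fc_trend_report, layer_similarity_profile
from invarscope import io as iomod


def main() -> None:
    stimuli = iomod.read_stimuli(common.DATA / "stimuli")
    library = iomod.read_augmented(common.DATA / "augmented",
                                   stimuli.train_set())
    extractor = common.extractor()
    profiles = layer_similarity_profile(extractor, stimuli, library)
    trends = conv_fc_trend_report(profiles)

    rows = []
    for p in profiles:
        q1, q3 = p.quartiles
        rows.append({"layer": p.layer_index, "kind": p.kind, "mean": p.mean,
                     "median": p.median, "q1": q1, "q3": q3})
        print(f"layer {p.layer_index} ({p.kind}): mean similarity "
              f"{p.mean:.4f} [q1 {q1:.4f}, q3 {q3:.4f}]")
    for name, tr in trends.items():
        print(f"{name} trend: S={tr.S:+d}, z={tr.z:.2f}, "
              f"p={tr.p_two_sided:.3f}, direction={tr.direction}")
    df = pd.DataFrame(rows)
    for name, tr in trends.items():
        df[f"MK_S_{name}"] = tr.S
        df[f"MK_p_{name}"] = tr.p_two_sided
        df[f"direction_{name}"] = tr.direction
    common.RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(common.RESULTS / "invariance_report.csv", index=False)
    print(f"wrote {common.RESULTS}/invariance_report.csv")


if __name__ == "__main__":
    main()
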