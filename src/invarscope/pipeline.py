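"""End-to-end pipeline driver with digest-based resume.

Stages: simulate -> augment -> extract -> invariance -> encode (original and
augmented, per enabled model family) -> evaluate. Every stage reads its
inputs from and writes its outputs to the run directory, records SHA-256
digests in a manifest, and is skipped on rerun when its recorded outputs are
intact and nothing upstream was recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .augmentation import augment_library
from .encoding import EncodingConfig, fit_encoding_model
from .errors import InvarscopeError
from .evaluation import (accuracy_table, layer_preference_percentages,
                         permutation_threshold, topk_accuracy_comparison,
                         voxel_attribution)
from .features import build_toy_extractor, extract_multi
from .invariance import conv_fc_trend_report, layer_similarity_profile
from .stimuli import generate_stimuli
from .voxels import generate_voxels
from ._rng import derive_int_seed


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; YAML-serializable."""

    seed: int = 0
    out_dir: str = "runs/default"
    # stimuli
    n_train: int = 400
    n_test: int = 60
    image_size: int = 32
    # extractor (desk-scale frozen CNN)
    channel_widths: tuple[int, ...] = (4, 6, 8, 8, 8)
    fc_widths: tuple[int, int, int] = (64, 48, 32)
    # augmentation
    n_aug: int = 10
    # synthetic voxels
    n_per_roi: int = 40
    layer_map: dict[str, dict[int, float]] | None = None
    invariant_fraction: float | dict[str, float] = 0.5
    sparsity: int = 10
    noise_sd: float = 0.2
    ensemble_k: int = 10
    # encoding
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    include_tl: bool = False
    tl_encoding: EncodingConfig = field(
        default_factory=lambda: EncodingConfig(model_kind="tl"))
    selection: str = "test"
    # evaluation
    alpha: float = 0.001
    n_perm: int = 100_000
    top_k: int = 200
    strong_group: tuple[int, ...] = (1, 2, 7, 8)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text)
        raw["channel_widths"] = tuple(raw["channel_widths"])
        raw["fc_widths"] = tuple(raw["fc_widths"])
        raw["strong_group"] = tuple(raw["strong_group"])
        for key in ("encoding", "tl_encoding"):
            sub = raw[key]
            sub["penalty_grid"] = tuple(sub["penalty_grid"])
            sub["hidden_widths"] = tuple(sub["hidden_widths"])
            raw[key] = EncodingConfig(**sub)
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict]
    versions: dict[str, str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "versions": self.versions}, indent=1, default=str))
        tmp.replace(path)  # atomic on POSIX


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_digest(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()


class _Runner:
    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = {}
        if self.manifest_path.exists():
            old = json.loads(self.manifest_path.read_text())
            if old.get("config_digest") == _config_digest(config):
                self.previous = old.get("stages", {})
        self.stages: dict[str, dict] = {}
        self.dirty = False  # set once any stage actually runs

    def _outputs_intact(self, name: str) -> bool:
        record = self.previous.get(name)
        if record is None:
            return False
        for rel, digest in record["outputs"].items():
            path = self.out / rel
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def run_stage(self, name: str, fn, outputs: list[str]) -> None:
        if not self.dirty and self._outputs_intact(name):
            record = dict(self.previous[name])
            record["skipped"] = True
            self.stages[name] = record
            return
        start = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            (self.out / f"FAILED_{name}").write_text(str(exc))
            raise InvarscopeError(f"stage {name!r} failed: {exc}") from exc
        wall = time.perf_counter() - start
        self.stages[name] = {
            "outputs": {rel: _sha256(self.out / rel) for rel in outputs},
            "wall_s": round(wall, 3), "skipped": False,
        }
        self.dirty = True


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest (also written to
    ``<out_dir>/manifest.json``)."""
    c = config
    runner = _Runner(c)
    out = runner.out
    extractor = build_toy_extractor(c.image_size, tuple(c.channel_widths),
                                    tuple(c.fc_widths),
                                    seed=derive_int_seed(c.seed, "extractor"))
    layers = tuple(li.index for li in extractor.layers)

    def simulate() -> None:
        stimuli = generate_stimuli(c.n_train, c.n_test, c.image_size,
                                   seed=derive_int_seed(c.seed, "stimuli"))
        iomod.write_stimuli(stimuli, out / "stimuli")
        dataset = generate_voxels(
            extractor, stimuli, n_per_roi=c.n_per_roi, layer_map=c.layer_map,
            invariant_fraction=c.invariant_fraction, sparsity=c.sparsity,
            noise_sd=c.noise_sd, ensemble_k=c.ensemble_k,
            seed=derive_int_seed(c.seed, "voxels"))
        iomod.write_responses(dataset.responses, out / "responses.h5",
                              voxel_specs=dataset.voxel_specs)
        iomod.write_responses_csv(dataset.responses, out / "responses.csv")

    runner.run_stage("simulate", simulate,
                     ["stimuli/stimuli.json", "responses.h5", "responses.csv"])

    def augment() -> None:
        stimuli = iomod.read_stimuli(out / "stimuli")
        augmented = augment_library(stimuli, n_aug=c.n_aug,
                                    seed=derive_int_seed(c.seed, "augment"))
        iomod.write_augmented(augmented, out / "augmented")

    runner.run_stage("augment", augment, ["augmented/manifest.csv"])

    def extract_stage() -> None:
        stimuli = iomod.read_stimuli(out / "stimuli")
        feats = extract_multi(extractor, stimuli.pixels, stimuli.image_ids,
                              layers)
        iomod.write_features(feats, out / "features.h5")

    runner.run_stage("extract", extract_stage, ["features.h5"])

    def invariance() -> None:
        stimuli = iomod.read_stimuli(out / "stimuli")
        augmented = iomod.read_augmented(out / "augmented",
                                         stimuli.train_set())
        profiles = layer_similarity_profile(extractor, stimuli, augmented)
        trends = conv_fc_trend_report(profiles)
        kind = {li.index: li.kind for li in extractor.layers}
        rows = []
        for p in profiles:
            q1, q3 = p.quartiles
            rows.append({"layer": p.layer_index, "kind": kind[p.layer_index],
                         "mean": p.mean, "median": p.median, "q1": q1, "q3": q3})
        df = pd.DataFrame(rows)
        for name, tr in trends.items():
            df[f"MK_S_{name}"] = tr.S
            df[f"MK_p_{name}"] = tr.p_two_sided
            df[f"direction_{name}"] = tr.direction
        df.to_csv(out / "invariance_report.csv", index=False)

    runner.run_stage("invariance", invariance, ["invariance_report.csv"])

    model_specs = [("linear", c.encoding)]
    if c.include_tl:
        model_specs.append(("tl", c.tl_encoding))

    for kind_name, enc_config in model_specs:
        for trained_on in ("original", "augmented"):
            stage = f"encode_{kind_name}_{trained_on}"
            csv_name = f"accuracy_{kind_name}_{trained_on}.csv"

            def encode(trained_on=trained_on, enc_config=enc_config,
                       csv_name=csv_name) -> None:
                stimuli = iomod.read_stimuli(out / "stimuli")
                responses = iomod.read_responses(out / "responses.h5")
                augmented = None
                if trained_on == "augmented":
                    augmented = iomod.read_augmented(out / "augmented",
                                                     stimuli.train_set())
                fit = fit_encoding_model(extractor, stimuli, responses,
                                         enc_config, augmented=augmented,
                                         layers=layers, selection=c.selection)
                accuracy_table(fit).to_csv(out / csv_name, index=False)

            runner.run_stage(stage, encode, [csv_name])

    def evaluate() -> None:
        threshold = permutation_threshold(
            n_test=c.n_test, alpha=c.alpha, n_perm=c.n_perm,
            seed=derive_int_seed(c.seed, "perm"))
        tables = {}
        for kind_name, _cfg in model_specs:
            for trained_on in ("original", "augmented"):
                tables[(kind_name, trained_on)] = pd.read_csv(
                    out / f"accuracy_{kind_name}_{trained_on}.csv")
        prefs, hist = layer_preference_percentages(
            pd.concat(tables.values(), ignore_index=True),
            strong_group=set(c.strong_group), threshold=threshold)
        prefs.to_csv(out / "layer_preferences.csv", index=False)
        hist.to_csv(out / "layer_histogram.csv", index=False)
        topk = topk_accuracy_comparison(tables[("linear", "original")],
                                        tables[("linear", "augmented")],
                                        k=c.top_k)
        topk.to_csv(out / "topk_comparison.csv", index=False)
        attribution = voxel_attribution(tables, threshold=threshold)
        attribution.two_model.to_csv(out / "attribution_two_model.csv",
                                     index=False)
        if attribution.four_model is not None:
            attribution.four_model.to_csv(out / "attribution_four_model.csv",
                                          index=False)
        (out / "threshold.json").write_text(json.dumps(
            {"alpha": c.alpha, "n_test": c.n_test, "n_perm": c.n_perm,
             "threshold": threshold}))

    eval_outputs = ["layer_preferences.csv", "layer_histogram.csv",
                    "topk_comparison.csv", "attribution_two_model.csv",
                    "threshold.json"]
    if c.include_tl:
        eval_outputs.append("attribution_four_model.csv")
    runner.run_stage("evaluate", evaluate, eval_outputs)

    manifest = RunManifest(
        config=dataclasses.asdict(c),
        stages=runner.stages,
        versions={"numpy": np.__version__, "pandas": pd.__version__},
    )
    payload = {"config_digest": _config_digest(c),
               "config": manifest.config, "stages": manifest.stages,
               "versions": manifest.versions}
    tmp = runner.manifest_path.with_suffix(".tmp")
    tmp.write_text(json.dumps(payload, indent=1, default=str))
    tmp.replace(runner.manifest_path)
    return manifest
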