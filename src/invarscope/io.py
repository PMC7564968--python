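"""Readers and writers for stimuli, augmented libraries, features, responses.

Interchange conventions: images as 8-bit grayscale PNG with a JSON sidecar of
main-body boxes and splits; numeric matrices as HDF5 (primary) with CSV
mirrors. All writers round-trip exactly (PNG at 8-bit quantization, HDF5
bit-exact).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .augmentation import AugmentationRecord, AugmentedStimulusSet
from .errors import InvalidArgumentError
from .features import LayerFeatureMatrix
from .stimuli import StimulusSet
from .voxels import SyntheticVoxelSpec, VoxelResponseSet

# -- stimuli ----------------------------------------------------------------


def write_stimuli(stimuli: StimulusSet, directory: str | Path) -> Path:
    """PNG per image plus a ``stimuli.json`` sidecar of boxes and splits."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for i, iid in enumerate(stimuli.image_ids):
        arr = np.round(np.clip(stimuli.pixels[i], 0, 1) * 255).astype(np.uint8)
        iio.imwrite(directory / f"{iid}.png", arr)
        sidecar[iid] = {"main_body_box": [int(v) for v in stimuli.boxes[i]],
                        "split": str(stimuli.splits[i])}
    path = directory / "stimuli.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_stimuli(directory: str | Path) -> StimulusSet:
    directory = Path(directory)
    sidecar = json.loads((directory / "stimuli.json").read_text())
    ids = sorted(sidecar)
    pixels = np.stack([iio.imread(directory / f"{iid}.png").astype(np.float64) / 255
                       for iid in ids])
    boxes = np.array([sidecar[iid]["main_body_box"] for iid in ids], dtype=np.int64)
    splits = np.array([sidecar[iid]["split"] for iid in ids], dtype=object)
    return StimulusSet(image_ids=ids, pixels=pixels, boxes=boxes, splits=splits)


# -- augmented library ------------------------------------------------------


def write_augmented(augmented: AugmentedStimulusSet, directory: str | Path) -> Path:
    """Variant PNGs named ``<original_id>_aug<k>.png`` plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for iid, entries in augmented.variants.items():
        for pix, rec in entries:
            name = f"{iid}_aug{rec.aug_index}.png"
            arr = np.round(np.clip(pix, 0, 1) * 255).astype(np.uint8)
            iio.imwrite(directory / name, arr)
            r0, c0, r1, c1 = rec.crop_box
            rows.append({"original_id": iid, "aug_index": rec.aug_index,
                         "crop_row_min": r0, "crop_col_min": c0,
                         "crop_row_max": r1, "crop_col_max": c1,
                         "flip_mode": rec.flip_mode, "rng_seed": rec.rng_seed})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_augmented(directory: str | Path,
                   originals: StimulusSet) -> AugmentedStimulusSet:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    variants: dict[str, list] = {}
    for row in manifest.itertuples(index=False):
        pix = iio.imread(
            directory / f"{row.original_id}_aug{row.aug_index}.png"
        ).astype(np.float64) / 255
        rec = AugmentationRecord(
            original_id=row.original_id, aug_index=int(row.aug_index),
            crop_box=(int(row.crop_row_min), int(row.crop_col_min),
                      int(row.crop_row_max), int(row.crop_col_max)),
            flip_mode=str(row.flip_mode), rng_seed=int(row.rng_seed))
        variants.setdefault(row.original_id, []).append((pix, rec))
    return AugmentedStimulusSet(originals=originals, variants=variants)


# -- features ---------------------------------------------------------------


def write_features(features: dict[int, LayerFeatureMatrix],
                   path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        any_layer = next(iter(features.values()))
        f.create_dataset("image_ids",
                         data=np.array(any_layer.image_ids, dtype="S"))
        grp = f.create_group("features")
        for l, mat in features.items():
            ds = grp.create_dataset(f"layer{l}", data=mat.matrix)
            ds.attrs["kind"] = mat.kind
            ds.attrs["layer_index"] = l
    return path


def read_features(path: str | Path) -> dict[int, LayerFeatureMatrix]:
    with h5py.File(path, "r") as f:
        ids = [s.decode() for s in f["image_ids"][()]]
        out = {}
        for name, ds in f["features"].items():
            l = int(ds.attrs["layer_index"])
            out[l] = LayerFeatureMatrix(layer_index=l, kind=str(ds.attrs["kind"]),
                                        matrix=ds[()], image_ids=ids)
    return out


# -- responses --------------------------------------------------------------


def _validate_responses(data: np.ndarray, voxel_ids: list[str],
                        image_ids: list[str]) -> None:
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        v, i = bad[0]
        raise InvalidArgumentError(
            f"non-finite response at voxel {voxel_ids[v]!r}, "
            f"image {image_ids[i]!r} ({bad.shape[0]} offending entries)")


def write_responses(responses: VoxelResponseSet, path: str | Path,
                    voxel_specs: list[SyntheticVoxelSpec] | None = None) -> Path:
    """HDF5 with /responses, /roi_labels, /voxel_ids, /image_ids and, for
    synthetic data, a /ground_truth table."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=responses.data)
        f.create_dataset("roi_labels",
                         data=np.array([str(r) for r in responses.rois], dtype="S"))
        f.create_dataset("voxel_ids",
                         data=np.array(responses.voxel_ids, dtype="S"))
        f.create_dataset("image_ids",
                         data=np.array(responses.image_ids, dtype="S"))
        if voxel_specs is not None:
            grp = f.create_group("ground_truth")
            grp.create_dataset("voxel_id", data=np.array(
                [s.voxel_id for s in voxel_specs], dtype="S"))
            grp.create_dataset("assigned_layer", data=np.array(
                [s.assigned_layer for s in voxel_specs]))
            grp.create_dataset("invariance_class", data=np.array(
                [s.invariance_class for s in voxel_specs], dtype="S"))
            grp.create_dataset("noise_sd", data=np.array(
                [s.noise_sd for s in voxel_specs]))
    return path


def write_responses_csv(responses: VoxelResponseSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(responses.data, columns=responses.image_ids)
    df.insert(0, "voxel_id", responses.voxel_ids)
    df.insert(1, "roi", [str(r) for r in responses.rois])
    df.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            raise InvalidArgumentError(f"{path} carries no ground truth")
        grp = f["ground_truth"]
        return pd.DataFrame({
            "voxel_id": [s.decode() for s in grp["voxel_id"][()]],
            "assigned_layer": grp["assigned_layer"][()],
            "invariance_class": [s.decode() for s in grp["invariance_class"][()]],
            "noise_sd": grp["noise_sd"][()],
        })


def read_responses(path: str | Path, dialect: str = "hdf5") -> VoxelResponseSet:
    """Read a voxels x images response matrix with ROI labels.

    Dialects: ``hdf5`` (this package's layout), ``csv`` (wide table with
    voxel_id and roi columns), ``mat`` (best-effort reader for the public
    vim-1 deposit's MATLAB v7.3 layout; not exercised by the test suite).
    """
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("responses", "roi_labels", "image_ids", "voxel_ids"):
                if key not in f:
                    raise InvalidArgumentError(f"{path} lacks dataset /{key}")
            data = f["responses"][()]
            rois = np.array([s.decode() for s in f["roi_labels"][()]],
                            dtype=object)
            voxel_ids = [s.decode() for s in f["voxel_ids"][()]]
            image_ids = [s.decode() for s in f["image_ids"][()]]
    elif dialect == "csv":
        df = pd.read_csv(path)
        if "roi" not in df.columns or "voxel_id" not in df.columns:
            raise InvalidArgumentError(f"{path} lacks voxel_id/roi columns")
        voxel_ids = df["voxel_id"].astype(str).tolist()
        rois = df["roi"].astype(str).to_numpy(dtype=object)
        image_ids = [c for c in df.columns if c not in ("voxel_id", "roi")]
        data = df[image_ids].to_numpy(dtype=np.float64)
    elif dialect == "mat":
        data, rois, voxel_ids, image_ids = _read_mat_responses(path)
    else:
        raise InvalidArgumentError(f"unknown dialect {dialect!r}")
    _validate_responses(data, voxel_ids, image_ids)
    return VoxelResponseSet(data=data, voxel_ids=voxel_ids, rois=rois,
                            image_ids=image_ids)


_VIM1_ROI_NAMES = {1: "V1", 2: "V2", 3: "V3", 4: "V3A", 5: "V3B", 6: "V4",
                   7: "LO"}


def _read_mat_responses(path: Path):
    """Best-effort reader for the vim-1 ``EstimatedResponses.mat`` layout
    (MATLAB v7.3 = HDF5): dataTrnS1 [images x voxels] and roiS1 labels."""
    with h5py.File(path, "r") as f:
        data_key = next((k for k in f if k.lower().startswith("datatrn")), None)
        roi_key = next((k for k in f if k.lower().startswith("roi")), None)
        if data_key is None or roi_key is None:
            raise InvalidArgumentError(
                f"{path} does not look like a vim-1 response deposit")
        data = np.asarray(f[data_key][()], dtype=np.float64)
        roi_codes = np.asarray(f[roi_key][()]).ravel().astype(int)
    if data.shape[0] != roi_codes.size:  # stored images x voxels
        data = data.T
    keep = np.isin(roi_codes, list(_VIM1_ROI_NAMES))
    data = data[keep]
    # The deposit encodes missing voxels as NaN rows; drop them up front.
    finite = np.isfinite(data).all(axis=1)
    data = data[finite]
    rois = np.array([_VIM1_ROI_NAMES[c] for c in roi_codes[keep][finite]],
                    dtype=object)
    voxel_ids = [f"vox_{i:06d}" for i in range(data.shape[0])]
    image_ids = [f"train_{j:05d}" for j in range(data.shape[1])]
    return data, rois, voxel_ids, image_ids
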