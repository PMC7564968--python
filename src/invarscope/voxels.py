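"""Synthetic voxel populations with known invariance ground truth.

Each synthetic voxel is a noisy sparse linear readout of one extractor
layer's features — the same functional form the linear encoding model
assumes, so parameter recovery is well-posed. Two voxel classes embody the
hypothesis under study:

* an EQUIVARIANT voxel responds to image i as  w . F_l(i) + eps : its signal
  tracks the exact feature vector, so transformed variants of i elicit
  different noiseless responses;
* an INVARIANT voxel responds as  w . Fbar_l(i) + eps , where Fbar_l(i) is
  the mean of F_l over ``ensemble_k`` fresh augmentations of i — by
  construction its noiseless response is identical for every augmented
  variant of i.

Region labels follow the ventral stream (V1, V2, V3, V4, LO); by default
deeper layers are more probable for V4/LO than for V1, mirroring the
low-to-high-level gradient. Responses are standardized per voxel over the
training split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .augmentation import augment_image
from .errors import InvalidArgumentError
from .features import FeatureExtractor, extract_multi
from .stimuli import StimulusSet
from ._rng import derive_int_seed, derive_rng

ROIS = ("V1", "V2", "V3", "V4", "LO")

#: ROI -> categorical distribution over assigned layers (ventral gradient).
DEFAULT_LAYER_MAP: dict[str, dict[int, float]] = {
    "V1": {1: 0.5, 2: 0.5},
    "V2": {2: 0.5, 3: 0.5},
    "V3": {3: 0.5, 4: 0.5},
    "V4": {4: 1 / 3, 5: 1 / 3, 6: 1 / 3},
    "LO": {5: 0.25, 6: 0.25, 7: 0.25, 8: 0.25},
}


@dataclass(frozen=True)
class SyntheticVoxelSpec:
    """Ground truth for one generated voxel."""

    voxel_id: str
    roi: str
    assigned_layer: int
    invariance_class: str  # "invariant" | "equivariant"
    weight_indices: np.ndarray  # feature indices of the nonzero weights
    weight_values: np.ndarray
    noise_sd: float


@dataclass
class VoxelResponseSet:
    """voxels x images response matrix with per-voxel ROI labels."""

    data: np.ndarray  # (n_voxels, n_images)
    voxel_ids: list[str]
    rois: np.ndarray
    image_ids: list[str]
    _vindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.voxel_ids), len(self.image_ids)):
            raise InvalidArgumentError("response matrix shape disagrees with labels")
        if len(self.rois) != len(self.voxel_ids):
            raise InvalidArgumentError("one ROI label per voxel required")
        self._vindex = {vid: i for i, vid in enumerate(self.voxel_ids)}

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def voxel_index(self, voxel_id: str) -> int:
        return self._vindex[voxel_id]

    def columns_for(self, image_ids: list[str]) -> np.ndarray:
        order = {iid: j for j, iid in enumerate(self.image_ids)}
        try:
            idx = [order[iid] for iid in image_ids]
        except KeyError as exc:
            raise InvalidArgumentError(f"unknown image id {exc}") from exc
        return self.data[:, idx]


@dataclass
class SyntheticDataset:
    stimuli: StimulusSet
    responses: VoxelResponseSet
    voxel_specs: list[SyntheticVoxelSpec]
    generation_seed: int
    ensemble_k: int


def _ensemble_mean_features(extractor: FeatureExtractor, stimuli: StimulusSet,
                            layers: tuple[int, ...], ensemble_k: int,
                            seed: int) -> dict[int, np.ndarray]:
    """Mean feature over ``ensemble_k`` fresh augmentations, per image."""
    sums = {l: None for l in layers}
    for i, iid in enumerate(stimuli.image_ids):
        rng = derive_rng(seed, "ensemble", iid)
        sub_seed = derive_int_seed(seed, "ensemble", iid)
        variants = augment_image(stimuli.pixels[i], tuple(stimuli.boxes[i]),
                                 ensemble_k, rng, original_id=iid,
                                 rng_seed=sub_seed)
        pix = np.stack([p for p, _ in variants])
        feats = extract_multi(extractor, pix,
                              [f"{iid}~e{k}" for k in range(ensemble_k)], layers)
        for l in layers:
            mean = feats[l].matrix.mean(axis=0)
            if sums[l] is None:
                sums[l] = np.empty((len(stimuli), mean.size))
            sums[l][i] = mean
    return sums


def generate_voxels(extractor: FeatureExtractor, stimuli: StimulusSet,
                    n_per_roi: int = 40,
                    layer_map: dict[str, dict[int, float]] | None = None,
                    invariant_fraction: float | dict[str, float] = 0.5,
                    sparsity: int = 10, noise_sd: float = 0.2,
                    ensemble_k: int = 10, seed: int = 0) -> SyntheticDataset:
    """Generate per-ROI voxel populations over the given stimuli.

    ``invariant_fraction`` may be a single value or a per-ROI mapping; within
    each ROI the first ``ceil(fraction * n_per_roi)`` drawn voxels are
    invariant (deterministic rounding rule). ``noise_sd`` is the noise
    standard deviation relative to the unit-variance noiseless signal.
    """
    if layer_map is None:
        layer_map = DEFAULT_LAYER_MAP
    if len(stimuli) == 0:
        raise InvalidArgumentError("stimuli set is empty")
    if sparsity < 1:
        raise InvalidArgumentError("sparsity must be at least 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    all_layers = sorted({l for dist in layer_map.values() for l in dist})
    if max(all_layers) > extractor.n_layers:
        raise InvalidArgumentError(
            f"layer_map references layer {max(all_layers)} beyond extractor "
            f"depth {extractor.n_layers}")

    feats = extract_multi(extractor, stimuli.pixels, stimuli.image_ids,
                          tuple(all_layers))
    exact = {l: feats[l].matrix for l in all_layers}
    averaged = _ensemble_mean_features(extractor, stimuli, tuple(all_layers),
                                       ensemble_k, derive_int_seed(seed, "ens-seed"))
    train_mask = stimuli.splits == "train"
    if not train_mask.any():
        raise InvalidArgumentError("need at least one training image")

    specs: list[SyntheticVoxelSpec] = []
    rows: list[np.ndarray] = []
    rois_out: list[str] = []
    voxel_ids: list[str] = []
    for roi, dist in layer_map.items():
        frac = (invariant_fraction[roi] if isinstance(invariant_fraction, dict)
                else invariant_fraction)
        if not 0.0 <= frac <= 1.0:
            raise InvalidArgumentError("invariant_fraction must lie in [0, 1]")
        n_invariant = math.ceil(frac * n_per_roi)
        layers = np.array(sorted(dist))
        probs = np.array([dist[l] for l in layers], dtype=float)
        probs = probs / probs.sum()
        for v in range(n_per_roi):
            voxel_id = f"{roi}_{v:04d}"
            rng = derive_rng(seed, "voxel", roi, v)
            invariance_class = "invariant" if v < n_invariant else "equivariant"
            layer = int(rng.choice(layers, p=probs))
            source = averaged if invariance_class == "invariant" else exact
            x = source[layer]
            dim = x.shape[1]
            k = min(sparsity, dim)
            idx = np.sort(rng.choice(dim, size=k, replace=False))
            w = rng.standard_normal(k)
            signal = x[:, idx] @ w
            sd = signal[train_mask].std()
            if sd > 0:
                signal = (signal - signal[train_mask].mean()) / sd
            response = signal + noise_sd * rng.standard_normal(signal.size)
            r_sd = response[train_mask].std()
            if r_sd > 0:
                response = (response - response[train_mask].mean()) / r_sd
            specs.append(SyntheticVoxelSpec(
                voxel_id=voxel_id, roi=roi, assigned_layer=layer,
                invariance_class=invariance_class, weight_indices=idx,
                weight_values=w, noise_sd=noise_sd))
            rows.append(response)
            rois_out.append(roi)
            voxel_ids.append(voxel_id)

    responses = VoxelResponseSet(
        data=np.vstack(rows), voxel_ids=voxel_ids,
        rois=np.array(rois_out, dtype=object),
        image_ids=list(stimuli.image_ids))
    return SyntheticDataset(stimuli=stimuli, responses=responses,
                            voxel_specs=specs, generation_seed=seed,
                            ensemble_k=ensemble_k)
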