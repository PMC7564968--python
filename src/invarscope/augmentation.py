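"""Main-body-preserving image augmentation: random crop, rescale, flip.

Each original yields ``n_aug`` variants. A variant is produced by (1) cropping
a random square whose side is drawn uniformly between the main-body side and
the full image side, positioned uniformly among placements that contain the
main-body box; (2) rescaling the crop back to the original size by bilinear
interpolation; (3) flipping in one of four ways (none / horizontal / vertical
/ both), drawn uniformly. The full transform is recorded so every variant is
reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import InvalidArgumentError
from .stimuli import Box, StimulusSet
from ._rng import derive_int_seed, derive_rng

FLIP_MODES = ("none", "horizontal", "vertical", "both")


@dataclass(frozen=True)
class AugmentationRecord:
    """Full record of one crop-rescale-flip draw."""

    original_id: str
    aug_index: int
    crop_box: Box  # half-open (row_min, col_min, row_max, col_max)
    flip_mode: str
    rng_seed: int


@dataclass
class AugmentedStimulusSet:
    """Per-original ordered lists of (pixels, record) variants."""

    originals: StimulusSet
    variants: dict[str, list[tuple[np.ndarray, AugmentationRecord]]]

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.variants.values())

    def records(self) -> list[AugmentationRecord]:
        return [rec for entries in self.variants.values() for _, rec in entries]


def apply_flip(pixels: np.ndarray, flip_mode: str) -> np.ndarray:
    if flip_mode == "none":
        return pixels
    if flip_mode == "horizontal":
        return pixels[:, ::-1]
    if flip_mode == "vertical":
        return pixels[::-1, :]
    if flip_mode == "both":
        return pixels[::-1, ::-1]
    raise InvalidArgumentError(f"unknown flip_mode {flip_mode!r}")


def _rescale(crop: np.ndarray, size: int) -> np.ndarray:
    if crop.shape == (size, size):
        return crop.copy()  # identity crop stays bit-identical
    return resize(crop, (size, size), order=1, anti_aliasing=False,
                  preserve_range=True, mode="edge")


def augment_image(pixels: np.ndarray, main_body_box: Box, n_aug: int,
                  rng: np.random.Generator, original_id: str = "",
                  rng_seed: int = 0) -> list[tuple[np.ndarray, AugmentationRecord]]:
    """Draw ``n_aug`` crop-rescale-flip variants of one square image."""
    size = pixels.shape[0]
    if pixels.shape[0] != pixels.shape[1]:
        raise InvalidArgumentError("image must be square")
    r0, c0, r1, c1 = (int(v) for v in main_body_box)
    if not (0 <= r0 < r1 <= size and 0 <= c0 < c1 <= size):
        raise InvalidArgumentError(f"main_body_box {main_body_box} exceeds image bounds")
    mb_side = max(r1 - r0, c1 - c0)

    out: list[tuple[np.ndarray, AugmentationRecord]] = []
    for k in range(n_aug):
        side = int(rng.integers(mb_side, size + 1))
        # Row/col origin uniform among placements containing the main body.
        rlo, rhi = max(0, r1 - side), min(r0, size - side)
        clo, chi = max(0, c1 - side), min(c0, size - side)
        rr = int(rng.integers(rlo, rhi + 1))
        cc = int(rng.integers(clo, chi + 1))
        flip_mode = FLIP_MODES[int(rng.integers(0, 4))]
        crop_box: Box = (rr, cc, rr + side, cc + side)
        variant = apply_flip(_rescale(pixels[rr:rr + side, cc:cc + side], size),
                             flip_mode)
        record = AugmentationRecord(original_id=original_id, aug_index=k,
                                    crop_box=crop_box, flip_mode=flip_mode,
                                    rng_seed=rng_seed)
        out.append((np.ascontiguousarray(variant), record))
    return out


def augment_stimulus(stimuli: StimulusSet, image_id: str, n_aug: int,
                     seed: int) -> list[tuple[np.ndarray, AugmentationRecord]]:
    """Augment one image of a set with its per-image derived seed."""
    i = stimuli.index_of(image_id)
    sub_seed = derive_int_seed(seed, "augment", image_id)
    rng = derive_rng(seed, "augment", image_id)
    return augment_image(stimuli.pixels[i], tuple(stimuli.boxes[i]), n_aug,
                         rng, original_id=image_id, rng_seed=sub_seed)


def augment_library(stimuli: StimulusSet, n_aug: int = 10,
                    seed: int = 0, split: str = "train") -> AugmentedStimulusSet:
    """Augment every image of the given split (training library by default)."""
    if len(stimuli) == 0:
        raise InvalidArgumentError("stimuli set is empty")
    subset = stimuli.subset(split)
    variants = {iid: augment_stimulus(stimuli, iid, n_aug, seed)
                for iid in subset.image_ids}
    return AugmentedStimulusSet(originals=subset, variants=variants)
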