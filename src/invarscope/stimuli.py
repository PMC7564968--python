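"""Synthetic grayscale stimulus generation.

Emulates a natural-image stimulus protocol: square grayscale images, each
containing a textured "object" (a superposition of oriented band-pass patches
and a geometric shape) confined to a main-body bounding box over a
low-amplitude background texture. The box operationalizes the "main body of
the object" that augmentation crops must preserve. Default library sizes match
the emulated recordings: 1750 training and 120 test images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError
from ._rng import derive_rng

#: Half-open box as (row_min, col_min, row_max, col_max), 0-based.
Box = tuple[int, int, int, int]


@dataclass
class StimulusSet:
    """Indexed grayscale images with main-body boxes and a train/test split.

    pixels is (n, size, size) float64 in [0, 1]; boxes is (n, 4) int with
    half-open (row_min, col_min, row_max, col_max); splits holds "train" or
    "test" per image.
    """

    image_ids: list[str]
    pixels: np.ndarray
    boxes: np.ndarray
    splits: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.image_ids) != self.pixels.shape[0]:
            raise InvalidArgumentError("image_ids and pixels disagree on count")
        self._index = {iid: i for i, iid in enumerate(self.image_ids)}

    def __len__(self) -> int:
        return len(self.image_ids)

    @property
    def image_size(self) -> int:
        return int(self.pixels.shape[1]) if len(self) else 0

    def index_of(self, image_id: str) -> int:
        return self._index[image_id]

    def subset(self, split: str) -> "StimulusSet":
        mask = self.splits == split
        return StimulusSet(
            image_ids=[iid for iid, m in zip(self.image_ids, mask) if m],
            pixels=self.pixels[mask],
            boxes=self.boxes[mask],
            splits=self.splits[mask],
        )

    def train_set(self) -> "StimulusSet":
        return self.subset("train")

    def test_set(self) -> "StimulusSet":
        return self.subset("test")


def _gabor_patch(size: int, cy: float, cx: float, sigma: float,
                 theta: float, freq: float, phase: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rows - cy, cols - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    envelope = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    return envelope * np.cos(2.0 * np.pi * freq * u + phase)


def _draw_object(rng: np.random.Generator, canvas: np.ndarray, box: Box) -> None:
    """Paint a textured object strictly inside ``box`` (in place)."""
    r0, c0, r1, c1 = box
    h, w = r1 - r0, c1 - c0
    side = min(h, w)
    patch = np.zeros((h, w))
    # Oriented band-pass texture: a few random Gabor patches.
    for _ in range(rng.integers(2, 5)):
        patch += rng.uniform(0.15, 0.35) * _gabor_patch(
            size=side,
            cy=rng.uniform(0.25, 0.75) * side,
            cx=rng.uniform(0.25, 0.75) * side,
            sigma=rng.uniform(0.12, 0.25) * side,
            theta=rng.uniform(0.0, np.pi),
            freq=rng.uniform(0.08, 0.3),
            phase=rng.uniform(0.0, 2.0 * np.pi),
        )[:h, :w]
    # One geometric shape: filled disk or rectangle, light or dark.
    amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.15, 0.3)
    if rng.random() < 0.5:
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = rng.uniform(0.3, 0.7) * h, rng.uniform(0.3, 0.7) * w
        radius = rng.uniform(0.15, 0.35) * side
        patch += amp * ((rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2)
    else:
        rh, rw = (rng.uniform(0.2, 0.5, size=2) * (h, w)).astype(int)
        rr = rng.integers(0, max(h - rh, 1))
        cc = rng.integers(0, max(w - rw, 1))
        patch[rr:rr + rh, cc:cc + rw] += amp
    # Soft circular window keeps the object weight inside the box.
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    window = np.exp(-(((rows - h / 2) / (0.55 * h)) ** 2
                      + ((cols - w / 2) / (0.55 * w)) ** 2) ** 2)
    canvas[r0:r1, c0:c1] += patch * window


def _generate_one(rng: np.random.Generator, size: int) -> tuple[np.ndarray, Box]:
    # Low-amplitude smoothed-noise background around mid-gray.
    background = 0.45 + 0.06 * gaussian_filter(rng.standard_normal((size, size)), 2.0)
    # Main-body box: side 40-60% of the image, strictly inside (margin >= 1).
    side = int(round(rng.uniform(0.4, 0.6) * size))
    side = min(side, size - 2)
    r0 = int(rng.integers(1, size - side))
    c0 = int(rng.integers(1, size - side))
    box: Box = (r0, c0, r0 + side, c0 + side)
    _draw_object(rng, background, box)
    return np.clip(background, 0.0, 1.0), box


def generate_stimuli(n_train: int, n_test: int, image_size: int = 64,
                     seed: int = 0) -> StimulusSet:
    """Generate ``n_train + n_test`` square synthetic stimuli.

    Deterministic given (arguments, seed); each image gets its own derived
    RNG stream so the content of image k does not depend on how many images
    precede it.
    """
    if image_size < 16:
        raise InvalidArgumentError(f"image_size must be >= 16, got {image_size}")
    if n_train < 0 or n_test < 0:
        raise InvalidArgumentError("n_train and n_test must be nonnegative")

    n = n_train + n_test
    pixels = np.empty((n, image_size, image_size), dtype=np.float64)
    boxes = np.empty((n, 4), dtype=np.int64)
    image_ids: list[str] = []
    splits = np.array(["train"] * n_train + ["test"] * n_test, dtype=object)
    for i in range(n):
        role, k = ("train", i) if i < n_train else ("test", i - n_train)
        image_id = f"{role}_{k:05d}"
        rng = derive_rng(seed, "stimulus", image_id)
        pixels[i], boxes[i] = _generate_one(rng, image_size)
        image_ids.append(image_id)
    return StimulusSet(image_ids=image_ids, pixels=pixels, boxes=boxes, splits=splits)
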