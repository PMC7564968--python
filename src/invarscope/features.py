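"""Frozen 8-layer hierarchical feature extractor (5 conv + 3 fc stages).

The built-in instance is a pure-NumPy convolutional network with deterministic
random weights: five 3x3 same-padded convolutions with ReLU (2x2 max-pooling
after stages 1, 2 and 5) followed by three fully connected ReLU stages. It is
frozen — never trained — and serves as a desk-scale hierarchical feature
extractor whose conv/fc dichotomy mirrors the AlexNet layout the analysis
targets. "The feature" of layer l is the post-activation (and post-pool,
where a pool follows) map, flattened in channel-row-column order.

An external pre-trained network can be wrapped through the same interface by
providing its weights as an .npz in the layout documented in
``load_external_extractor``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidArgumentError, UnavailableResourceError
from ._rng import derive_rng

#: Stages followed by a 2x2 max-pool (1-based conv stage indices).
POOLED_STAGES = (1, 2, 5)


@dataclass(frozen=True)
class LayerInfo:
    index: int  # 1-based
    kind: str  # "conv" | "fc"
    output_dim: int


@dataclass(frozen=True)
class LayerFeatureMatrix:
    """images x flattened-features for one layer."""

    layer_index: int
    kind: str
    matrix: np.ndarray  # (n_images, dim)
    image_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.image_ids):
            raise InvalidArgumentError("row count must equal number of image ids")
        if not np.isfinite(self.matrix).all():
            raise InvalidArgumentError("feature matrix contains non-finite entries")


class FeatureExtractor:
    """Frozen NumPy CNN: conv stages then fc stages, exposed as layers 1..L."""

    def __init__(self, image_size: int, conv_weights: list[np.ndarray],
                 conv_biases: list[np.ndarray], fc_weights: list[np.ndarray],
                 fc_biases: list[np.ndarray], weights_seed: int = 0,
                 provenance: str = "builtin") -> None:
        self.image_size = image_size
        self.conv_weights = conv_weights  # each (C_out, C_in, 3, 3)
        self.conv_biases = conv_biases
        self.fc_weights = fc_weights  # each (D_out, D_in)
        self.fc_biases = fc_biases
        self.weights_seed = weights_seed
        self.provenance = provenance
        self.layers = self._layer_table()

    @property
    def n_layers(self) -> int:
        return len(self.conv_weights) + len(self.fc_weights)

    def _layer_table(self) -> list[LayerInfo]:
        table: list[LayerInfo] = []
        size = self.image_size
        for i, w in enumerate(self.conv_weights, start=1):
            if i in POOLED_STAGES:
                size //= 2
            table.append(LayerInfo(i, "conv", w.shape[0] * size * size))
        for j, w in enumerate(self.fc_weights, start=1):
            table.append(LayerInfo(len(self.conv_weights) + j, "fc", w.shape[0]))
        return table

    # -- forward pass ------------------------------------------------------

    @staticmethod
    def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Same-padded 3x3 convolution; x is (N, C, H, W)."""
        n, c, h, width = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * width, c * 9)
        out = cols @ w.reshape(w.shape[0], -1).T + b
        return out.reshape(n, h, width, w.shape[0]).transpose(0, 3, 1, 2)

    @staticmethod
    def _maxpool2(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))

    def _forward(self, images: np.ndarray,
                 layers: tuple[int, ...]) -> dict[int, np.ndarray]:
        """Run the network once, returning flattened features per asked layer."""
        wanted = set(layers)
        deepest = max(layers)
        out: dict[int, np.ndarray] = {}
        x = images[:, None, :, :].astype(np.float64)
        n_conv = len(self.conv_weights)
        for i in range(1, n_conv + 1):
            x = np.maximum(self._conv2d(x, self.conv_weights[i - 1],
                                        self.conv_biases[i - 1]), 0.0)
            if i in POOLED_STAGES:
                x = self._maxpool2(x)
            if i in wanted:
                out[i] = x.reshape(x.shape[0], -1).copy()
            if i == deepest:
                return out
        v = x.reshape(x.shape[0], -1)
        for j in range(1, len(self.fc_weights) + 1):
            v = np.maximum(v @ self.fc_weights[j - 1].T + self.fc_biases[j - 1], 0.0)
            if n_conv + j in wanted:
                out[n_conv + j] = v.copy()
            if n_conv + j == deepest:
                return out
        return out


def build_toy_extractor(image_size: int = 64,
                        channel_widths: tuple[int, ...] = (8, 12, 16, 16, 16),
                        fc_widths: tuple[int, int, int] = (256, 128, 32),
                        seed: int = 0) -> FeatureExtractor:
    """Construct the frozen built-in 5-conv + 3-fc extractor.

    Weights are He-scaled Gaussians drawn deterministically from ``seed``;
    conv biases are small positive constants so rectified maps are not
    identically zero, fc biases are zero.
    """
    if len(channel_widths) != 5 or len(fc_widths) != 3:
        raise InvalidArgumentError("expected 5 conv widths and 3 fc widths")
    if any(w <= 0 for w in channel_widths + tuple(fc_widths)):
        raise InvalidArgumentError("layer widths must be positive")
    n_pools = len(POOLED_STAGES)
    if image_size < 2**n_pools or image_size % (2**n_pools) != 0:
        raise InvalidArgumentError(
            f"image_size must be a positive multiple of {2**n_pools}")

    rng = derive_rng(seed, "toy-extractor")
    conv_w, conv_b = [], []
    c_in = 1
    for c_out in channel_widths:
        fan_in = c_in * 9
        conv_w.append(rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in))
        conv_b.append(np.full(c_out, 0.05))
        c_in = c_out
    final_map = image_size // (2**n_pools)
    d_in = channel_widths[-1] * final_map * final_map
    fc_w, fc_b = [], []
    for d_out in fc_widths:
        fc_w.append(rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in))
        fc_b.append(np.zeros(d_out))
        d_in = d_out
    return FeatureExtractor(image_size, conv_w, conv_b, fc_w, fc_b,
                            weights_seed=seed, provenance="builtin")


def load_external_extractor(path: str | Path) -> FeatureExtractor:
    """Wrap an externally trained network stored as .npz.

    Expected arrays: ``image_size`` (scalar), ``conv{i}_w``/``conv{i}_b`` for
    i in 1..5 and ``fc{j}_w``/``fc{j}_b`` for j in 1..3, in the same layout as
    the built-in extractor. Missing file raises; the built-in extractor is
    never substituted silently.
    """
    path = Path(path)
    if not path.exists():
        raise UnavailableResourceError(f"extractor weights not found: {path}")
    with np.load(path) as data:
        try:
            image_size = int(data["image_size"])
            conv_w = [data[f"conv{i}_w"] for i in range(1, 6)]
            conv_b = [data[f"conv{i}_b"] for i in range(1, 6)]
            fc_w = [data[f"fc{j}_w"] for j in range(1, 4)]
            fc_b = [data[f"fc{j}_b"] for j in range(1, 4)]
        except KeyError as exc:
            raise UnavailableResourceError(
                f"weights file {path} lacks required array {exc}") from exc
    return FeatureExtractor(image_size, conv_w, conv_b, fc_w, fc_b,
                            provenance="external")


def _check_inputs(extractor: FeatureExtractor, images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1] != extractor.image_size \
            or images.shape[2] != extractor.image_size:
        raise InvalidArgumentError(
            f"images must be (n, {extractor.image_size}, {extractor.image_size})")
    return images


def extract_multi(extractor: FeatureExtractor, images: np.ndarray,
                  image_ids: list[str], layers: tuple[int, ...] | None = None,
                  batch_size: int = 64) -> dict[int, LayerFeatureMatrix]:
    """Extract several layers in one forward pass, batched for memory.

    Batching is over images only and cannot change results: every row is
    computed by the same deterministic arithmetic regardless of batch
    composition.
    """
    if layers is None:
        layers = tuple(li.index for li in extractor.layers)
    for layer in layers:
        if not 1 <= layer <= extractor.n_layers:
            raise InvalidArgumentError(
                f"layer {layer} out of range 1..{extractor.n_layers}")
    images = _check_inputs(extractor, images)
    if images.shape[0] != len(image_ids):
        raise InvalidArgumentError("image count and image_ids disagree")
    chunks: dict[int, list[np.ndarray]] = {l: [] for l in layers}
    for start in range(0, images.shape[0], batch_size):
        part = extractor._forward(images[start:start + batch_size], tuple(layers))
        for l in layers:
            chunks[l].append(part[l])
    kind = {li.index: li.kind for li in extractor.layers}
    empty_dim = {li.index: li.output_dim for li in extractor.layers}
    out = {}
    for l in layers:
        mat = (np.concatenate(chunks[l], axis=0) if chunks[l]
               else np.empty((0, empty_dim[l])))
        out[l] = LayerFeatureMatrix(layer_index=l, kind=kind[l], matrix=mat,
                                    image_ids=list(image_ids))
    return out


def extract(extractor: FeatureExtractor, images: np.ndarray,
            image_ids: list[str], layer: int,
            batch_size: int = 64) -> LayerFeatureMatrix:
    """Features of one layer for an ordered image collection."""
    return extract_multi(extractor, images, image_ids, (layer,), batch_size)[layer]
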