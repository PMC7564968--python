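"""Layer-wise representation-invariance profiling.

For each extractor layer, the similarity between an original image's feature
vector and each of its augmented variants' feature vectors is measured by the
cosine similarity

    D_cos = (F_l(I_o) . F_l(I_A)) / (||F_l(I_o)|| ||F_l(I_A)||)

and averaged per original. A layer whose features barely move under crop /
rescale / flip (D_cos near 1) represents invariantly; a layer whose features
track the transform scores lower. The layer-wise trend of mean similarity is
tested with the Mann-Kendall sign statistic, separately over the
convolutional prefix and the fully connected suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .augmentation import AugmentedStimulusSet
from .errors import InvalidArgumentError, UndefinedValueError
from .features import FeatureExtractor, extract_multi
from .stimuli import StimulusSet


@dataclass(frozen=True)
class SimilarityDistribution:
    """Per-image mean original-vs-variant similarities for one layer."""

    layer_index: int
    kind: str
    per_image_means: np.ndarray  # one value per original image

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_image_means))

    @property
    def median(self) -> float:
        return float(np.median(self.per_image_means))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.per_image_means, [25, 75])
        return float(q1), float(q3)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall trend over an ordered sequence."""

    S: int
    variance: float
    z: float
    p_two_sided: float
    direction: str  # "increasing" | "decreasing" | "none"


def cosine_similarity(f_o: np.ndarray, f_a: np.ndarray) -> float:
    f_o = np.asarray(f_o, dtype=np.float64).ravel()
    f_a = np.asarray(f_a, dtype=np.float64).ravel()
    if f_o.shape != f_a.shape:
        raise InvalidArgumentError(
            f"vector lengths differ: {f_o.size} vs {f_a.size}")
    no, na = np.linalg.norm(f_o), np.linalg.norm(f_a)
    if no == 0.0 or na == 0.0:
        raise UndefinedValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(f_o, f_a) / (no * na), -1.0, 1.0))


def _rowwise_cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity of matching rows of two matrices."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise UndefinedValueError("cosine similarity undefined for a zero vector")
    return np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)


def layer_similarity_profile(extractor: FeatureExtractor, stimuli: StimulusSet,
                             augmented: AugmentedStimulusSet,
                             layers: tuple[int, ...] | None = None,
                             matched: bool = True,
                             batch_images: int = 64,
                             ) -> list[SimilarityDistribution]:
    """Per-layer distributions of mean original-vs-variant similarity.

    ``matched=True`` pairs each original with its own variants (the default
    reading: transformation invariance of the same content). ``matched=False``
    instead pairs each original with the variants of every other image, a
    content-mismatch baseline.
    """
    if layers is None:
        layers = tuple(li.index for li in extractor.layers)
    ids = [iid for iid in stimuli.image_ids if iid in augmented.variants]
    if not ids:
        raise InvalidArgumentError("no augmented variants for the given stimuli")
    kind = {li.index: li.kind for li in extractor.layers}
    sums = {l: np.zeros(len(ids)) for l in layers}
    counts = np.zeros(len(ids))

    # Stream image by image batches: originals + their variants together.
    for start in range(0, len(ids), batch_images):
        block = ids[start:start + batch_images]
        orig_px = np.stack([stimuli.pixels[stimuli.index_of(i)] for i in block])
        var_px, owners = [], []
        for j, iid in enumerate(block):
            for pix, _rec in augmented.variants[iid]:
                var_px.append(pix)
                owners.append(j)
        owners = np.asarray(owners, dtype=int)
        all_px = np.concatenate([orig_px, np.stack(var_px)]) if var_px else orig_px
        all_ids = [f"o{j}" for j in range(len(block))] + [f"v{k}" for k in range(len(var_px))]
        feats = extract_multi(extractor, all_px, all_ids, layers)
        for l in layers:
            mat = feats[l].matrix
            orig_f, var_f = mat[:len(block)], mat[len(block):]
            if matched:
                sims = _rowwise_cosine(orig_f[owners], var_f)
                np.add.at(sums[l], start + owners, sims)
            else:
                # Cross pairing: each original vs variants of other images.
                norms_o = np.linalg.norm(orig_f, axis=1)
                norms_v = np.linalg.norm(var_f, axis=1)
                if np.any(norms_o == 0.0) or np.any(norms_v == 0.0):
                    raise UndefinedValueError("zero feature vector in similarity")
                cross = (orig_f @ var_f.T) / np.outer(norms_o, norms_v)
                for j in range(len(block)):
                    mask = owners != j
                    if mask.any():
                        sums[l][start + j] += float(cross[j, mask].sum())
        if matched:
            for j in range(len(block)):
                counts[start + j] += len(augmented.variants[block[j]])
        else:
            for j in range(len(block)):
                counts[start + j] += int((owners != j).sum())

    if np.any(counts == 0):
        raise InvalidArgumentError("some images have no variants to compare")
    return [SimilarityDistribution(layer_index=l, kind=kind[l],
                                   per_image_means=sums[l] / counts)
            for l in layers]


def mann_kendall_trend(sequence: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance.

    S = sum over ordered pairs i<j of sign(x_j - x_i);
    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups of size
    t; z uses a continuity correction and the standard normal two-sided p.
    """
    x = np.asarray(sequence, dtype=np.float64)
    n = x.size
    if n < 3:
        raise InvalidArgumentError("Mann-Kendall test needs at least 3 values")
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)))
    variance = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if s == 0 or variance <= 0:
        z = 0.0
    else:
        z = (s - np.sign(s)) / np.sqrt(variance)
    p = float(2.0 * norm.sf(abs(z)))
    if p < alpha and s != 0:
        direction = "increasing" if s > 0 else "decreasing"
    else:
        direction = "none"
    return TrendResult(S=s, variance=float(variance), z=float(z),
                       p_two_sided=p, direction=direction)


def conv_fc_trend_report(profiles: list[SimilarityDistribution],
                         conv_layers: tuple[int, ...] = (1, 2, 3, 4, 5),
                         fc_layers: tuple[int, ...] = (5, 6, 7, 8),
                         ) -> dict[str, TrendResult]:
    """Trend of layer-mean similarity over the conv prefix and the fc suffix.

    The fc window defaults to layers 5..8 so the turn from the deepest conv
    stage into the fully connected stack is part of the tested rise; pass
    (6, 7, 8) to restrict to fully connected layers only.

    The reported direction is descriptive — the sign of S — because windows
    of 3-5 layers can never clear a p < 0.05 gate under the normal
    approximation even when strictly monotone; the p-value is reported
    alongside so callers can apply their own significance gate.
    """
    means = {p.layer_index: p.mean for p in profiles}
    for l in tuple(conv_layers) + tuple(fc_layers):
        if l not in means:
            raise InvalidArgumentError(f"no similarity profile for layer {l}")
    out = {}
    for name, window in (("conv", conv_layers), ("fc", fc_layers)):
        res = mann_kendall_trend([means[l] for l in window])
        direction = ("increasing" if res.S > 0
                     else "decreasing" if res.S < 0 else "none")
        out[name] = TrendResult(S=res.S, variance=res.variance, z=res.z,
                                p_two_sided=res.p_two_sided,
                                direction=direction)
    return out
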