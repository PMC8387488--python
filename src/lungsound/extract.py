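"""Frozen convolutional feature extractors behind one pluggable contract.

The registry mirrors the six image backbones of the benchmark grid
(InceptionV3, DenseNet201, ResNet50, ResNet101, VGG16, VGG19) plus a light
``random_fallback``. Each entry is a frozen, seeded random-weight
convolutional network whose downsampling path reproduces the named
architecture's spatial/channel output signature exactly (e.g. VGG16 on a
256x256 input: five 2x poolings -> 8x8x512). Random convolutional projections
of this kind are untrained but information-preserving, so they provide
deterministic, download-free features for the classifier heads; loading
pretrained ImageNet weights would require a deep-learning runtime and is not
supported (``pretrained=True`` raises).

The three stack channels map to the network's three input channels in the
fixed order (mel, hpss_avg, delta). Named architectures apply the standard
ImageNet per-channel input normalization; the fallback applies identity
scaling.
"""

from __future__ import annotations

import hashlib
import zlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import SpectrogramStack

__all__ = [
    "FeatureExtractor",
    "FeatureMap",
    "ExtractorError",
    "REGISTRY_NAMES",
    "get_extractor",
    "extract_features",
]


class ExtractorError(KeyError):
    """Unknown extractor name or unsupported extractor mode."""


# layer spec: (kind, kernel, stride, padding, out_channels); out_channels is
# ignored for pools. Padding follows each architecture's convention ('same'
# k//2 zero padding, or 'valid').
_THIN = 32  # intermediate width; the final layer carries the true signature

_ARCHS: dict[str, list[tuple]] = {
    "vgg16": [
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", 512), ("pool", 2, 2, "valid", 0),
    ],
    "vgg19": [
        ("conv", 3, 1, "same", _THIN), ("conv", 3, 1, "same", _THIN),
        ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", _THIN), ("pool", 2, 2, "valid", 0),
        ("conv", 3, 1, "same", 512), ("pool", 2, 2, "valid", 0),
    ],
    # stride-32 stem+stages as in the residual family
    "resnet50": [
        ("conv", 7, 2, "same", _THIN), ("pool", 3, 2, "same", 0),
        ("conv", 3, 1, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", 2048),
    ],
    "resnet101": [
        ("conv", 7, 2, "same", _THIN), ("pool", 3, 2, "same", 0),
        ("conv", 3, 1, "same", _THIN), ("conv", 3, 1, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", 2048),
    ],
    "densenet201": [
        ("conv", 7, 2, "same", _THIN), ("pool", 3, 2, "same", 0),
        ("conv", 3, 1, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", _THIN),
        ("conv", 3, 2, "same", 1920),
    ],
    # valid-padded stem as in the Inception family: 256 -> 6
    "inceptionv3": [
        ("conv", 3, 2, "valid", _THIN), ("conv", 3, 1, "valid", _THIN),
        ("conv", 3, 1, "same", _THIN), ("pool", 3, 2, "valid", 0),
        ("conv", 1, 1, "valid", _THIN), ("conv", 3, 1, "valid", _THIN),
        ("pool", 3, 2, "valid", 0),
        ("conv", 3, 2, "valid", _THIN),
        ("conv", 3, 2, "valid", 2048),
    ],
    "random_fallback": [
        ("conv", 3, 2, "same", 32), ("conv", 3, 2, "same", 32),
        ("conv", 3, 2, "same", 48), ("conv", 3, 2, "same", 64),
        ("conv", 3, 2, "same", 64),
    ],
}

REGISTRY_NAMES = tuple(_ARCHS)

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def _out_len(n: int, k: int, s: int, pad: str) -> int:
    p = k // 2 if pad == "same" else 0
    return (n + 2 * p - k) // s + 1


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: str) -> np.ndarray:
    """x: (H, W, Cin), w: (k, k, Cin, Cout) -> (Hout, Wout, Cout)."""
    k = w.shape[0]
    if pad == "same" and k > 1:
        p = k // 2
        x = np.pad(x, ((p, p), (p, p), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(0, 1))  # (H', W', C, k, k)
    win = win[::stride, ::stride]
    h, wd = win.shape[:2]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, k * k * x.shape[2])
    wmat = w.reshape(k * k * w.shape[2], w.shape[3])
    return (cols @ wmat).reshape(h, wd, w.shape[3])


def _maxpool2d(x: np.ndarray, k: int, stride: int, pad: str) -> np.ndarray:
    if pad == "same" and k > 1:
        p = k // 2
        x = np.pad(x, ((p, p), (p, p), (0, 0)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(0, 1))
    return win[::stride, ::stride].max(axis=(3, 4))


class FeatureExtractor:
    """A frozen seeded random-weight convolutional feature extractor.

    Weights are drawn once at construction (He-scaled Gaussians) and never
    mutated; the same (name, seed) always yields the same parameters, and the
    same input always yields the same output.
    """

    def __init__(self, name: str, seed: int = 0):
        key = name.lower()
        if key not in _ARCHS:
            raise ExtractorError(
                f"unknown extractor {name!r}; valid names: {sorted(_ARCHS)}"
            )
        self.name = key
        self.seed = seed
        self.frozen = True
        rng = np.random.default_rng((zlib.crc32(key.encode()) ^ (seed & 0x7FFFFFFF)))
        self._layers: list[tuple] = []
        cin = 3
        for kind, k, stride, pad, cout in _ARCHS[key]:
            if kind == "conv":
                std = np.sqrt(2.0 / (k * k * cin))
                w = (rng.standard_normal((k, k, cin, cout)) * std).astype(np.float64)
                self._layers.append(("conv", w, stride, pad))
                cin = cout
            else:
                self._layers.append(("pool", k, stride, pad))
        self._out_channels = cin

    # -- contract -----------------------------------------------------------
    def output_shape(self, input_size: int = 256) -> tuple[int, int, int]:
        """(H, W, C) output signature for a square input, by layer arithmetic."""
        n = input_size
        for layer in self._layers:
            if layer[0] == "conv":
                _, w, stride, pad = layer
                n = _out_len(n, w.shape[0], stride, pad)
            else:
                _, k, stride, pad = layer
                n = _out_len(n, k, stride, pad)
        return (n, n, self._out_channels)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for layer in self._layers:
            if layer[0] == "conv":
                h.update(np.ascontiguousarray(layer[1]).tobytes())
        return h.hexdigest()

    def _forward_one(self, img: np.ndarray) -> np.ndarray:
        x = img.transpose(1, 2, 0).astype(np.float64)  # (H, W, 3)
        if self.name != "random_fallback":
            x = (x - _IMAGENET_MEAN) / _IMAGENET_STD
        for layer in self._layers:
            if layer[0] == "conv":
                _, w, stride, pad = layer
                x = np.maximum(_conv2d(x, w, stride, pad), 0.0)
            else:
                _, k, stride, pad = layer
                x = _maxpool2d(x, k, stride, pad)
        return x

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        """batch: (N, 3, H, W) -> (N, Hout, Wout, C)."""
        batch = np.asarray(batch)
        if batch.ndim != 4 or batch.shape[1] != 3:
            raise ValueError(
                f"expected batch of shape (N, 3, H, W), got {batch.shape}"
            )
        return np.stack([self._forward_one(img) for img in batch])


class FeatureMap:
    """Feature tensor for one segment, tagged with its extractor."""

    __slots__ = ("tensor", "extractor_name", "segment_id")

    def __init__(self, tensor: np.ndarray, extractor_name: str, segment_id: str = ""):
        tensor = np.asarray(tensor)
        if not np.all(np.isfinite(tensor)):
            raise ValueError("feature tensor contains non-finite values")
        self.tensor = tensor
        self.extractor_name = extractor_name
        self.segment_id = segment_id


def get_extractor(name: str, pretrained: bool = False, seed: int = 0) -> FeatureExtractor:
    """Look up a frozen extractor by architecture name.

    Only seeded random-weight instances are available (``pretrained=False``);
    requesting pretrained ImageNet weights raises, since no deep-learning
    runtime or weight bundle ships with this package.
    """
    if pretrained:
        raise ExtractorError(
            "pretrained ImageNet weights are not available: they require a "
            "deep-learning runtime and a network download; use pretrained=False "
            "for the seeded random-weight extractor"
        )
    return FeatureExtractor(name, seed=seed)


def extract_features(
    extractor: FeatureExtractor, stacks
) -> list[FeatureMap]:
    """Apply a frozen extractor to a batch of spectrogram stacks.

    Accepts SpectrogramStack objects or a (N, 3, 256, 256) array. The batch
    result equals the concatenation of single-item results (the forward pass
    is per-sample), and the extractor's parameters are never touched.
    """
    if isinstance(stacks, np.ndarray):
        arrs = stacks
        ids = [""] * len(stacks)
    else:
        arrs = np.stack([s.channels for s in stacks])
        ids = [s.segment_id for s in stacks]
    exp = (len(arrs), 3, 256, 256)
    if arrs.shape != exp:
        raise ValueError(f"expected stacks of shape {exp}, got {arrs.shape}")
    out = extractor(arrs)
    return [
        FeatureMap(out[i], extractor.name, ids[i]) for i in range(len(arrs))
    ]
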