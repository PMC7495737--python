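"""Parallel multi-width convolution over the attended sentence sequence.

Each kernel of window size w computes ``S_t = ReLU(W · x_{t:t+w-1} + b)`` at
every position (stride 1, 'same' zero padding so the position count is
preserved for the capsule stage), and the per-window feature maps are
concatenated along the feature axis.  Defaults follow the model
configuration: windows 3, 4, 5 with 128 feature maps each (384 features
total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConvKernel:
    """One convolution width: W is [w*d_in, feature_maps], b is [feature_maps]."""

    window: int
    weight: np.ndarray
    bias: np.ndarray

    @property
    def feature_maps(self) -> int:
        return self.bias.shape[0]


@dataclass
class ConvParams:
    kernels: list[ConvKernel]

    @property
    def total_maps(self) -> int:
        return sum(k.feature_maps for k in self.kernels)

    def validate(self, d_in: int) -> None:
        for k in self.kernels:
            if k.window <= 0:
                raise ValueError("window size must be positive")
            if k.weight.shape != (k.window * d_in, k.feature_maps):
                raise ValueError(
                    f"kernel weight shape {k.weight.shape} inconsistent with "
                    f"window {k.window} and input dim {d_in}"
                )

    @classmethod
    def init(
        cls,
        d_in: int,
        windows: tuple[int, ...],
        feature_maps: int,
        rng: np.random.Generator,
    ) -> "ConvParams":
        kernels = []
        for w in windows:
            limit = np.sqrt(6.0 / (w * d_in + feature_maps))
            kernels.append(
                ConvKernel(
                    window=w,
                    weight=rng.uniform(-limit, limit, size=(w * d_in, feature_maps)),
                    bias=np.zeros(feature_maps),
                )
            )
        return cls(kernels=kernels)


def same_pad_amounts(window: int) -> tuple[int, int]:
    """Left/right zero padding giving output length == input length."""
    return (window - 1) // 2, window // 2


def sliding_windows(X: np.ndarray, window: int) -> np.ndarray:
    """[n, d] -> [n, window*d] of zero-padded w-grams (im2col)."""
    n, d = X.shape
    left, right = same_pad_amounts(window)
    Xp = np.pad(X, ((left, right), (0, 0)))
    return np.concatenate([Xp[k : k + n] for k in range(window)], axis=1)


def parallel_convolution(X: np.ndarray, params: ConvParams) -> np.ndarray:
    """Concatenated ReLU feature maps of every kernel width at every position."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("input must be a non-empty [n, d] matrix")
    params.validate(X.shape[1])
    outputs = []
    for k in params.kernels:
        S = sliding_windows(X, k.window) @ k.weight + k.bias
        outputs.append(np.maximum(S, 0.0))
    return np.concatenate(outputs, axis=1)
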