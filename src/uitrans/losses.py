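"""The mixed training objective: volumetric mean absolute error plus a
lambda-weighted perceptual loss computed on 2D z-slices and averaged per
volume,

    L_total = L_MAE + lambda * L_perceptual,    lambda = 0.01 by default.

The perceptual term measures the distance between activations of a
frozen 2D convolutional feature pyramid applied slice by slice. Rather
than requiring downloaded pretrained weights, the default extractor is a
fixed, seeded, randomly initialized VGG-style pyramid — random frozen
convolutional features are a well-established stand-in that preserves
the structural-similarity role of the loss and keeps the package fully
deterministic; externally supplied pretrained weights can be dropped in
via ``perceptual_extractor="pretrained_external"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv3d, Module
from .volume import Volume3D

#: Minimum in-plane slice size accepted by the feature pyramid.
MIN_SLICE_SIZE = 8


@dataclass
class LossConfig:
    lambda_weight: float = 0.01
    perceptual_extractor: str = "random_fixed"  # or "pretrained_external"
    perceptual_layers: tuple[int, ...] = (0, 1, 2)
    slice_axis: str = "z"
    extractor_seed: int = 7
    pretrained_weights: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.lambda_weight) or self.lambda_weight < 0:
            raise ValueError("lambda_weight must be finite and >= 0")
        if self.slice_axis != "z":
            raise ValueError("slices are taken along z (x-y planes)")
        if self.perceptual_extractor not in ("random_fixed", "pretrained_external"):
            raise ValueError(
                f"unknown perceptual_extractor {self.perceptual_extractor!r}")
        if (self.perceptual_extractor == "pretrained_external"
                and self.pretrained_weights is None):
            raise ValueError("pretrained_external requires pretrained_weights")

    def to_dict(self) -> dict:
        return {"lambda_weight": self.lambda_weight,
                "perceptual_extractor": self.perceptual_extractor,
                "perceptual_layers": list(self.perceptual_layers),
                "slice_axis": self.slice_axis,
                "extractor_seed": self.extractor_seed,
                "pretrained_weights": self.pretrained_weights}


def _as_tensor5(v) -> Tensor:
    """Coerce Volume3D / (D,H,W) / (N,1,D,H,W) input to a 5D Tensor."""
    if isinstance(v, Volume3D):
        v = v.values
    if isinstance(v, Tensor):
        if v.ndim == 3:
            return ag.reshape(v, (1, 1, *v.shape))
        if v.ndim == 5:
            return v
        raise ValueError(f"expected 3D or 5D tensor, got ndim={v.ndim}")
    arr = np.asarray(v, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None, None]
    if arr.ndim != 5:
        raise ValueError(f"expected 3D or 5D array, got ndim={arr.ndim}")
    return Tensor(arr)


def _check_shapes(a: Tensor, b: Tensor):
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")


def mae_loss(v, v_hat) -> Tensor:
    """Mean absolute voxelwise difference (1/(DHW)) sum |V - V_hat|."""
    a, b = _as_tensor5(v), _as_tensor5(v_hat)
    _check_shapes(a, b)
    return ag.mean(ag.abs_(a - b))


class PerceptualExtractor(Module):
    """Frozen VGG-style 2D feature pyramid, applied per z-slice.

    Slices enter as a batch of 3-channel 2D images (the single channel is
    replicated, the usual RGB input convention); features are tapped
    after each resolution block.
    """

    def __init__(self, seed: int = 7):
        rng = np.random.default_rng(seed)
        k, s = (1, 3, 3), (1, 2, 2)
        self.conv1 = Conv3d(rng, 3, 8, kernel=k)
        self.pool1 = Conv3d(rng, 8, 8, kernel=k, stride=s)
        self.conv2 = Conv3d(rng, 8, 16, kernel=k)
        self.pool2 = Conv3d(rng, 16, 16, kernel=k, stride=s)
        self.conv3 = Conv3d(rng, 16, 16, kernel=k)
        for p in self.parameters():
            p.requires_grad = False

    def load_weights(self, path: str | Path):
        with np.load(Path(path), allow_pickle=False) as archive:
            keys = sorted(archive.files)
            self.load_state_arrays([archive[k] for k in keys])

    def features(self, x: Tensor) -> list[Tensor]:
        t0 = ag.leaky_relu(self.conv1(x), 0.01)
        x = ag.leaky_relu(self.pool1(t0), 0.01)
        t1 = ag.leaky_relu(self.conv2(x), 0.01)
        x = ag.leaky_relu(self.pool2(t1), 0.01)
        t2 = ag.leaky_relu(self.conv3(x), 0.01)
        return [t0, t1, t2]


_EXTRACTOR_CACHE: dict[tuple, PerceptualExtractor] = {}


def get_extractor(config: LossConfig) -> PerceptualExtractor:
    key = (config.perceptual_extractor, config.extractor_seed,
           config.pretrained_weights)
    if key not in _EXTRACTOR_CACHE:
        ext = PerceptualExtractor(config.extractor_seed)
        if config.perceptual_extractor == "pretrained_external":
            ext.load_weights(config.pretrained_weights)
        _EXTRACTOR_CACHE[key] = ext
    return _EXTRACTOR_CACHE[key]


def _slices_as_batch(v: Tensor) -> Tensor:
    """(N,1,D,H,W) -> (N*D, 3, 1, H, W): z-slices as 3-channel 2D images."""
    N, C, D, H, W = v.shape
    if min(H, W) < MIN_SLICE_SIZE:
        raise ValueError(
            f"slice size {(H, W)} below the extractor minimum of "
            f"{MIN_SLICE_SIZE} pixels per in-plane axis")
    x = ag.transpose(v, (0, 2, 1, 3, 4))  # (N,D,1,H,W)
    x = ag.reshape(x, (N * D, 1, 1, H, W))
    return ag.concat([x, x, x], axis=1)


def perceptual_loss(v, v_hat, config: LossConfig | None = None) -> Tensor:
    """Mean squared feature distance at the configured pyramid taps,
    averaged over z-slices (per-volume average) and taps. Symmetric, >= 0,
    zero iff the feature activations coincide.
    """
    config = config or LossConfig()
    a, b = _as_tensor5(v), _as_tensor5(v_hat)
    _check_shapes(a, b)
    ext = get_extractor(config)
    fa = ext.features(_slices_as_batch(a))
    fb = ext.features(_slices_as_batch(b))
    terms = []
    for idx in config.perceptual_layers:
        diff = fa[idx] - fb[idx]
        terms.append(ag.mean(diff * diff))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def loss_terms(v, v_hat, config: LossConfig | None = None) -> dict:
    """All loss terms as Tensors: {"total", "mae", "perceptual", "lambda"}.

    With lambda = 0 the perceptual pyramid is skipped entirely and
    "perceptual" is None; L_total then equals L_MAE exactly.
    """
    config = config or LossConfig()
    mae = mae_loss(v, v_hat)
    if config.lambda_weight == 0:
        return {"total": mae, "mae": mae, "perceptual": None,
                "lambda": config.lambda_weight}
    perc = perceptual_loss(v, v_hat, config)
    return {"total": mae + config.lambda_weight * perc, "mae": mae,
            "perceptual": perc, "lambda": config.lambda_weight}


def total_loss(v, v_hat, config: LossConfig | None = None) -> Tensor:
    """L_total = L_MAE + lambda * L_perceptual."""
    return loss_terms(v, v_hat, config)["total"]
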