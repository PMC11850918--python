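"""Tiled inference: restore arbitrarily sized volumes with a trained
network by mosaicking overlapping tiles blended with a tapered-cosine
window (flat interior, cosine ramps over the overlap), normalized so the
blending weights sum to one at every voxel.
"""

from __future__ import annotations

import numpy as np

from .model import ShapeError, UITransNet
from .nn import autograd as ag
from .volume import Volume3D


def _tile_window(tile: tuple[int, int, int], overlap: int) -> np.ndarray:
    axes = []
    for n in tile:
        w = np.ones(n, dtype=np.float32)
        if overlap > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(overlap) + 0.5)
                                       / overlap))
            w[:overlap] = ramp
            w[-overlap:] = ramp[::-1]
        axes.append(w)
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def _starts(total: int, tile: int, step: int) -> list[int]:
    if total <= tile:
        return [0]
    starts = list(range(0, total - tile, step))
    starts.append(total - tile)
    return starts


def tiled_restore(net: UITransNet, volume, tile=(32, 32, 32),
                  overlap: int = 8) -> np.ndarray:
    """Blend per-tile forward passes into a full-size restored volume.

    Tile dims must be divisible by 2**n_stages; the volume is
    reflect-padded when smaller than one tile. Output shape equals input
    shape; the final activation from the network config is applied once
    at the end.
    """
    v = volume.values if isinstance(volume, Volume3D) else np.asarray(
        volume, dtype=np.float32)
    tile = tuple(int(t) for t in tile)
    req = 2 ** net.config.n_stages
    if any(t % req for t in tile):
        raise ShapeError(
            f"tile dims {tile} must be divisible by 2**n_stages = {req}")
    if overlap < 0 or overlap >= min(tile) / 2:
        raise ValueError("need 0 <= overlap < min(tile)/2")
    orig_shape = v.shape
    pad = [(0, max(0, t - s)) for t, s in zip(tile, orig_shape)]
    if any(p[1] for p in pad):
        v = np.pad(v, pad, mode="reflect")
    step = tuple(t - overlap for t in tile)
    window = _tile_window(tile, overlap)
    out = np.zeros(v.shape, dtype=np.float64)
    wsum = np.zeros(v.shape, dtype=np.float64)
    for sz in _starts(v.shape[0], tile[0], step[0]):
        for sy in _starts(v.shape[1], tile[1], step[1]):
            for sx in _starts(v.shape[2], tile[2], step[2]):
                sl = (slice(sz, sz + tile[0]), slice(sy, sy + tile[1]),
                      slice(sx, sx + tile[2]))
                with ag.no_grad():
                    pred = net.forward(v[sl]).data[0, 0]
                out[sl] += pred * window
                wsum[sl] += window
    result = (out / wsum).astype(np.float32)
    result = result[tuple(slice(0, s) for s in orig_shape)]
    if net.config.final_activation == "clamp01":
        result = np.clip(result, 0.0, 1.0)
    return result


def blending_weight_field(shape: tuple[int, int, int], tile, overlap: int,
                          normalized: bool = True) -> np.ndarray:
    """Blend-weight sum over a volume. With ``normalized=True`` this is
    the effective per-voxel weight total actually applied by
    :func:`tiled_restore` (its mosaic divides by the accumulated weights,
    so the effective total is 1 everywhere); the raw accumulation is
    available with ``normalized=False``.
    """
    tile = tuple(int(t) for t in tile)
    step = tuple(t - overlap for t in tile)
    window = _tile_window(tile, overlap)
    wsum = np.zeros(shape, dtype=np.float64)
    for sz in _starts(shape[0], tile[0], step[0]):
        for sy in _starts(shape[1], tile[1], step[1]):
            for sx in _starts(shape[2], tile[2], step[2]):
                wsum[sz:sz + tile[0], sy:sy + tile[1], sx:sx + tile[2]] += window
    if normalized:
        return wsum / wsum
    return wsum
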