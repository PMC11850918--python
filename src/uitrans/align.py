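"""Rigid pixel-level registration of input/ground-truth volume pairs.

Paired acquisitions from the two LSFM modes are nominally pixel-aligned,
but stage drift between passes can introduce small integer-voxel offsets.
Alignment is an exhaustive search over integer translations in all three
directions, maximizing the Pearson correlation computed on the
overlapping region only (no zero-fill bias). Ties are broken by smallest
shift magnitude, then lexicographically. Above ``COARSE_THRESHOLD`` the
search runs coarse-to-fine (2x-downsampled prescan, then local
refinement) purely for speed; results below that are exhaustive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .volume import Volume3D

COARSE_THRESHOLD = 8


class NoSignalError(ValueError):
    """Raised when a volume has no variance to align on."""


@dataclass(frozen=True)
class ShiftVector:
    dz: int
    dy: int
    dx: int
    pearson_at_best: float

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.dz, self.dy, self.dx)


def _vals(v) -> np.ndarray:
    return v.values if isinstance(v, Volume3D) else np.asarray(v, np.float32)


def _overlap_pearson(moving: np.ndarray, reference: np.ndarray,
                     shift: tuple[int, int, int]) -> float:
    """Pearson between reference and moving translated by ``shift``,
    over the overlapping region only. Translating by +d means moving
    content moves toward higher indices.
    """
    slices_ref, slices_mov = [], []
    for d, n in zip(shift, reference.shape):
        if abs(d) >= n:
            return -np.inf
        if d >= 0:
            slices_ref.append(slice(d, n))
            slices_mov.append(slice(0, n - d))
        else:
            slices_ref.append(slice(0, n + d))
            slices_mov.append(slice(-d, n))
    a = reference[tuple(slices_ref)].ravel().astype(np.float64)
    b = moving[tuple(slices_mov)].ravel().astype(np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _search(moving, reference, candidates) -> ShiftVector:
    best = None
    for shift in candidates:
        p = _overlap_pearson(moving, reference, shift)
        key = (-p, sum(abs(c) for c in shift), shift)
        if best is None or key < best[0]:
            best = (key, shift, p)
    _, shift, p = best
    return ShiftVector(*shift, pearson_at_best=p)


def _apply_shift(moving: np.ndarray, shift: tuple[int, int, int],
                 pad_value: float) -> np.ndarray:
    out = np.full_like(moving, pad_value)
    src, dst = [], []
    for d, n in zip(shift, moving.shape):
        if d >= 0:
            dst.append(slice(d, n))
            src.append(slice(0, n - d))
        else:
            dst.append(slice(0, n + d))
            src.append(slice(-d, n))
    out[tuple(dst)] = moving[tuple(src)]
    return out


def rigid_align(moving, reference, max_shift: int = 8
                ) -> tuple[ShiftVector, Volume3D]:
    """Find the integer translation of ``moving`` maximizing Pearson
    correlation with ``reference``; returns the shift and the shifted
    volume (padded with the background estimate, the moving median).
    """
    mov, ref = _vals(moving), _vals(reference)
    if mov.shape != ref.shape:
        raise ValueError(f"shapes differ: {mov.shape} vs {ref.shape}")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if mov.std() == 0 or ref.std() == 0:
        raise NoSignalError("constant volume: nothing to align on")
    if max_shift == 0:
        best = ShiftVector(0, 0, 0, _overlap_pearson(mov, ref, (0, 0, 0)))
    elif max_shift <= COARSE_THRESHOLD:
        rng = range(-max_shift, max_shift + 1)
        best = _search(mov, ref, itertools.product(rng, rng, rng))
    else:
        # coarse-to-fine: 2x-downsampled exhaustive prescan, then +-2 refine
        mov2, ref2 = mov[::2, ::2, ::2], ref[::2, ::2, ::2]
        half = (max_shift + 1) // 2
        rng = range(-half, half + 1)
        coarse = _search(mov2, ref2, itertools.product(rng, rng, rng))
        center = tuple(2 * c for c in coarse.as_tuple)
        cand = []
        for dz in range(center[0] - 2, center[0] + 3):
            for dy in range(center[1] - 2, center[1] + 3):
                for dx in range(center[2] - 2, center[2] + 3):
                    if max(abs(dz), abs(dy), abs(dx)) <= max_shift:
                        cand.append((dz, dy, dx))
        best = _search(mov, ref, cand)
    pad = float(np.median(mov))
    aligned = _apply_shift(mov, best.as_tuple, pad)
    voxel = (moving.voxel_size_um if isinstance(moving, Volume3D)
             else Volume3D(mov).voxel_size_um)
    return best, Volume3D(aligned, voxel)


def normalize_volume(volume, lo_pct: float = 0.1, hi_pct: float = 99.9):
    """Affine map sending the lo/hi percentiles to 0/1, clipped to [0, 1].

    A constant volume maps to all-0.5 (with a warning), since no contrast
    exists to normalize.
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    v = _vals(volume)
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    if hi == lo:
        import warnings
        warnings.warn("constant volume: normalization returns 0.5 everywhere")
        out = np.full_like(v, 0.5)
    else:
        out = np.clip((v - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    if isinstance(volume, Volume3D):
        return volume.with_values(out)
    return out


def crop_to_size(volume, size: tuple[int, int, int], anchor: str = "center"):
    """Exact-size crop at the given anchor ('center' or 'corner')."""
    v = _vals(volume)
    size = tuple(int(s) for s in size)
    if any(s > n for s, n in zip(size, v.shape)):
        raise ValueError(f"crop size {size} exceeds volume shape {v.shape}")
    if anchor == "center":
        starts = [(n - s) // 2 for s, n in zip(size, v.shape)]
    elif anchor == "corner":
        starts = [0, 0, 0]
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    out = v[tuple(slice(st, st + s) for st, s in zip(starts, size))].copy()
    if isinstance(volume, Volume3D):
        return volume.with_values(out)
    return out
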