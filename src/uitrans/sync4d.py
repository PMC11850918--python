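"""Post-acquisition cardiac-cycle synchronization for 4D reconstruction.

A beating heart is filmed one z-plane at a time (a long time series per
slice); because acquisition of different slices starts at arbitrary
cardiac phases, the slices must be phase-aligned before they can be
assembled into time-resolved volumes. The synchronization signal is the
per-frame mean intensity within an automatically selected high-variance
region of each slice movie; the heartbeat period is estimated from its
autocorrelation, and per-slice phase offsets are chained pairwise by
maximizing the circular cross-correlation of period-folded traces of
adjacent slices. Phase binning uses nearest-frame assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import DEFAULT_VOXEL_SIZE_UM, Volume3D
from .synthetic import BeatingPhantom4D, DegradationParams, degrade, Phantom3D

#: Minimum normalized autocorrelation peak accepted as periodic.
PERIODICITY_THRESHOLD = 0.1
#: Minimum adjacent-slice trace correlation; below this the previous
#: slice offset is propagated with a warning.
CHAIN_CORR_THRESHOLD = 0.2
#: Fraction of highest-variance pixels used as the synchronization ROI.
ROI_FRACTION = 0.25


class AperiodicSignalError(ValueError):
    """No significant periodicity found in the intensity trace."""


@dataclass
class SliceMovieSet:
    """Per-z-slice time series: movies[z] has shape (T, H, W)."""

    movies: list[np.ndarray]
    frame_interval_ms: float = 3.0

    def __post_init__(self):
        if not self.movies:
            raise ValueError("movie list must be non-empty")
        self.movies = [np.asarray(m, dtype=np.float32) for m in self.movies]
        shapes = {m.shape for m in self.movies}
        if len(shapes) != 1 or self.movies[0].ndim != 3:
            raise ValueError("all movies must share one (T, H, W) shape")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.movies)

    @property
    def n_frames(self) -> int:
        return self.movies[0].shape[0]


@dataclass
class Heartbeat4D:
    """One reconstructed volume per cardiac phase bin."""

    volumes: list[Volume3D]
    period_frames: int
    slice_offsets: list[int]

    def __post_init__(self):
        if len(self.volumes) != self.period_frames:
            raise ValueError("need exactly one volume per phase bin")


# -- period estimation ---------------------------------------------------------


def _roi_trace(movie: np.ndarray) -> np.ndarray:
    """Mean intensity per frame within the top-variance pixel region."""
    var = movie.var(axis=0)
    if var.max() == 0:
        return movie.mean(axis=(1, 2))
    thr = np.quantile(var, 1.0 - ROI_FRACTION)
    roi = var >= thr
    return movie[:, roi].mean(axis=1)


def estimate_period(movie: np.ndarray, min_period: int = 2) -> int:
    """Heartbeat period in frames from the autocorrelation of the
    mean-intensity trace: the dominant peak (excluding lag 0), refined to
    sub-frame precision by parabolic interpolation and reported rounded.
    """
    movie = np.asarray(movie, dtype=np.float32)
    if movie.ndim != 3 or movie.shape[0] < 3:
        raise ValueError("movie must be (T, H, W) with T >= 3")
    trace = _roi_trace(movie).astype(np.float64)
    trace = trace - trace.mean()
    if trace.std() == 0:
        raise AperiodicSignalError("constant intensity trace")
    T = trace.size
    r = np.correlate(trace, trace, mode="full")[T - 1:]
    r /= r[0]
    max_lag = T // 2
    lags = np.arange(min_period, max_lag)
    if lags.size == 0:
        raise AperiodicSignalError("trace too short for period estimation")
    seg = r[min_period:max_lag]
    # local maxima only, so a slowly decaying r(1) cannot win
    local = np.zeros_like(seg, dtype=bool)
    local[1:-1] = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    # significance: fixed floor plus the white-noise envelope (r_k of an
    # uncorrelated trace has sd ~ 1/sqrt(T); 4 sd rejects its maxima)
    threshold = max(PERIODICITY_THRESHOLD, 4.0 / np.sqrt(T))
    if not local.any() or seg[local].max() < threshold:
        raise AperiodicSignalError(
            f"no autocorrelation peak above the significance threshold "
            f"({threshold:.3f})")
    k = int(lags[local][np.argmax(seg[local])])
    # parabolic sub-frame refinement around the peak
    if 1 <= k < r.size - 1:
        y0, y1, y2 = r[k - 1], r[k], r[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k = k + 0.5 * (y0 - y2) / denom
    return int(round(k))


# -- phase synchronization -----------------------------------------------------


def _fold_movie(movie: np.ndarray, period: int) -> np.ndarray:
    """Per-pixel average cycle: (P, H, W) mean over congruent phases."""
    T = movie.shape[0]
    n = (T // period) * period
    return movie[:n].reshape(-1, period, *movie.shape[1:]).mean(axis=0)


def _circular_offset(ref_cycle: np.ndarray, cycle: np.ndarray
                     ) -> tuple[int, float]:
    """Shift d maximizing the image correlation between ref_cycle[p] and
    cycle[(p + d) mod P], both (P, n_pixels) folded cycles.

    A scalar intensity trace can frequency-double under symmetric
    dilation/contraction (making offsets ambiguous modulo half a period);
    correlating the full per-pixel cycles removes that degeneracy.
    """
    P = ref_cycle.shape[0]
    a = (ref_cycle - ref_cycle.mean()).ravel()
    na = np.sqrt((a * a).sum())
    best_d, best_c = 0, -np.inf
    for d in range(P):
        b = (np.roll(cycle, -d, axis=0) - cycle.mean()).ravel()
        denom = na * np.sqrt((b * b).sum())
        c = (a * b).sum() / denom if denom > 0 else -np.inf
        if c > best_c:
            best_d, best_c = d, float(c)
    return best_d, best_c


def synchronize_movies(movies: SliceMovieSet, period_frames: int | None = None,
                       voxel_size_um=DEFAULT_VOXEL_SIZE_UM) -> Heartbeat4D:
    """Phase-align per-slice movies and assemble per-phase volumes.

    Offsets are chained: slice 0 defines phase zero (offset 0), and each
    subsequent slice's offset maximizes the circular cross-correlation of
    its period-folded intensity trace with its neighbor's. The volume for
    phase p takes slice z's frame (p + offset_z) mod period.
    """
    if period_frames is None:
        period_frames = estimate_period(movies.movies[0])
    period = int(period_frames)
    if movies.n_frames < 2 * period:
        raise ValueError(
            f"need at least two periods of data ({2 * period} frames), "
            f"got {movies.n_frames}")
    # validate a shared period across slices (spot-check every slice)
    for z, m in enumerate(movies.movies):
        try:
            pz = estimate_period(m)
        except AperiodicSignalError:
            continue
        if abs(pz - period) > 1:
            raise ValueError(
                f"slice {z} has period {pz}, inconsistent with {period}")
    cycles = [_fold_movie(m, period).astype(np.float64)
              for m in movies.movies]
    # chain outward from the slice with the strongest beating signal, so
    # weak (near-empty) edge slices cannot corrupt downstream links
    strength = [float(np.var(c, axis=0).mean()) for c in cycles]
    ref = int(np.argmax(strength))
    offsets = [0] * movies.n_slices
    for z in list(range(ref + 1, movies.n_slices)) + \
            list(range(ref - 1, -1, -1)):
        prev = z - 1 if z > ref else z + 1
        d, corr = _circular_offset(cycles[prev], cycles[z])
        if corr < CHAIN_CORR_THRESHOLD:
            warnings.warn(
                f"slice {z}: adjacent-slice correlation {corr:.2f} below "
                f"{CHAIN_CORR_THRESHOLD}; propagating previous offset")
            d = 0
        offsets[z] = (offsets[prev] + d) % period
    volumes = []
    for p in range(period):
        planes = [movies.movies[z][(p + offsets[z]) % period]
                  for z in range(movies.n_slices)]
        volumes.append(Volume3D(np.stack(planes), tuple(voxel_size_um)))
    return Heartbeat4D(volumes, period, offsets)


# -- synthetic movie generation (ground truth for recovery tests) --------------


def movies_from_beating(beating: BeatingPhantom4D, n_frames: int,
                        slice_offsets: list[int] | None = None,
                        params: DegradationParams | None = None,
                        seed: int = 0, noise: bool = True,
                        frame_interval_ms: float = 3.0) -> SliceMovieSet:
    """Re-slice a beating phantom into per-z movies with known per-slice
    phase offsets (each slice's acquisition starts at its own cardiac
    phase), optionally degraded through the LSFM forward model. With
    ``noise=False`` only the deterministic optics (PSF blur + haze) are
    applied — a noise-free acquisition still passes through the
    microscope.
    """
    from .synthetic import add_scatter_haze, apply_psf, child_seeds

    period = beating.period_frames
    n_z = beating.frames[0].shape[0]
    if slice_offsets is None:
        slice_offsets = [0] * n_z
    if len(slice_offsets) != n_z:
        raise ValueError("need one offset per z slice")
    # deterministic optics (blur + haze) per cardiac phase; noise is drawn
    # per (slice, frame) since every plane is a separate camera exposure
    source: list[np.ndarray] = []
    for frame in beating.frames[:period]:
        if params is not None:
            vol = add_scatter_haze(apply_psf(frame.as_volume(), params), params)
            source.append(vol.values)
        else:
            source.append(frame.values)
    movies = []
    slice_seeds = child_seeds(seed, n_z)
    for z in range(n_z):
        rng = np.random.default_rng(slice_seeds[z])
        frames = []
        for t in range(int(n_frames)):
            plane = source[(t + slice_offsets[z]) % period][z]
            if params is not None and noise:
                noisy = rng.poisson(
                    params.photon_gain * np.clip(plane, 0, None).astype(np.float64)
                ) / params.photon_gain
                if params.read_sigma > 0:
                    noisy = noisy + rng.normal(0.0, params.read_sigma,
                                               size=plane.shape)
                plane = noisy.astype(np.float32)
            frames.append(plane)
        movies.append(np.stack(frames))
    return SliceMovieSet(movies, frame_interval_ms)
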