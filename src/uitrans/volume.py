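"""Single-channel 3D volumes with voxel-size metadata, plus TIFF I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Default physical sampling (z, y, x) in micrometres per voxel.
DEFAULT_VOXEL_SIZE_UM = (0.325, 0.325, 0.325)


@dataclass
class Volume3D:
    """A (D, H, W) intensity volume and its voxel size in micrometres."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"invalid voxel size {self.voxel_size_um}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.voxel_size_um)

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(values, self.voxel_size_um)

    def sigma_vox(self, lateral_um: float, axial_um: float) -> tuple[float, float, float]:
        """Convert (axial z, lateral y/x) Gaussian widths from um to voxels."""
        vz, vy, vx = self.voxel_size_um
        return (axial_um / vz, lateral_um / vy, lateral_um / vx)


def write_tiff(path: str | Path, volume: Volume3D, sidecar: dict | None = None):
    """Write a volume as a multi-page (z-plane) 32-bit float TIFF.

    If ``sidecar`` is given, a JSON file with the same stem records it
    together with the voxel size.
    """
    path = Path(path)
    tifffile.imwrite(path, volume.values.astype(np.float32))
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("voxel_size_um", list(volume.voxel_size_um))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_tiff(path: str | Path,
              voxel_size_um: tuple[float, float, float] | None = None) -> Volume3D:
    """Read a multi-page TIFF stack as a Volume3D.

    Voxel size is taken from the JSON sidecar when present, then from the
    ``voxel_size_um`` argument, then the package default.
    """
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float32)
    if values.ndim == 2:
        values = values[None]
    sidecar = path.with_suffix(".json")
    if voxel_size_um is None and sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
            voxel_size_um = tuple(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM))
        except (json.JSONDecodeError, TypeError):
            voxel_size_um = None
    return Volume3D(values, voxel_size_um or DEFAULT_VOXEL_SIZE_UM)
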