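"""Reading, writing and resampling of cryo-EM density maps (MRC2014).

Maps are held as a :class:`DensityMap`: a 3D float32 grid indexed ``[ix, iy, iz]``
in Cartesian X, Y, Z order, together with the (isotropic) voxel size in
Angstrom, the Cartesian origin of voxel ``(0, 0, 0)``, and the map sigma
(root-mean-square spread of the density values, the EM-community density unit).

All downstream thresholds in this package (annotation gates, segment filters,
evaluation gates) are expressed in multiples of sigma, so maps are normalized
with :func:`normalize_sigma` before annotation or prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DensityMap",
    "MapFormatError",
    "DegenerateMapError",
    "read_mrc",
    "write_mrc",
    "compute_sigma",
    "normalize_sigma",
    "rescale_voxel_size",
    "VOXEL_WINDOW",
    "TARGET_VOXEL",
]

#: Accepted voxel-size window in Angstrom; maps outside are resampled.
VOXEL_WINDOW = (1.0, 1.2)
#: Voxel size maps are resampled to when outside the window.
TARGET_VOXEL = 1.1

_ISO_RTOL = 1e-3  # relative tolerance for calling a voxel size isotropic


class MapFormatError(ValueError):
    """Raised for malformed or unsupported map files."""


class DegenerateMapError(ValueError):
    """Raised when an operation requires a non-constant density grid."""


@dataclass
class DensityMap:
    """A 3D scalar density grid with Cartesian registration metadata."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise MapFormatError(f"grid must be 3D with all dims >= 1, got shape {self.grid.shape}")
        if not (self.voxel_size > 0):
            raise MapFormatError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def index_to_cartesian(self, idx: np.ndarray) -> np.ndarray:
        """Cartesian Angstrom position of (fractional) voxel index ``idx``."""
        return self.origin + np.asarray(idx, dtype=np.float64) * self.voxel_size

    def cartesian_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a Cartesian Angstrom position."""
        return (np.asarray(xyz, dtype=np.float64) - self.origin) / self.voxel_size

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated density at Cartesian positions (N, 3).

        Positions outside the grid sample 0 (the mean level of a
        sigma-normalized map).
        """
        pts = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        idx = (pts - self.origin) / self.voxel_size
        return map_coordinates(self.grid.astype(np.float64), idx.T, order=1,
                               mode="constant", cval=0.0)


def read_mrc(path: str) -> DensityMap:
    """Read an MRC2014 volume, reordering axes to X, Y, Z.

    The voxel size and origin come from the header; the grid is reordered
    according to MAPC/MAPR/MAPS so that index ``[ix, iy, iz]`` always walks
    Cartesian X, Y, Z. The header RMS field is adopted as ``sigma`` when it is
    positive; otherwise ``sigma`` is left unset.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC file {path!r}: {exc}") from exc
    # header word 4: MODE; only float maps (mode 2) and integer modes gemmi
    # converts to float are meaningful densities here
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid, copy=True)
    if grid.ndim != 3:
        raise MapFormatError(f"map data in {path!r} is not a 3D volume")
    sx, sy, sz = ccp4.grid.spacing
    if min(sx, sy, sz) <= 0:
        raise MapFormatError(f"non-positive voxel size {(sx, sy, sz)} in {path!r}")
    mean_s = (sx + sy + sz) / 3.0
    if max(abs(sx - mean_s), abs(sy - mean_s), abs(sz - mean_s)) > _ISO_RTOL * mean_s:
        raise MapFormatError(
            f"anisotropic voxel size {(sx, sy, sz)} in {path!r}; only isotropic maps are supported")
    # ORIGIN record (words 50-52) takes precedence; fall back to NXSTART-style
    # offsets expressed on the X,Y,Z-ordered grid.
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    if np.all(origin == 0.0):
        axis_pos = ccp4.axis_positions()  # file axis -> position of X,Y,Z
        starts_file = [ccp4.header_i32(w) for w in (5, 6, 7)]
        starts = [0, 0, 0]
        for file_axis, xyz_axis in enumerate(axis_pos):
            starts[xyz_axis] = starts_file[file_axis]
        origin = np.array(starts, dtype=np.float64) * mean_s
    rms = float(ccp4.header_float(55))
    return DensityMap(grid=grid, voxel_size=float(mean_s), origin=origin,
                      sigma=rms if rms > 0 else None)


def write_mrc(dmap: DensityMap, path: str) -> None:
    """Write a map as MRC2014 mode 2 (float32).

    The RMS header field is recomputed from the grid, never copied from
    ``dmap.sigma``, so the header always describes the data actually written.
    """
    data = np.ascontiguousarray(dmap.grid, dtype=np.float32)
    grid = gemmi.FloatGrid(data)
    n = data.shape
    grid.set_unit_cell(gemmi.UnitCell(n[0] * dmap.voxel_size, n[1] * dmap.voxel_size,
                                      n[2] * dmap.voxel_size, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)  # mode 2 + recompute DMIN/DMAX/DMEAN/RMS
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write MRC file {path!r}: {exc}") from exc


def compute_sigma(dmap: DensityMap) -> float:
    """Map sigma: the r.m.s. spread (standard deviation) of all voxel values.

    Stored on the map as ``dmap.sigma``. Raises :class:`DegenerateMapError`
    for a constant grid.
    """
    g = dmap.grid.astype(np.float64)
    sigma = float(g.std())
    if sigma == 0.0 or not math.isfinite(sigma):
        raise DegenerateMapError("density grid is constant; sigma is undefined")
    dmap.sigma = sigma
    return sigma


def normalize_sigma(dmap: DensityMap) -> DensityMap:
    """Return a new map in sigma units: zero mean, unit r.m.s. spread."""
    g = dmap.grid.astype(np.float64)
    sigma = compute_sigma(dmap)
    out = ((g - g.mean()) / sigma).astype(np.float32)
    return DensityMap(grid=out, voxel_size=dmap.voxel_size,
                      origin=dmap.origin.copy(), sigma=1.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rescale_voxel_size(dmap: DensityMap, target: float = TARGET_VOXEL,
                       window: tuple = VOXEL_WINDOW) -> DensityMap:
    """Resample a map to ``target`` Angstrom/voxel if outside ``window``.

    Maps already inside the window are returned unchanged (same object).
    Resampling is trilinear, preserves the Cartesian origin and extent
    (up to rounding of the new dimension counts), and samples 0 outside
    the original grid.
    """
    if window[0] <= dmap.voxel_size <= window[1]:
        return dmap
    new_shape = tuple(max(1, _round_half_away(n * dmap.voxel_size / target))
                      for n in dmap.shape)
    scale = target / dmap.voxel_size  # new index -> old index factor
    axes = [np.arange(n, dtype=np.float64) * scale for n in new_shape]
    coords = np.meshgrid(*axes, indexing="ij")
    new_grid = map_coordinates(dmap.grid.astype(np.float64), coords, order=1,
                               mode="constant", cval=0.0).astype(np.float32)
    out = DensityMap(grid=new_grid, voxel_size=target, origin=dmap.origin.copy())
    if float(new_grid.std()) > 0:
        compute_sigma(out)
    return out
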