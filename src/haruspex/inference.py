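"""Whole-map prediction: tiling, stitching, and density partitioning.

A sigma-normalized map is covered by non-overlapping 20^3 output tiles, each
predicted from its 40^3 input window (the tile dilated by 10 voxels of
context, zero-padded beyond the map edge, 0 being the mean level after
normalization). Every voxel belongs to exactly one tile, so stitching is
seam-free by construction.

The four output maps are formed by argmax partition: each voxel's full input
density goes to its most probable class, so the four maps sum voxelwise to
the input map exactly — together they are the input map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .map_io import (DensityMap, DegenerateMapError, TARGET_VOXEL, VOXEL_WINDOW,
                     normalize_sigma, rescale_voxel_size)
from .model_annotation import CLASSES
from .network import Network
from .training_data import INPUT_SIZE, OUTPUT_SIZE

__all__ = ["PredictionVolume", "tile_map", "predict_map", "partition_density"]

_CTX = (INPUT_SIZE - OUTPUT_SIZE) // 2  # context margin per side


@dataclass
class PredictionVolume:
    """Four co-registered class-probability grids (..., 4), summing to 1."""

    probs: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4 or self.probs.shape[-1] != len(CLASSES):
            raise ValueError(f"probs must be (nx,ny,nz,{len(CLASSES)})")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.probs.shape[:3]

    def argmax_classes(self) -> np.ndarray:
        """Per-voxel winning class index; ties go to the lowest channel."""
        return self.probs.argmax(axis=-1)


def tile_map(dmap: DensityMap) -> List[Tuple[np.ndarray, Tuple[int, int, int]]]:
    """(40^3 input window, output-corner index) pairs covering the map.

    Output tiles of 20^3 at stride 20 cover every voxel exactly once; input
    windows extend 10 voxels beyond each tile face, zero-padded outside the
    map.
    """
    shape = dmap.shape
    grid = dmap.grid
    tiles = []
    for cx in range(0, shape[0], OUTPUT_SIZE):
        for cy in range(0, shape[1], OUTPUT_SIZE):
            for cz in range(0, shape[2], OUTPUT_SIZE):
                window = np.zeros((INPUT_SIZE,) * 3, dtype=np.float32)
                los = np.array([cx, cy, cz]) - _CTX
                his = los + INPUT_SIZE
                src = tuple(slice(max(lo, 0), min(hi, n))
                            for lo, hi, n in zip(los, his, shape))
                dst = tuple(slice(s.start - lo, s.stop - lo)
                            for s, lo in zip(src, los))
                window[dst] = grid[src]
                tiles.append((window, (cx, cy, cz)))
    return tiles


def predict_map(net: Network, dmap: DensityMap) -> PredictionVolume:
    """Full pipeline: normalize, rescale if needed, tile, predict, stitch.

    The returned probabilities are registered to the ORIGINAL input grid: if
    the map was resampled for prediction, probabilities are trilinearly
    resampled back and renormalized per voxel.
    """
    if float(dmap.grid.std()) == 0.0:
        raise DegenerateMapError("cannot predict on a constant map")
    norm = normalize_sigma(dmap)
    work = rescale_voxel_size(norm, TARGET_VOXEL, VOXEL_WINDOW)
    rescaled = work is not norm

    probs = np.zeros(work.shape + (len(CLASSES),), dtype=np.float32)
    for window, (cx, cy, cz) in tile_map(work):
        pred = net.forward_sample(window)
        ex = min(cx + OUTPUT_SIZE, work.shape[0]) - cx
        ey = min(cy + OUTPUT_SIZE, work.shape[1]) - cy
        ez = min(cz + OUTPUT_SIZE, work.shape[2]) - cz
        probs[cx:cx + ex, cy:cy + ey, cz:cz + ez] = pred[:ex, :ey, :ez]

    if rescaled:
        # resample each channel back onto the original grid, then renormalize
        scale = dmap.voxel_size / work.voxel_size
        axes = [np.arange(n, dtype=np.float64) * scale for n in dmap.shape]
        coords = np.meshgrid(*axes, indexing="ij")
        out = np.empty(dmap.shape + (len(CLASSES),), dtype=np.float32)
        for c in range(len(CLASSES)):
            out[..., c] = map_coordinates(probs[..., c].astype(np.float64), coords,
                                          order=1, mode="nearest")
        out = np.clip(out, 0.0, None)
        tot = out.sum(axis=-1, keepdims=True)
        flat = tot[..., 0] <= 0
        out[flat] = 0.0
        out[flat, CLASSES.index("unassigned")] = 1.0
        tot[tot <= 0] = 1.0
        probs = out / tot
    return PredictionVolume(probs=probs, voxel_size=dmap.voxel_size,
                            origin=dmap.origin.copy())


def partition_density(dmap: DensityMap, pv: PredictionVolume) -> List[DensityMap]:
    """Split the input map into four class maps that sum back to it exactly.

    Each voxel's density is copied unmodified into the map of its argmax
    class (ties: lowest channel index); the other three maps get 0 there.
    Returned in channel order helix, sheet, nucleotide, unassigned.
    """
    if pv.shape != dmap.shape:
        raise ValueError("prediction volume and map are not co-registered")
    winner = pv.argmax_classes()
    out = []
    for c in range(len(CLASSES)):
        grid = np.where(winner == c, dmap.grid, np.float32(0.0))
        out.append(DensityMap(grid=grid.astype(np.float32),
                              voxel_size=dmap.voxel_size,
                              origin=dmap.origin.copy()))
    return out
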