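"""Segment extraction, filtering, augmentation and train/eval splitting.

Annotated maps are tiled into non-overlapping 70^3-voxel segments (partial
edge blocks zero-padded, padded voxels excluded from the loss). A segment is
kept only if it passes three content filters: at least 100 model atoms with
interpolated density >= 1 sigma inside it, mean backbone density >= 3 sigma,
and at least 5% of its volume carrying a structural class.

Training samples are 40^3 density crops with the center-aligned 20^3 label
block, augmented by one of the 24 axis-aligned cube rotations and a random
translational offset, and weighted 16:1 in favour of non-unassigned voxels
(excluded voxels get weight 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .map_io import DensityMap
from .model_annotation import StructuralModel
from .voxel_labeling import LabelVolume, UNASSIGNED

__all__ = [
    "SEGMENT_SIZE",
    "INPUT_SIZE",
    "OUTPUT_SIZE",
    "Segment",
    "SegmentFilter",
    "TrainingSample",
    "RotationOp",
    "extract_segments",
    "enumerate_rotations",
    "sample_training_example",
    "voxel_loss_weights",
    "split_segments",
    "POSITIVE_WEIGHT",
]

SEGMENT_SIZE = 70
INPUT_SIZE = 40
OUTPUT_SIZE = 20
_MARGIN = (INPUT_SIZE - OUTPUT_SIZE) // 2   # 10-voxel context on each side
_MAX_OFFSET = SEGMENT_SIZE - INPUT_SIZE     # 30

#: Loss weight of non-unassigned voxels relative to unassigned ones.
POSITIVE_WEIGHT = 16.0


@dataclass
class Segment:
    density: np.ndarray   # (70,70,70) float32, sigma units
    labels: np.ndarray    # (70,70,70) int8
    mask: np.ndarray      # (70,70,70) bool, True -> excluded
    provenance: Tuple[str, Tuple[int, int, int]] = ("", (0, 0, 0))

    def __post_init__(self) -> None:
        want = (SEGMENT_SIZE,) * 3
        for name in ("density", "labels", "mask"):
            arr = getattr(self, name)
            if arr.shape != want:
                raise ValueError(f"segment {name} must have shape {want}, got {arr.shape}")


@dataclass
class SegmentFilter:
    """Content gates a 70^3 segment must pass to enter training."""

    min_atoms: int = 100             # atoms at >= atom_density_floor inside the block
    atom_density_floor: float = 1.0  # sigma
    min_backbone_mean: float = 3.0   # sigma
    min_annotated_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_atoms, self.atom_density_floor, self.min_backbone_mean,
               self.min_annotated_fraction) <= 0:
            raise ValueError("all filter thresholds must be > 0")


@dataclass
class TrainingSample:
    input: np.ndarray    # (40,40,40) float32
    target: np.ndarray   # (20,20,20,4) float32 one-hot
    weight: np.ndarray   # (20,20,20) float32, 0 exactly on excluded voxels


def extract_segments(dmap: DensityMap, model: StructuralModel, lv: LabelVolume,
                     seg_filter: Optional[SegmentFilter] = None,
                     map_id: str = "") -> List[Segment]:
    """Tile a map into filtered 70^3 segments anchored at multiples of 70."""
    f = seg_filter or SegmentFilter()
    if dmap.shape != lv.shape:
        raise ValueError("map and label volume are not co-registered")

    atom_coords = model.all_atom_coords()
    if atom_coords.size:
        atom_vals = dmap.interpolate(atom_coords)
        atom_idx = (atom_coords - dmap.origin) / dmap.voxel_size
    backbone = [xyz for res in model.polymer_residues() for xyz in res.backbone_atoms()]
    backbone = np.array(backbone) if backbone else np.empty((0, 3))
    if backbone.size:
        bb_vals = dmap.interpolate(backbone)
        bb_idx = (backbone - dmap.origin) / dmap.voxel_size

    segments: List[Segment] = []
    S = SEGMENT_SIZE
    shape = dmap.shape
    corners = [range(0, shape[ax], S) for ax in range(3)]
    for cx in corners[0]:
        for cy in corners[1]:
            for cz in corners[2]:
                c = np.array([cx, cy, cz], dtype=np.float64)
                if atom_coords.size == 0:
                    continue
                in_block = np.all((atom_idx >= c) & (atom_idx < c + S), axis=1)
                n_good = int(np.count_nonzero(in_block & (atom_vals >= f.atom_density_floor)))
                if n_good < f.min_atoms:
                    continue
                if backbone.size == 0:
                    continue
                bb_in = np.all((bb_idx >= c) & (bb_idx < c + S), axis=1)
                if not bb_in.any() or bb_vals[bb_in].mean() < f.min_backbone_mean:
                    continue
                density = np.zeros((S, S, S), dtype=np.float32)
                labels = np.full((S, S, S), UNASSIGNED, dtype=np.int8)
                mask = np.ones((S, S, S), dtype=bool)  # padding is excluded
                ex = min(cx + S, shape[0]) - cx
                ey = min(cy + S, shape[1]) - cy
                ez = min(cz + S, shape[2]) - cz
                sl_src = (slice(cx, cx + ex), slice(cy, cy + ey), slice(cz, cz + ez))
                density[:ex, :ey, :ez] = dmap.grid[sl_src]
                labels[:ex, :ey, :ez] = lv.class_grid[sl_src]
                mask[:ex, :ey, :ez] = lv.exclude[sl_src]
                annotated = np.count_nonzero(labels != UNASSIGNED) / labels.size
                if annotated < f.min_annotated_fraction:
                    continue
                segments.append(Segment(density=density, labels=labels, mask=mask,
                                        provenance=(map_id, (cx, cy, cz))))
    return segments


@dataclass(frozen=True)
class RotationOp:
    """One of the 24 orientation-preserving axis-aligned cube rotations.

    ``apply(v)`` transposes axes by ``perm`` then flips the axes listed in
    ``flips``; the corresponding linear map has determinant +1.
    """

    perm: Tuple[int, int, int]
    flips: Tuple[int, ...]

    def apply(self, volume: np.ndarray) -> np.ndarray:
        out = np.transpose(volume, self.perm + tuple(range(3, volume.ndim)))
        if self.flips:
            out = np.flip(out, axis=self.flips)
        return np.ascontiguousarray(out)


def _perm_parity(perm: Sequence[int]) -> int:
    p = list(perm)
    parity = 1
    for i in range(len(p)):
        while p[i] != i:
            j = p[i]
            p[i], p[j] = p[j], p[i]
            parity = -parity
    return parity


def enumerate_rotations() -> List[RotationOp]:
    """The 24 distinct proper 90-degree rotations of a cube, identity first.

    Deterministic order: sorted by (perm, flip set).
    """
    from itertools import permutations, product

    ops = []
    for perm in permutations((0, 1, 2)):
        for signs in product((1, -1), repeat=3):
            det = _perm_parity(perm) * signs[0] * signs[1] * signs[2]
            if det != 1:
                continue
            flips = tuple(ax for ax, s in enumerate(signs) if s < 0)
            ops.append(RotationOp(perm=perm, flips=flips))
    ops.sort(key=lambda op: (op.perm, op.flips))
    return ops


_ROTATIONS = enumerate_rotations()


def voxel_loss_weights(target_classes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel loss weights: 16 for structural classes, 1 for unassigned,
    0 wherever the exclusion mask is set."""
    if target_classes.shape != mask.shape:
        raise ValueError("target and mask shapes differ")
    w = np.where(target_classes != UNASSIGNED, POSITIVE_WEIGHT, 1.0).astype(np.float32)
    w[mask] = 0.0
    return w


def sample_training_example(seg: Segment, rng: np.random.Generator) -> TrainingSample:
    """Rotation + translation augmented (40^3 input, 20^3 target) sample."""
    rot = _ROTATIONS[int(rng.integers(len(_ROTATIONS)))]
    off = rng.integers(0, _MAX_OFFSET + 1, size=3)
    density = rot.apply(seg.density)
    labels = rot.apply(seg.labels)
    mask = rot.apply(seg.mask)
    ox, oy, oz = (int(v) for v in off)
    inp = density[ox:ox + INPUT_SIZE, oy:oy + INPUT_SIZE, oz:oz + INPUT_SIZE]
    tsl = (slice(ox + _MARGIN, ox + _MARGIN + OUTPUT_SIZE),
           slice(oy + _MARGIN, oy + _MARGIN + OUTPUT_SIZE),
           slice(oz + _MARGIN, oz + _MARGIN + OUTPUT_SIZE))
    t_cls = labels[tsl]
    t_mask = mask[tsl]
    onehot = np.zeros(t_cls.shape + (4,), dtype=np.float32)
    for ci in range(4):
        onehot[..., ci] = t_cls == ci
    return TrainingSample(input=np.ascontiguousarray(inp, dtype=np.float32),
                          target=onehot,
                          weight=voxel_loss_weights(t_cls, t_mask))


def center_sample(seg: Segment) -> TrainingSample:
    """Deterministic unaugmented sample: identity rotation, centered crop."""
    off = _MAX_OFFSET // 2
    inp = seg.density[off:off + INPUT_SIZE, off:off + INPUT_SIZE, off:off + INPUT_SIZE]
    tsl = slice(off + _MARGIN, off + _MARGIN + OUTPUT_SIZE)
    t_cls = seg.labels[tsl, tsl, tsl]
    t_mask = seg.mask[tsl, tsl, tsl]
    onehot = np.zeros(t_cls.shape + (4,), dtype=np.float32)
    for ci in range(4):
        onehot[..., ci] = t_cls == ci
    return TrainingSample(input=np.ascontiguousarray(inp, dtype=np.float32),
                          target=onehot,
                          weight=voxel_loss_weights(t_cls, t_mask))


def split_segments(segments: Sequence[Segment], eval_fraction: float = 0.05,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[List[Segment], List[Segment]]:
    """Uniform random disjoint train/eval split; eval gets max(1, round(f*N))."""
    n = len(segments)
    if n < 2:
        raise ValueError(f"need at least 2 segments to split, got {n}")
    rng = rng or np.random.default_rng()
    n_eval = max(1, int(round(eval_fraction * n)))
    order = rng.permutation(n)
    eval_idx = set(int(i) for i in order[:n_eval])
    train = [segments[i] for i in range(n) if i not in eval_idx]
    evals = [segments[i] for i in range(n) if i in eval_idx]
    return train, evals
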