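"""Synthetic structural models and simulated density maps with known truth.

Phantoms exist so that every pipeline stage — annotation, segment extraction,
network training, tiled inference, evaluation — can be exercised without any
archive downloads. Density is a sum of isotropic Gaussians at atom centers
plus optional white noise: adequate for testing the machinery, deliberately
not a claim of realism (experimental reconstructions carry error structure
and processing artifacts that no simple simulator reproduces).

Geometry builders produce ideal backbones from internal coordinates:

* :func:`build_ideal_helix` — alpha-helix, phi=-57, psi=-47, omega=180;
* :func:`build_antiparallel_sheet` — extended strands (phi=-135, psi=135)
  rigid-body refined so that narrow-pair N...O distances hit 2.9 A, giving
  canonical antiparallel hydrogen-bond registry;
* :func:`build_nucleic_chain` — simplified A-form-like single-stranded
  backbone (P, O5', C5', C4', C3', O3') with ~32.7 deg twist and 2.81 A rise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from ._geom import place_atom, rotation_from_axis_angle
from .map_io import DensityMap
from .model_annotation import (Chain, Residue, ResidueLabels, StructuralModel,
                               assign_secondary_structure)

__all__ = [
    "Pose",
    "ElementSpec",
    "PhantomSpec",
    "build_ideal_helix",
    "build_antiparallel_sheet",
    "build_nucleic_chain",
    "build_phantom_model",
    "simulate_density",
    "make_phantom_dataset",
    "random_phantom_spec",
]

# ideal backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -135.0, 135.0


@dataclass
class Pose:
    """Rigid-body placement: y = R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @classmethod
    def random(cls, rng: np.random.Generator, center: Sequence[float]) -> "Pose":
        # uniform rotation from a random quaternion
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        return cls(rotation=R, translation=np.asarray(center, dtype=np.float64))


def _apply_pose(model: StructuralModel, pose: Optional[Pose]) -> StructuralModel:
    if pose is None:
        return model
    # recenter on the model centroid before posing so translation = placement center
    coords = model.all_atom_coords()
    centroid = coords.mean(axis=0)
    for res in model.residues():
        for name in res.atoms:
            res.atoms[name] = pose.apply(res.atoms[name] - centroid)
    return model


def _build_backbone(n: int, phi: float, psi: float, chain_id: str,
                    start_seq: int, res_name: str = "ALA") -> Chain:
    """Ideal polypeptide backbone with constant (phi, psi), omega = 180."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    chain = Chain(chain_id=chain_id)
    for i in range(n):
        O = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        chain.residues.append(Residue(
            chain_id=chain_id, seqid=start_seq + i, icode="", name=res_name,
            kind="aa", atoms={"N": N[i], "CA": CA[i], "C": C[i], "O": O}))
    return chain


def build_ideal_helix(n: int, pose: Optional[Pose] = None,
                      chain_id: str = "A", start_seq: int = 1) -> StructuralModel:
    """Ideal alpha-helix backbone of ``n`` residues (full N, CA, C, O)."""
    if n < 4:
        raise ValueError(f"a helix needs at least 4 residues, got {n}")
    model = StructuralModel(chains=[_build_backbone(n, HELIX_PHI, HELIX_PSI,
                                                    chain_id, start_seq)])
    return _apply_pose(model, pose)


def _refine_strand_transform(base: Chain, flipped_coords: np.ndarray,
                             base_coords: np.ndarray, L: int) -> np.ndarray:
    """Rigid transform of the flipped strand giving canonical N...O registry.

    Narrow pairs (i, L-1-i) for even i receive two 2.9 A N...O bonds each
    (the antiparallel Kabsch-Sander double-bond pattern).
    """
    idx_N = {i: 4 * i for i in range(L)}     # atoms stored N, CA, C, O per residue
    idx_CA = {i: 4 * i + 1 for i in range(L)}
    idx_O = {i: 4 * i + 3 for i in range(L)}
    narrow = [(i, L - 1 - i) for i in range(0, L, 2) if i != L - 1 - i]
    all_pairs = [(i, L - 1 - i) for i in range(L)]

    def residuals(p):
        R = rotation_from_axis_angle([1, 0, 0], p[3]) @ \
            rotation_from_axis_angle([0, 1, 0], p[4]) @ \
            rotation_from_axis_angle([0, 0, 1], p[5])
        moved = flipped_coords @ R.T + p[:3]
        out = []
        for i, j in narrow:
            out.append(np.linalg.norm(moved[idx_N[i]] - base_coords[idx_O[j]]) - 2.9)
            out.append(np.linalg.norm(moved[idx_O[i]] - base_coords[idx_N[j]]) - 2.9)
        # soft pleating regularizer: paired CA atoms ~4.9 A apart
        for i, j in all_pairs:
            out.append(0.3 * (np.linalg.norm(moved[idx_CA[i]] - base_coords[idx_CA[j]]) - 4.9))
        return out

    # initial guess: strands side by side at the canonical ~4.8 A spacing
    p0 = np.array([0.0, 4.8, 0.0, 0.0, 0.0, 0.0])
    sol = least_squares(residuals, p0, max_nfev=2000)
    R = rotation_from_axis_angle([1, 0, 0], sol.x[3]) @ \
        rotation_from_axis_angle([0, 1, 0], sol.x[4]) @ \
        rotation_from_axis_angle([0, 0, 1], sol.x[5])
    return flipped_coords @ R.T + sol.x[:3]


def build_antiparallel_sheet(n_strands: int, strand_len: int,
                             pose: Optional[Pose] = None,
                             chain_ids: Optional[Sequence[str]] = None,
                             start_seq: int = 1) -> StructuralModel:
    """Antiparallel beta-sheet: extended strands with H-bond registry.

    Each strand is its own chain. Successive strands alternate direction and
    are placed by a rigid transform refined so narrow-pair N...O distances
    are 2.9 A, so the Kabsch-Sander antiparallel bridge pattern holds.
    """
    if n_strands < 2:
        raise ValueError(f"a sheet needs at least 2 strands, got {n_strands}")
    if strand_len < 3:
        raise ValueError(f"strands need at least 3 residues, got {strand_len}")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + k) for k in range(n_strands)]
    L = strand_len
    base = _build_backbone(L, STRAND_PHI, STRAND_PSI, chain_ids[0], start_seq)
    atom_order = ("N", "CA", "C", "O")

    def coords_of(chain: Chain) -> np.ndarray:
        return np.array([res.atoms[a] for res in chain.residues for a in atom_order])

    base_coords = coords_of(base)
    centroid = base_coords.mean(axis=0)
    axis = base.residues[-1].atoms["CA"] - base.residues[0].atoms["CA"]
    axis /= np.linalg.norm(axis)
    # flip 180 deg about an axis perpendicular to the strand direction:
    # reverses direction while keeping the backbone in roughly the same plane
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    Rflip = rotation_from_axis_angle(perp, 180.0)
    flipped = (base_coords - centroid) @ Rflip.T + centroid
    second_coords = _refine_strand_transform(base, flipped, base_coords, L)

    # the base->partner map, applied repeatedly, tiles the sheet
    strands_coords = [base_coords, second_coords]
    if n_strands > 2:
        # solve the rigid map base->second once, then iterate it
        bc = base_coords - base_coords.mean(axis=0)
        sc = second_coords - second_coords.mean(axis=0)
        U, _, Vt = np.linalg.svd(sc.T @ bc)
        d = np.sign(np.linalg.det(U @ Vt))
        Rmap = U @ np.diag([1.0, 1.0, d]) @ Vt
        tmap = second_coords.mean(axis=0) - base_coords.mean(axis=0) @ Rmap.T
        for _ in range(n_strands - 2):
            strands_coords.append(strands_coords[-1] @ Rmap.T + tmap)

    model = StructuralModel()
    for k, coords in enumerate(strands_coords):
        chain = Chain(chain_id=chain_ids[k])
        for i in range(L):
            atoms = {a: coords[4 * i + m].copy() for m, a in enumerate(atom_order)}
            chain.residues.append(Residue(chain_id=chain_ids[k], seqid=start_seq + i,
                                          icode="", name="ALA", kind="aa", atoms=atoms))
        model.chains.append(chain)
    return _apply_pose(model, pose)


# simplified A-form-like backbone: (radius A, phase deg, z A) per atom
_NUC_CYL = {
    "P": (9.4, 0.0, 0.0),
    "O5'": (9.0, 6.0, 0.5),
    "C5'": (9.3, 12.0, 1.0),
    "C4'": (9.2, 18.0, 1.4),
    "C3'": (9.0, 24.0, 1.9),
    "O3'": (8.9, 28.0, 2.3),
}
_NUC_TWIST = 32.7   # deg per residue
_NUC_RISE = 2.81    # A per residue


def build_nucleic_chain(n: int, pose: Optional[Pose] = None,
                        chain_id: str = "N", start_seq: int = 1) -> StructuralModel:
    """Single-stranded oligonucleotide backbone on an A-form-like helix."""
    if n < 2:
        raise ValueError(f"a nucleic chain needs at least 2 residues, got {n}")
    chain = Chain(chain_id=chain_id)
    for i in range(n):
        atoms = {}
        for name, (r, phase, dz) in _NUC_CYL.items():
            theta = np.radians(i * _NUC_TWIST + phase)
            atoms[name] = np.array([r * np.cos(theta), r * np.sin(theta),
                                    i * _NUC_RISE + dz])
        chain.residues.append(Residue(chain_id=chain_id, seqid=start_seq + i,
                                      icode="", name="U", kind="nuc", atoms=atoms))
    model = StructuralModel(chains=[chain])
    return _apply_pose(model, pose)


# ---------------------------------------------------------------------------
# phantom specification and density simulation

@dataclass
class ElementSpec:
    kind: str                      # "helix" | "sheet" | "nucleotide"
    n_residues: int                # strand length for sheets
    pose: Optional[Pose] = None
    n_strands: int = 4             # sheets only


@dataclass
class PhantomSpec:
    elements: List[ElementSpec]
    box: Tuple[int, int, int] = (70, 70, 70)
    voxel_size: float = 1.1
    atom_sigma: float = 1.0
    noise_sigma: float = 0.1
    seed: int = 0


_element_cache: dict = {}


def _element_raw(kind: str, n_residues: int, n_strands: int) -> StructuralModel:
    """Element geometry at its construction origin, cached (builders are pure)."""
    key = (kind, n_residues, n_strands)
    if key not in _element_cache:
        if kind == "helix":
            built = build_ideal_helix(n_residues)
        elif kind == "sheet":
            built = build_antiparallel_sheet(n_strands, n_residues)
        elif kind == "nucleotide":
            built = build_nucleic_chain(n_residues)
        else:
            raise ValueError(f"unknown element kind {kind!r}")
        _element_cache[key] = built
    return _element_cache[key]


def _build_element(el: ElementSpec, chain_offset: int) -> StructuralModel:
    import copy

    raw = _element_raw(el.kind, el.n_residues, el.n_strands)
    model = copy.deepcopy(raw)
    for k, chain in enumerate(model.chains):
        cid = chr(ord("A") + ((chain_offset + k) % 26))
        chain.chain_id = cid
        for res in chain.residues:
            res.chain_id = cid
    return _apply_pose(model, el.pose)


def build_phantom_model(spec: PhantomSpec) -> StructuralModel:
    """Assemble all elements of a phantom into one model (distinct chain ids)."""
    model = StructuralModel()
    offset = 0
    for el in spec.elements:
        sub = _build_element(el, offset)
        offset += len(sub.chains)
        model.chains.extend(sub.chains)
    return model


def simulate_density(model: StructuralModel, box: Tuple[int, int, int],
                     atom_sigma: float = 1.0, noise_sigma: float = 0.0,
                     seed: Optional[int] = None, voxel_size: float = 1.1,
                     origin: Sequence[float] = (0.0, 0.0, 0.0)) -> DensityMap:
    """Sum-of-Gaussians density for a model, sigma-normalized.

    Each atom contributes a unit-height isotropic Gaussian of width
    ``atom_sigma`` (A); ``noise_sigma`` adds white Gaussian noise in the same
    pre-normalization units.
    """
    grid = np.zeros(box, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    cut = 4.0 * atom_sigma
    inv2s2 = 1.0 / (2.0 * atom_sigma ** 2)
    for atom in model.all_atom_coords():
        los, his, dxs = [], [], []
        ok = True
        for ax in range(3):
            lo = int(np.ceil((atom[ax] - cut - origin[ax]) / voxel_size))
            hi = int(np.floor((atom[ax] + cut - origin[ax]) / voxel_size)) + 1
            lo, hi = max(lo, 0), min(hi, box[ax])
            if lo >= hi:
                ok = False
                break
            los.append(lo)
            his.append(hi)
            dxs.append(origin[ax] + np.arange(lo, hi) * voxel_size - atom[ax])
        if not ok:
            continue
        d2 = (dxs[0] ** 2)[:, None, None] + (dxs[1] ** 2)[None, :, None] \
            + (dxs[2] ** 2)[None, None, :]
        grid[los[0]:his[0], los[1]:his[1], los[2]:his[2]] += np.exp(-d2 * inv2s2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        grid += rng.normal(0.0, noise_sigma, size=box)
    std = grid.std()
    if std == 0:
        raise ValueError("simulated density is constant; add atoms or noise")
    grid = (grid - grid.mean()) / std
    return DensityMap(grid=grid.astype(np.float32), voxel_size=voxel_size,
                      origin=origin, sigma=1.0)


# element inventories that comfortably satisfy the segment filters in a
# 70^3 box at 1.1 A (>=100 atoms at >=1 sigma, backbone mean >=3 sigma,
# >=5% of the volume annotated)
_DEFAULT_INVENTORY = {
    "helix": [("helix", 30, 1)] * 8,
    "sheet": [("sheet", 14, 6)] * 6,
    "nucleotide": [("nucleotide", 18, 1)] * 9,
}


def random_phantom_spec(kind: str, seed: int, box: Tuple[int, int, int] = (70, 70, 70),
                        voxel_size: float = 1.1, atom_sigma: float = 1.0,
                        noise_sigma: float = 0.1) -> PhantomSpec:
    """A phantom of one structural kind with randomized, non-clashing poses."""
    if kind not in _DEFAULT_INVENTORY:
        raise ValueError(f"unknown phantom kind {kind!r}")
    rng = np.random.default_rng(seed)
    extent = np.array(box, dtype=np.float64) * voxel_size
    margin = 5.0
    elements: List[ElementSpec] = []
    placed: List[np.ndarray] = []
    from scipy.spatial import cKDTree

    for ek, n_res, n_str in _DEFAULT_INVENTORY[kind]:
        raw = _element_raw(ek, n_res, n_str).all_atom_coords()
        raw = raw - raw.mean(axis=0)
        for _attempt in range(250):
            center = rng.uniform(margin, extent - margin, size=3)
            pose = Pose.random(rng, center)
            coords = raw @ pose.rotation.T + pose.translation
            if (coords < margin).any() or (coords > extent - margin).any():
                continue
            if placed and cKDTree(np.concatenate(placed)).query(coords, k=1)[0].min() < 3.0:
                continue
            elements.append(ElementSpec(kind=ek, n_residues=n_res, pose=pose,
                                        n_strands=n_str))
            placed.append(coords)
            break
    return PhantomSpec(elements=elements, box=box, voxel_size=voxel_size,
                       atom_sigma=atom_sigma, noise_sigma=noise_sigma,
                       seed=int(rng.integers(2 ** 31 - 1)))


def write_minimal_pdb(model: StructuralModel, path: str) -> None:
    """Write a model as fixed-column PDB ATOM records (backbone only is fine).

    Enough for round trips through :func:`read_model`; no header metadata.
    """
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "P": "P",
                "O5'": "O", "C5'": "C", "C4'": "C", "C3'": "C", "O3'": "O"}
    serial = 1
    lines = []
    for chain in model.chains:
        for res in chain.residues:
            for name, xyz in res.atoms.items():
                el = elements.get(name, name[0])
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad_name}{'':1s}{res.name:>3s} "
                    f"{chain.chain_id:1s}{res.seqid:4d}{res.icode:1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


@dataclass
class PhantomData:
    """One realized phantom: map, model, residue labels, voxel labels."""

    spec: PhantomSpec
    dmap: DensityMap
    model: StructuralModel
    labels: ResidueLabels
    label_volume: "object"  # LabelVolume; forward-declared to avoid cycle


def make_phantom_dataset(specs: Sequence[PhantomSpec], annotation_cfg=None,
                         segment_filter=None):
    """Run the full annotation pipeline on each phantom and cut segments.

    Returns ``(segments, phantoms)`` where ``segments`` is the concatenated
    list over phantoms (zero-segment phantoms are skipped with a warning) and
    ``phantoms`` holds the intermediate artifacts for inspection.
    """
    from .training_data import SegmentFilter, extract_segments
    from .voxel_labeling import AnnotationConfig, annotate_voxels

    annotation_cfg = annotation_cfg or AnnotationConfig()
    segment_filter = segment_filter or SegmentFilter()
    all_segments = []
    phantoms: List[PhantomData] = []
    for k, spec in enumerate(specs):
        model = build_phantom_model(spec)
        dmap = simulate_density(model, spec.box, spec.atom_sigma,
                                spec.noise_sigma, spec.seed, spec.voxel_size)
        labels = assign_secondary_structure(model)
        lv = annotate_voxels(dmap, model, labels, annotation_cfg)
        segs = extract_segments(dmap, model, lv, segment_filter, map_id=f"phantom{k}")
        if not segs:
            warnings.warn(f"phantom {k} produced no segments passing the filter; skipped")
            continue
        all_segments.extend(segs)
        phantoms.append(PhantomData(spec=spec, dmap=dmap, model=model,
                                    labels=labels, label_volume=lv))
    return all_segments, phantoms
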