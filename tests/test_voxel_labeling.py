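"""Voxel annotation: density gates, distance rules, and oracle equivalence."""

import numpy as np
import pytest

from haruspex.map_io import DensityMap
from haruspex.model_annotation import Residue, ResidueLabels, StructuralModel, Chain
from haruspex.phantoms import (Pose, build_ideal_helix, simulate_density,
                               build_nucleic_chain)
from haruspex.model_annotation import assign_secondary_structure
from haruspex.voxel_labeling import (AnnotationConfig, CLASS_TO_INDEX,
                                     LabelVolume, UNASSIGNED, annotate_voxels,
                                     residue_backbone_density)

_PRIORITY = {"nucleotide": 0, "helix": 1, "sheet": 2}


def brute_force_annotate(dmap, model, labels, cfg):
    """All-pairs distance-scan oracle implementing the annotation rules.

    Independent O(voxels x atoms) reimplementation: for every voxel compute
    exact distances to every gated backbone atom and every model atom, then
    apply the 3 A / 5 A / 1 sigma / 2 sigma rules.
    """
    shape = dmap.shape
    centers = [dmap.origin[ax] + np.arange(shape[ax]) * dmap.voxel_size
               for ax in range(3)]
    best_d2 = np.full(shape, np.inf)
    best_rank = np.full(shape, 127, dtype=np.int8)
    best_cls = np.full(shape, UNASSIGNED, dtype=np.int8)
    mask_d2 = np.full(shape, np.inf)
    min_any_d2 = np.full(shape, np.inf)

    def dist2(atom):
        dx = centers[0] - atom[0]
        dy = centers[1] - atom[1]
        dz = centers[2] - atom[2]
        return (dx ** 2)[:, None, None] + (dy ** 2)[None, :, None] \
            + (dz ** 2)[None, None, :]

    for res in model.polymer_residues():
        cls = labels.get(res)
        if cls == "unassigned":
            continue
        dens = residue_backbone_density(dmap, res)
        if dens is None or dens < cfg.mask_gate:
            continue
        for atom in res.backbone_atoms():
            d2 = dist2(atom)
            if dens > cfg.annotate_gate:
                rank = _PRIORITY[cls]
                upd = (d2 <= cfg.label_radius ** 2) & \
                    ((d2 < best_d2) | ((d2 == best_d2) & (rank < best_rank)))
                best_d2[upd] = d2[upd]
                best_rank[upd] = rank
                best_cls[upd] = CLASS_TO_INDEX[cls]
            else:
                upd = (d2 <= cfg.label_radius ** 2) & (d2 < mask_d2)
                mask_d2[upd] = d2[upd]
    for atom in model.all_atom_coords():
        np.minimum(min_any_d2, dist2(atom), out=min_any_d2)

    class_grid = np.full(shape, UNASSIGNED, dtype=np.int8)
    exclude = np.zeros(shape, dtype=bool)
    has_label = np.isfinite(best_d2)
    label_wins = has_label & (best_d2 <= mask_d2)
    class_grid[label_wins] = best_cls[label_wins]
    exclude[np.isfinite(mask_d2) & ~label_wins] = True
    exclude[(min_any_d2 > cfg.far_radius ** 2) & (dmap.grid >= cfg.density_floor)] = True
    return class_grid, exclude


def _normalized_noise_map(rng, shape, voxel=1.0):
    g = rng.normal(size=shape)
    g = (g - g.mean()) / g.std()
    return DensityMap(grid=g.astype(np.float32), voxel_size=voxel, sigma=1.0)


def _bump(dmap, center, amplitude, width=1.2):
    """Add a Gaussian bump to a map and re-normalize to unit sigma."""
    shape = dmap.shape
    ax = [dmap.origin[i] + np.arange(shape[i]) * dmap.voxel_size - center[i]
          for i in range(3)]
    d2 = (ax[0] ** 2)[:, None, None] + (ax[1] ** 2)[None, :, None] \
        + (ax[2] ** 2)[None, None, :]
    g = dmap.grid + amplitude * np.exp(-d2 / (2 * width ** 2)).astype(np.float32)
    g = (g - g.mean()) / g.std()
    return DensityMap(grid=g.astype(np.float32), voxel_size=dmap.voxel_size,
                      origin=dmap.origin, sigma=1.0)


class TestResidueBackboneDensity:
    def _residue(self, coords):
        names = ["N", "CA", "C", "O"][:len(coords)]
        return Residue(chain_id="A", seqid=1, icode="", name="ALA", kind="aa",
                       atoms={n: np.asarray(c, float) for n, c in zip(names, coords)})

    def test_constant_map(self):
        dmap = DensityMap(grid=np.full((10, 10, 10), 2.5, dtype=np.float32),
                          voxel_size=1.0)
        res = self._residue([[4.2, 5.1, 3.3], [5.0, 5.0, 5.0]])
        assert residue_backbone_density(dmap, res) == pytest.approx(2.5)

    def test_value_at_voxel_center(self):
        grid = np.zeros((8, 8, 8), dtype=np.float32)
        grid[4, 4, 4] = 3.0
        dmap = DensityMap(grid=grid, voxel_size=1.0)
        res = self._residue([[4.0, 4.0, 4.0]])
        assert residue_backbone_density(dmap, res) == pytest.approx(3.0)

    def test_midpoint_interpolation(self):
        grid = np.zeros((8, 8, 8), dtype=np.float32)
        grid[4, 4, 4] = 4.0  # neighbour (5,4,4) stays 0
        dmap = DensityMap(grid=grid, voxel_size=1.0)
        res = self._residue([[4.5, 4.0, 4.0]])
        assert residue_backbone_density(dmap, res) == pytest.approx(2.0)

    def test_all_atoms_outside_is_sentinel(self):
        dmap = DensityMap(grid=np.zeros((8, 8, 8), dtype=np.float32), voxel_size=1.0)
        res = self._residue([[100.0, 100.0, 100.0]])
        assert residue_backbone_density(dmap, res) is None


class TestAnnotateRules:
    def _one_residue_model(self, center):
        res = Residue(chain_id="A", seqid=1, icode="", name="ALA", kind="aa",
                      atoms={"N": center + np.array([-1.2, 0, 0]),
                             "CA": center,
                             "C": center + np.array([1.2, 0.5, 0]),
                             "O": center + np.array([1.2, 1.7, 0])})
        return StructuralModel(chains=[Chain(chain_id="A", residues=[res])]), res

    def test_high_density_residue_annotates_exact_oracle(self, rng):
        dmap = _normalized_noise_map(np.random.default_rng(11), (32, 32, 32))
        center = np.array([16.0, 16.0, 16.0])
        model, res = self._one_residue_model(center)
        for atom in res.backbone_atoms():
            dmap = _bump(dmap, atom, 30.0)
        labels = ResidueLabels({res.key: "helix"})
        dens = residue_backbone_density(dmap, res)
        assert dens > 2.0  # constructed to pass the annotate gate
        cfg = AnnotationConfig()
        lv = annotate_voxels(dmap, model, labels, cfg)
        cg, ex = brute_force_annotate(dmap, model, labels, cfg)
        np.testing.assert_array_equal(lv.class_grid, cg)
        np.testing.assert_array_equal(lv.exclude, ex)
        assert (lv.class_grid == CLASS_TO_INDEX["helix"]).sum() > 50

    def test_weak_density_residue_masks_not_annotates(self):
        dmap = _normalized_noise_map(np.random.default_rng(12), (32, 32, 32))
        center = np.array([16.0, 16.0, 16.0])
        model, res = self._one_residue_model(center)
        for atom in res.backbone_atoms():
            dmap = _bump(dmap, atom, 0.75)
        dens = residue_backbone_density(dmap, res)
        assert 1.0 <= dens <= 2.0  # constructed to land in the mask band
        labels = ResidueLabels({res.key: "helix"})
        lv = annotate_voxels(dmap, model, labels)
        assert (lv.class_grid != UNASSIGNED).sum() == 0
        # voxels near the backbone are excluded from training
        ca_idx = tuple(int(round(v)) for v in center)
        assert lv.exclude[ca_idx]

    def test_far_high_density_blob_excluded(self):
        dmap = _normalized_noise_map(np.random.default_rng(13), (32, 32, 32))
        center = np.array([8.0, 8.0, 8.0])
        model, res = self._one_residue_model(center)
        blob = np.array([24.0, 24.0, 24.0])  # ~27 A from the residue
        dmap = _bump(dmap, blob, 40.0)
        for atom in res.backbone_atoms():
            dmap = _bump(dmap, atom, 30.0)
        labels = ResidueLabels({res.key: "helix"})
        lv = annotate_voxels(dmap, model, labels)
        assert lv.exclude[24, 24, 24]
        # a sub-sigma ripple far away stays trainable
        assert not lv.exclude[28, 8, 8] or dmap.grid[28, 8, 8] >= 1.0

    def test_non_normalized_map_rejected(self):
        dmap = DensityMap(grid=np.random.default_rng(0)
                          .normal(0, 5, size=(8, 8, 8)).astype(np.float32),
                          voxel_size=1.0)
        model, res = self._one_residue_model(np.array([4.0, 4.0, 4.0]))
        with pytest.raises(ValueError, match="normalized"):
            annotate_voxels(dmap, model, ResidueLabels({res.key: "helix"}))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_phantoms(self, seed):
        rng = np.random.default_rng(200 + seed)
        kind = ["helix", "sheet", "nucleotide"][seed % 3]
        if kind == "helix":
            sub = build_ideal_helix(8, Pose.random(rng, [16.0, 16.0, 16.0]))
        elif kind == "nucleotide":
            sub = build_nucleic_chain(4, Pose.random(rng, [16.0, 16.0, 16.0]))
        else:
            from haruspex.phantoms import build_antiparallel_sheet
            sub = build_antiparallel_sheet(2, 5, Pose.random(rng, [16.0, 16.0, 16.0]))
        dmap = simulate_density(sub, (32, 32, 32), atom_sigma=1.0,
                                noise_sigma=0.15, seed=seed, voxel_size=1.0)
        labels = assign_secondary_structure(sub)
        # force some residues into each band regardless of detection outcome
        cfg = AnnotationConfig()
        lv = annotate_voxels(dmap, sub, labels, cfg)
        cg, ex = brute_force_annotate(dmap, sub, labels, cfg)
        np.testing.assert_array_equal(lv.class_grid, cg)
        np.testing.assert_array_equal(lv.exclude, ex)


def test_translation_equivariance():
    rng = np.random.default_rng(31)
    helix = build_ideal_helix(8, Pose.random(rng, [20.0, 20.0, 20.0]))
    dmap = simulate_density(helix, (44, 44, 44), atom_sigma=1.0,
                            noise_sigma=0.0, voxel_size=1.0)
    labels = assign_secondary_structure(helix)
    lv = annotate_voxels(dmap, helix, labels)
    # shift model and grid by one voxel along x
    rolled = DensityMap(grid=np.roll(dmap.grid, 1, axis=0),
                        voxel_size=1.0, sigma=1.0)
    import copy
    shifted = copy.deepcopy(helix)
    for res in shifted.residues():
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + np.array([1.0, 0.0, 0.0])
    labels2 = assign_secondary_structure(shifted)
    lv2 = annotate_voxels(rolled, shifted, labels2)
    np.testing.assert_array_equal(np.roll(lv.class_grid, 1, axis=0)[2:-2],
                                  lv2.class_grid[2:-2])


def test_one_hot_and_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    cg = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int8)
    ex = rng.random((6, 6, 6)) < 0.2
    lv = LabelVolume(class_grid=cg, exclude=ex, voxel_size=1.1,
                     origin=np.array([1.0, 2.0, 3.0]))
    oh = lv.one_hot()
    np.testing.assert_array_equal(oh.sum(axis=-1), np.ones((6, 6, 6)))
    assert oh.argmax(axis=-1).astype(np.int8).tolist() == cg.tolist()
    path = tmp_path / "lv.h5"
    lv.save_hdf5(path)
    back = LabelVolume.load_hdf5(path)
    np.testing.assert_array_equal(back.class_grid, cg)
    np.testing.assert_array_equal(back.exclude, ex)
    assert back.voxel_size == pytest.approx(1.1)
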