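"""3D stage: conformers, Gaussian overlap vs grid integration, overlays."""

import numpy as np
import pytest
from rdkit.Chem import rdMolAlign

import chemcascade as cc
from chemcascade.shape import (
    Conformer,
    Transform,
    _alpha,
    cascade_filter_3d,
    self_overlap,
)

from conftest import random_rigid_transform


def grid_overlap_oracle(conf_a, conf_b, transform=None, spacing=0.2):
    """Independent route: integrate the product of the two Gaussian densities
    on a regular grid (first-order overlap equals this integral exactly)."""
    if transform is None:
        transform = Transform.identity()
    cb = transform.apply(conf_b.coords)
    pts_min = np.minimum(conf_a.coords.min(0), cb.min(0)) - 3.5
    pts_max = np.maximum(conf_a.coords.max(0), cb.max(0)) + 3.5
    axes = [np.arange(pts_min[d], pts_max[d], spacing) for d in range(3)]
    aa = _alpha(conf_a.radii)
    ab = _alpha(conf_b.radii)
    total = 0.0
    gy, gz = np.meshgrid(axes[1], axes[2], indexing="ij")
    yz = np.stack([gy.ravel(), gz.ravel()], axis=1)
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        rho_a = np.zeros(len(pts))
        for c, al in zip(conf_a.coords, aa):
            rho_a += 2.7 * np.exp(-al * ((pts - c) ** 2).sum(1))
        rho_b = np.zeros(len(pts))
        for c, al in zip(cb, ab):
            rho_b += 2.7 * np.exp(-al * ((pts - c) ** 2).sum(1))
        total += (rho_a * rho_b).sum()
    return total * spacing**3


def single_atom_conformer(radius=1.7, pos=(0.0, 0.0, 0.0)):
    return Conformer(
        coords=np.array([pos], float),
        radii=np.array([radius]),
        elements=("C",),
        feature_types=(),
        feature_coords=np.zeros((0, 3)),
    )


def moved_copy(conf, transform):
    return Conformer(
        coords=transform.apply(conf.coords),
        radii=conf.radii,
        elements=conf.elements,
        feature_types=conf.feature_types,
        feature_coords=transform.apply(conf.feature_coords)
        if len(conf.feature_types)
        else conf.feature_coords,
    )


class TestConformers:
    def test_rigid_ring_collapses_to_one(self, benzene):
        cs = cc.generate_conformers(benzene, n=10, seed=4)
        assert len(cs.conformers) == 1

    def test_same_seed_bitwise_identical(self, library):
        a = cc.generate_conformers(library[5], n=5, seed=9)
        b = cc.generate_conformers(library[5], n=5, seed=9)
        assert len(a.conformers) == len(b.conformers)
        for ca, cb2 in zip(a.conformers, b.conformers):
            assert np.array_equal(ca.coords, cb2.coords)

    def test_flexible_chain_prune_rmsd(self):
        chain = cc.standardize_structure("CCCCCCCCOCCNCC", "chain")
        cs = cc.generate_conformers(chain, n=10, seed=1)
        assert 1 <= len(cs.conformers) <= 10
        mol = cs.mol
        ids = [c.GetId() for c in mol.GetConformers()]
        from rdkit import Chem

        noh = Chem.RemoveHs(mol)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rms = rdMolAlign.GetBestRMS(noh, noh, prbId=ids[i], refId=ids[j])
                assert rms >= 0.5 - 1e-6


class TestGaussianOverlap:
    def test_self_overlap_positive(self, benzene):
        conf = cc.generate_conformers(benzene, n=1, seed=0).conformers[0]
        assert self_overlap(conf) > 0

    def test_distant_atoms_negligible(self):
        a = single_atom_conformer()
        b = single_atom_conformer(pos=(100.0, 0.0, 0.0))
        assert cc.gaussian_overlap_volume(a, b) < 1e-6

    def test_two_atoms_decay_and_grid_oracle(self):
        r = 1.7
        a = single_atom_conformer(r)
        at0 = single_atom_conformer(r, (0, 0, 0))
        atr = single_atom_conformer(r, (r, 0, 0))
        v0 = cc.gaussian_overlap_volume(a, at0)
        vr = cc.gaussian_overlap_volume(a, atr)
        assert vr < v0
        assert v0 == pytest.approx(grid_overlap_oracle(a, at0), rel=0.02)
        assert vr == pytest.approx(grid_overlap_oracle(a, atr), rel=0.02)

    def test_symmetric_under_swap_with_inverse(self, library):
        conf = cc.generate_conformers(library[2], n=1, seed=0).conformers[0]
        conf2 = cc.generate_conformers(library[30], n=1, seed=0).conformers[0]
        rng = np.random.default_rng(3)
        t = random_rigid_transform(rng)
        v1 = cc.gaussian_overlap_volume(conf, conf2, t)
        v2 = cc.gaussian_overlap_volume(conf2, conf, t.inverse())
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_grid_oracle_on_molecules(self, library):
        rng = np.random.default_rng(12)
        for idx in [0, 40]:
            conf = cc.generate_conformers(library[idx], n=1, seed=2).conformers[0]
            other = cc.generate_conformers(library[idx + 7], n=1, seed=2).conformers[0]
            t = random_rigid_transform(rng)
            analytic = cc.gaussian_overlap_volume(conf, other, t)
            assert analytic == pytest.approx(grid_overlap_oracle(conf, other, t), rel=0.02)


class TestOptimizeOverlay:
    def test_recovers_rigid_copy(self, library):
        conf = cc.generate_conformers(library[8], n=1, seed=5).conformers[0]
        rng = np.random.default_rng(8)
        moved = moved_copy(conf, random_rigid_transform(rng))
        _, shape_t = cc.optimize_overlay(conf, moved)
        assert shape_t >= 0.99

    def test_single_atom_exact(self):
        a = single_atom_conformer()
        b = single_atom_conformer(pos=(2.0, 1.0, -3.0))
        _, shape_t = cc.optimize_overlay(a, b)
        assert shape_t == pytest.approx(1.0, abs=1e-6)

    def test_size_mismatch_bounded_by_smaller_volume(self, library):
        methane = single_atom_conformer(1.7)
        big = cc.generate_conformers(library[0], n=1, seed=1).conformers[0]
        _, shape_t = cc.optimize_overlay(big, methane)
        assert shape_t < 0.5

    def test_invariant_to_pre_transformation(self, library):
        conf_a = cc.generate_conformers(library[15], n=1, seed=3).conformers[0]
        conf_b = cc.generate_conformers(library[60], n=1, seed=3).conformers[0]
        _, base = cc.optimize_overlay(conf_a, conf_b)
        rng = np.random.default_rng(21)
        _, moved = cc.optimize_overlay(conf_a, moved_copy(conf_b, random_rigid_transform(rng)))
        assert moved == pytest.approx(base, abs=1e-3)


class TestColorTanimoto:
    def test_identity_is_one_with_features(self, phenol):
        conf = cc.generate_conformers(phenol, n=1, seed=0).conformers[0]
        assert cc.color_tanimoto(conf, conf) == pytest.approx(1.0)

    def test_disjoint_feature_types_zero(self):
        # quaternary ammonium (cation only features) vs carboxylate-free donor
        a = cc.generate_conformers(
            cc.standardize_structure("CCCC", "butane"), n=1, seed=0
        ).conformers[0]
        b = cc.generate_conformers(
            cc.standardize_structure("OCO", "diol"), n=1, seed=0
        ).conformers[0]
        shared = set(a.feature_types) & set(b.feature_types)
        assert not shared
        assert cc.color_tanimoto(a, b) == 0.0

    def test_featureless_molecule_scores_zero(self):
        bare = single_atom_conformer()
        other = single_atom_conformer()
        assert cc.color_tanimoto(bare, other) == 0.0

    def test_self_recovery_under_optimizer(self, phenol):
        conf = cc.generate_conformers(phenol, n=1, seed=0).conformers[0]
        rng = np.random.default_rng(4)
        moved = moved_copy(conf, random_rigid_transform(rng))
        transform, _ = cc.optimize_overlay(conf, moved)
        assert cc.color_tanimoto(conf, moved, transform) >= 0.95


class TestTanimotoCombo:
    def test_identical_compound_near_two(self, library):
        cs = cc.generate_conformers(library[3], n=1, seed=6)
        score = cc.tanimoto_combo(cs, cs)
        assert score.tanimoto_combo >= 1.98

    def test_featureless_pair_is_shape_only(self):
        conf = single_atom_conformer()
        cs = cc.ConformerSet("x", (conf,), 1, 0, None)
        score = cc.tanimoto_combo(cs, cs)
        assert score.color_tanimoto == 0.0
        assert score.tanimoto_combo == pytest.approx(score.shape_tanimoto)

    def test_max_over_conformer_pairs_brute_force(self, library):
        chain = cc.standardize_structure("CCOC(=O)CCNC(=O)c1ccccc1", "flex")
        a = cc.generate_conformers(chain, n=3, seed=2)
        b = cc.generate_conformers(library[20], n=3, seed=2)
        score = cc.tanimoto_combo(a, b)
        brute = -np.inf
        for cd in a.conformers:
            for ca in b.conformers:
                t, st = cc.optimize_overlay(ca, cd)
                brute = max(brute, st + cc.color_tanimoto(ca, cd, t))
        assert score.tanimoto_combo == pytest.approx(brute, abs=1e-9)

    def test_combo_invariants(self, small_study):
        score = cc.tanimoto_combo(
            cc.generate_conformers(small_study.drugs[0], n=2, seed=1),
            cc.generate_conformers(small_study.compounds[0], n=2, seed=1),
        )
        assert 0.0 <= score.shape_tanimoto <= 1.0
        assert 0.0 <= score.color_tanimoto <= 1.0
        assert score.tanimoto_combo == pytest.approx(
            score.shape_tanimoto + score.color_tanimoto
        )


class TestCascade3D:
    def test_threshold_boundary(self):
        def ov(combo):
            return cc.OverlayScore("d", "a", combo / 2, combo / 2, combo, Transform.identity(), (0, 0))

        assert cascade_filter_3d([ov(1.6)]) != []
        assert cascade_filter_3d([ov(1.49)]) == []
        assert cascade_filter_3d([]) == []
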