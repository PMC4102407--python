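"""SASA, measurements, ensemble statistics, water tracking, rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metalswitch import (ConformationEnsemble, GeneratorConfig, cluster_frames,
                         gen_ensemble, hbond_series, measure, rank_sum_test,
                         rmsd_series, rmsf_profile, sasa, track_water)
from metalswitch.structio import StructureModel

from conftest import make_atom


# ---------------------------------------------------------------------------
# SASA vs analytic closed forms
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_atom_matches_sphere(self):
        s = StructureModel(atoms=[make_atom(1, "O", "HOH", 1, [0, 0, 0],
                                            het=True)])
        for probe in (0.5, 1.4):
            area = sasa(s, probe=probe)[0]
            exact = 4 * math.pi * (1.52 + probe) ** 2
            assert abs(area - exact) / exact < 0.01

    def test_two_overlapping_spheres_match_cap_formula(self):
        r = 1.52
        probe = 1.4
        R = r + probe
        d = 2.0  # center separation < 2R: overlapping
        atoms = [make_atom(1, "O", "HOH", 1, [0, 0, 0], het=True),
                 make_atom(2, "O", "HOH", 2, [d, 0, 0], het=True)]
        s = StructureModel(atoms=atoms)
        areas = sasa(s, probe=probe)
        # equal spheres: each loses a cap of height h = R - d/2
        h = R - d / 2
        exact_each = 4 * math.pi * R * R - 2 * math.pi * R * h
        for a in areas:
            assert abs(a - exact_each) / exact_each < 0.01

    def test_buried_atom_has_zero_area(self):
        # dense icosahedral cage around a central atom
        atoms = [make_atom(1, "ZN", "ZN", 1, [0, 0, 0], het=True)]
        phi = (1 + math.sqrt(5)) / 2
        verts = [p for p in itertools.product((-1, 1), repeat=3)]
        verts += [(0, c * 1 / phi, d * phi) for c in (-1, 1) for d in (-1, 1)]
        verts += [(c * 1 / phi, d * phi, 0) for c in (-1, 1) for d in (-1, 1)]
        verts += [(c * phi, 0, d * 1 / phi) for c in (-1, 1) for d in (-1, 1)]
        for i, v in enumerate(verts):
            pos = 2.2 * np.array(v, dtype=float) / np.linalg.norm(v)
            atoms.append(make_atom(i + 2, "O", "HOH", i + 2, pos, het=True))
        s = StructureModel(atoms=atoms)
        assert sasa(s, probe=0.5)[0] == 0.0

    def test_unknown_element_raises(self):
        s = StructureModel(atoms=[make_atom(1, "X", "UNK", 1, [0, 0, 0],
                                            het=True, element="XX")])
        with pytest.raises(ValueError, match="XX"):
            sasa(s)


# ---------------------------------------------------------------------------
# measure
# ---------------------------------------------------------------------------

class TestMeasure:
    @pytest.fixture()
    def triple(self):
        atoms = [make_atom(1, "CA", "GLY", 1, [0, 0, 0]),
                 make_atom(2, "CA", "GLY", 2, [1, 0, 0]),
                 make_atom(3, "CA", "GLY", 3, [2, 0, 0])]
        return StructureModel(atoms=atoms)

    def test_unit_distance(self, triple):
        assert measure(triple, ["A:1:CA", "A:2:CA"]) == pytest.approx(1.0)

    def test_collinear_angle(self, triple):
        assert measure(triple, ["A:1:CA", "A:2:CA", "A:3:CA"]) == \
            pytest.approx(180.0)

    def test_right_angle(self):
        atoms = [make_atom(1, "CA", "GLY", 1, [1, 0, 0]),
                 make_atom(2, "CA", "GLY", 2, [0, 0, 0]),
                 make_atom(3, "CA", "GLY", 3, [0, 1, 0])]
        s = StructureModel(atoms=atoms)
        assert measure(s, [("A", 1, "CA"), ("A", 2, "CA"), ("A", 3, "CA")]) \
            == pytest.approx(90.0)

    def test_unresolved_key_raises(self, triple):
        with pytest.raises(KeyError):
            measure(triple, ["A:1:CA", "B:9:CB"])


# ---------------------------------------------------------------------------
# hbond series
# ---------------------------------------------------------------------------

class TestHbondSeries:
    def test_static_ensemble_zero_variance(self, tiny_static_ensemble):
        series = hbond_series(tiny_static_ensemble,
                              [(("A", 135, "ND1"), ("A", 127, "OE1"))])
        assert series[0].variance == 0.0
        assert not series[0].used_proton

    def test_two_state_means_recovered(self, clean_center):
        rng = np.random.default_rng(3)
        i = [k for k, a in enumerate(clean_center.atoms)
             if a.key == ("A", 135, "", "ND1")][0]
        j = [k for k, a in enumerate(clean_center.atoms)
             if a.key == ("A", 127, "", "OE1")][0]
        base = clean_center.coords()
        sep = (base[j] - base[i]) / np.linalg.norm(base[j] - base[i])
        frames = []
        for f in range(400):
            c = base.copy()
            target = 2.8 if f % 2 == 0 else 3.8
            c[j] = c[i] + target * sep
            c[j] += rng.normal(0, 0.02, 3)
            frames.append(c)
        ens = ConformationEnsemble(clean_center.copy(), np.stack(frames))
        d = hbond_series(ens, [(("A", 135, "ND1"), ("A", 127, "OE1"))])[0]
        lo = np.median(d.values[d.values < 3.3])
        hi = np.median(d.values[d.values >= 3.3])
        assert lo == pytest.approx(2.8, abs=0.05)
        assert hi == pytest.approx(3.8, abs=0.05)

    def test_proton_used_when_present(self, clean_center):
        coords = np.stack([clean_center.coords()] * 3)
        ens = ConformationEnsemble(clean_center.copy(), coords)
        d = hbond_series(ens, [(("A", 501, "O"), ("A", 177, "OE1"), "H1")])[0]
        assert d.used_proton

    def test_clamp_widening_matches_generator_offset(self, state_ensembles):
        pair = [(("A", 135, "NE2"), ("A", 177, "OE1"))]
        d0 = hbond_series(state_ensembles["Ca0"], pair)[0]
        d2 = hbond_series(state_ensembles["Ca2"], pair)[0]
        offset = state_ensembles["Ca2"].ground_truth["clamp_offset"]
        assert d2.median - d0.median == pytest.approx(offset, rel=0.10)


# ---------------------------------------------------------------------------
# RMSF / RMSD
# ---------------------------------------------------------------------------

class TestRmsf:
    def test_duplicated_frames_zero(self, tiny_static_ensemble):
        prof = rmsf_profile(tiny_static_ensemble)
        assert np.allclose(prof.to_numpy(), 0.0)

    def test_single_frame_raises(self, clean_center):
        ens = ConformationEnsemble(clean_center.copy(),
                                   clean_center.coords()[None])
        with pytest.raises(ValueError):
            rmsf_profile(ens)

    def test_isotropic_sigma_gives_sigma_sqrt3(self):
        # uncorrelated per-residue displacements (no chain smoothing) so
        # the closed form sigma*sqrt(3) applies after rigid-body fitting
        cfg = GeneratorConfig(seed=41, state_label="Ca1",
                              background_amplitude=0.4, kernel_width=1e-9)
        ens = gen_ensemble(cfg, n_frames=500)
        prof = rmsf_profile(ens)
        expected_nm = 0.4 * math.sqrt(3) / 10.0
        assert prof.median() == pytest.approx(expected_nm, rel=0.05)

    def test_loop_residues_exceed_background_in_ca0(self, state_ensembles):
        prof = rmsf_profile(state_ensembles["Ca0"])
        loops = state_ensembles["Ca0"].ground_truth["loops"]
        in_loop = [r for r in prof.index
                   if any(lo <= r <= hi for lo, hi in loops)]
        out_loop = [r for r in prof.index if r not in set(in_loop)]
        assert prof[in_loop].min() > prof[out_loop].median() * 1.5

    def test_rigid_transform_invariance(self, state_ensembles):
        ens = state_ensembles["Ca1"]
        prof = rmsf_profile(ens)
        R = Rotation.from_euler("zyx", [12, 34, 56], degrees=True).as_matrix()
        moved = ConformationEnsemble(
            ens.template.copy(), ens.coords @ R.T + np.array([3.0, -1.0, 2.0]),
            state_label=ens.state_label)
        prof2 = rmsf_profile(moved)
        assert np.abs(prof.to_numpy() - prof2.to_numpy()).max() < 1e-6


class TestRmsdSeries:
    def test_static_vs_frame0_zero(self, tiny_static_ensemble):
        ref = tiny_static_ensemble.frame(0)
        sel = list(range(tiny_static_ensemble.n_atoms))
        out = rmsd_series(tiny_static_ensemble, ref, selection=sel)
        assert np.allclose(out, 0.0)

    def test_rigid_rotation_removed(self, clean_center):
        base = clean_center.coords()
        frames = []
        for k in range(5):
            R = Rotation.from_euler("z", 20 * k, degrees=True).as_matrix()
            frames.append(base @ R.T + k)
        ens = ConformationEnsemble(clean_center.copy(), np.stack(frames))
        sel = [i for i, a in enumerate(clean_center.atoms)][:10]
        out = rmsd_series(ens, clean_center, selection=sel)
        assert np.abs(out).max() < 1e-9

    def test_fixed_deformation_recovered(self, clean_center):
        base = clean_center.coords()
        n = len(base)
        rng = np.random.default_rng(7)
        # random deformation of fixed RMSD 1.5 Å (0.15 nm), mean-free and
        # rotation-free enough to survive superposition approximately
        d = rng.normal(size=(n, 3))
        d -= d.mean(axis=0)
        d *= 1.5 / np.sqrt((d ** 2).sum() / n)
        frames = np.stack([base + d] * 6)
        ens = ConformationEnsemble(clean_center.copy(), frames)
        out = rmsd_series(ens, clean_center,
                          selection=list(range(n)))
        assert np.all(np.abs(out - 0.15) < 0.02)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterFrames:
    def _two_conformers(self, clean_center):
        rng = np.random.default_rng(11)
        base = clean_center.coords()
        n = len(base)
        shift = rng.normal(size=(n, 3))
        shift -= shift.mean(axis=0)
        shift *= 5.0 / np.sqrt((shift ** 2).sum() / n)   # 0.5 nm apart
        frames = []
        for k in range(10):
            center = base if k % 2 == 0 else base + shift
            frames.append(center + rng.normal(0, 0.1, (n, 3)))
        sel = list(range(n))
        ens = ConformationEnsemble(clean_center.copy(), np.stack(frames))
        return ens, sel

    def test_two_separated_conformers_two_clusters(self, clean_center):
        ens, sel = self._two_conformers(clean_center)
        clusters = cluster_frames(ens, cutoff=0.1, selection=sel)
        assert len(clusters) == 2
        assert sorted(len(c.members) for c in clusters) == [5, 5]

    def test_large_cutoff_single_cluster(self, clean_center):
        ens, sel = self._two_conformers(clean_center)
        clusters = cluster_frames(ens, cutoff=10.0, selection=sel)
        assert len(clusters) == 1
        assert len(clusters[0].members) == ens.n_frames

    def test_static_single_cluster_center_first_frame(self,
                                                      tiny_static_ensemble):
        sel = list(range(tiny_static_ensemble.n_atoms))
        clusters = cluster_frames(tiny_static_ensemble, cutoff=0.05,
                                  selection=sel)
        assert len(clusters) == 1
        assert clusters[0].center == 0

    def test_sizes_sum_to_frames_and_centers_are_members(self, clean_center):
        ens, sel = self._two_conformers(clean_center)
        clusters = cluster_frames(ens, cutoff=0.2, selection=sel)
        assert sum(len(c.members) for c in clusters) == ens.n_frames
        for c in clusters:
            assert c.center in c.members


# ---------------------------------------------------------------------------
# water tracking
# ---------------------------------------------------------------------------

class TestTrackWater:
    def test_fixed_water_constant_pose(self, base_cfg):
        from metalswitch import gen_water_frames
        cfg = GeneratorConfig(seed=51, water_regime="fixed",
                              water_jitter=0.0, state_label="Ca1")
        ens = gen_water_frames(cfg, n=50)
        poses = track_water(ens, ("A", 401, "ZN"), ("A", 141, "ND1"),
                            ("A", 148, "CG"))
        d = [p.d_zn for p in poses]
        assert np.allclose(d, 2.0, atol=0.2)
        assert not any(p.exchanged for p in poses)

    def test_alpha_recomputation_invariant(self, base_cfg):
        from metalswitch import gen_water_frames
        cfg = GeneratorConfig(seed=52, water_regime="bimodal")
        ens = gen_water_frames(cfg, n=60)
        poses = track_water(ens, ("A", 401, "ZN"), ("A", 141, "ND1"),
                            ("A", 148, "CG"))
        i_zn = ens.atom_index(("A", 401, "ZN"))
        i_ref = ens.atom_index(("A", 141, "ND1"))
        for p in poses:
            if p.absent:
                continue
            iw = ens.atom_index(p.water_id)
            o = ens.coords[p.frame_index, iw]
            zn = ens.coords[p.frame_index, i_zn]
            ref = ens.coords[p.frame_index, i_ref]
            v1, v2 = o - zn, ref - zn
            alpha = math.degrees(math.acos(
                np.clip(np.dot(v1, v2)
                        / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1, 1)))
            assert abs(alpha - p.alpha) < 1e-9

    def test_no_water_all_absent(self, clean_center):
        dry = StructureModel(atoms=[a.copy() for a in clean_center.atoms
                                    if a.residue_name != "HOH"])
        ens = ConformationEnsemble(dry, np.stack([dry.coords()] * 3))
        poses = track_water(ens, ("A", 401, "ZN"), ("A", 141, "ND1"))
        assert all(p.absent for p in poses)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def oracle_exact_p(x, y, alternative="two-sided"):
    """Brute-force exact Mann-Whitney p: enumerate all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    us = [u_stat([pooled[i] for i in comb],
                 [pooled[i] for i in range(n + m) if i not in set(comb)])
          for comb in itertools.combinations(range(n + m), n)]
    us = np.array(us)
    mean_u = n * m / 2.0
    if alternative == "two-sided":
        count = np.sum(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    elif alternative == "greater":
        count = np.sum(us >= u_obs - 1e-12)
    else:
        count = np.sum(us <= u_obs + 1e-12)
    return count / len(us)


class TestRankSum:
    def test_identical_samples_degenerate(self):
        res = rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.degenerate and res.p_value == 1.0

    def test_disjoint_triples_exact_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 9), rng.integers(2, 9)
        x = rng.permutation(100)[:n].astype(float)
        y = (rng.permutation(100)[:m] + 0.5).astype(float)  # no ties
        for alt in ("two-sided", "less", "greater"):
            res = rank_sum_test(x, y, alternative=alt)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                oracle_exact_p(x, y, alt), abs=1e-12)

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0.0, 1.0, 200)
        y = rng.normal(1.0, 1.0, 200)
        res = rank_sum_test(x, y)
        assert res.method == "asymptotic"
        assert res.p_value < 1e-10

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
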