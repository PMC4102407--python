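"""Ion-affinity model, charge assignment, PB solver, thermodynamic cycle."""

import numpy as np
import pytest

from metalswitch import energetics as en
from metalswitch.energetics import (ChargeModel, ComparabilityError,
                                    ConfigurationError, PBOptions,
                                    TableCoverageError, affinity_difference,
                                    assign_charges, binding_energy,
                                    grid_energy, ion_affinity, ion_sites,
                                    solve_pb, surface_potential,
                                    water_binding_ddg)
from metalswitch.structio import StructureModel

from conftest import make_atom


# ---------------------------------------------------------------------------
# empirical ion affinity
# ---------------------------------------------------------------------------

class TestIonAffinity:
    def test_monotone_in_exposure(self):
        assert ion_affinity(5.0) < ion_affinity(10.0)

    def test_zero_exposure_is_minimum(self):
        dg0 = ion_affinity(0.0)
        for a in (0.1, 1.0, 20.0):
            assert dg0 < ion_affinity(a)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            ion_affinity(-1.0)

    def test_unset_coefficients_error(self):
        with pytest.raises(ConfigurationError):
            ion_affinity(1.0, coefficients={})
        with pytest.raises(ConfigurationError):
            ion_affinity(1.0, coefficients={"intercept": 0.0, "slope": -1.0})


class TestAffinityDifference:
    def test_buried_vs_exposed_positive(self, state_centers):
        ddg, sites = affinity_difference(state_centers["Ca2"])
        assert ddg > 0
        assert sites[0].site_label == "Ca1"
        assert sites[0].sasa_05 < sites[1].sasa_05

    def test_swapping_labels_negates(self, state_centers):
        s = state_centers["Ca2"]
        ddg, sites = affinity_difference(s)
        serial1 = [x.ion.serial for x in sites if x.site_label == "Ca1"][0]
        serial2 = [x.ion.serial for x in sites if x.site_label == "Ca2"][0]
        swapped, _ = affinity_difference(s, ca1_serial=serial2,
                                         ca2_serial=serial1)
        assert swapped == pytest.approx(-ddg)

    def test_fewer_than_two_ions_raises(self, state_centers):
        with pytest.raises(ComparabilityError):
            affinity_difference(state_centers["Ca1"])

    def test_panel_sd_matches_direct_recomputation(self, base_cfg):
        from metalswitch import GeneratorConfig, gen_center
        reps = []
        for seed in (61, 62, 63):
            cfg = GeneratorConfig(seed=seed, center_sigma=0.05)
            reps.append(gen_center(cfg, state="Ca2"))
        table = en.affinity_difference_panel(reps)
        vals = table["ddg_kJmol"].to_numpy()
        assert table.attrs["mean_ddg"] == pytest.approx(vals.mean())
        assert table.attrs["sd_ddg"] == pytest.approx(vals.std(ddof=1))


# ---------------------------------------------------------------------------
# charge assignment
# ---------------------------------------------------------------------------

def _free_glutamate():
    # Glu with charged termini: net formal charge -1
    atoms = [
        make_atom(1, "N", "GLU", 1, [0, 0, 0]),
        make_atom(2, "CA", "GLU", 1, [1.5, 0, 0]),
        make_atom(3, "C", "GLU", 1, [2.2, 1.2, 0]),
        make_atom(4, "O", "GLU", 1, [1.8, 2.3, 0]),
        make_atom(5, "OXT", "GLU", 1, [3.5, 1.1, 0], element="O"),
        make_atom(6, "CB", "GLU", 1, [2.2, -1.2, 0]),
        make_atom(7, "CG", "GLU", 1, [3.6, -1.2, 0]),
        make_atom(8, "CD", "GLU", 1, [4.3, -2.5, 0]),
        make_atom(9, "OE1", "GLU", 1, [3.7, -3.6, 0], element="O"),
        make_atom(10, "OE2", "GLU", 1, [5.6, -2.5, 0], element="O"),
    ]
    return StructureModel(atoms=atoms)


class TestAssignCharges:
    def test_free_glutamate_net_minus_one(self):
        q = assign_charges(_free_glutamate())
        assert q.total_charge == pytest.approx(-1.0, abs=1e-6)

    def test_calcium_ion_plus_two(self):
        s = StructureModel(atoms=[make_atom(1, "CA", "CA", 402, [0, 0, 0],
                                            het=True)])
        q = assign_charges(s)
        assert q.total_charge == pytest.approx(2.0)

    def test_every_residue_sums_to_integer_charge(self, base_cfg):
        from metalswitch import gen_shhn_like
        s = gen_shhn_like(base_cfg, state="Ca2")
        q = assign_charges(s)
        for (ch, num, icode, rname), atoms in s.residues():
            total = sum(q.charges[s.atoms.index(a)] for a in atoms)
            assert abs(total - round(total)) < 1e-6, (rname, num, total)

    def test_water_without_hydrogens_neutral(self):
        s = StructureModel(atoms=[make_atom(1, "O", "HOH", 501, [0, 0, 0],
                                            het=True)])
        with pytest.warns(UserWarning, match="no hydrogens"):
            q = assign_charges(s)
        assert q.total_charge == 0.0

    def test_uncovered_residue_raises(self):
        s = StructureModel(atoms=[make_atom(1, "C1", "LIG", 1, [0, 0, 0])])
        with pytest.raises(TableCoverageError):
            assign_charges(s)


# ---------------------------------------------------------------------------
# PB solver vs closed forms
# ---------------------------------------------------------------------------

def _single_ion(radius=1.0):
    s = StructureModel(atoms=[make_atom(1, "NA", "NA", 1, [0.0, 0, 0],
                                        het=True)])
    q = ChargeModel(charges=np.array([1.0]), radii=np.array([radius]))
    return s, q


class TestSolvePB:
    def test_coulomb_limit_within_3_percent(self):
        s, q = _single_ion()
        opt = PBOptions(spacing=0.5, padding=12.0, eps_in=79.0, eps_out=79.0,
                        ionic_strength=0.0, tol=1e-7)
        grid = solve_pb(s, q, opt)
        C = en.COULOMB_KJMOL_A / (en.KB_KJMOL * opt.temperature)
        for r in (2.0, 4.0, 6.0, 8.0):  # beyond 3 grid cells
            phi = grid.interpolate(np.array([[r, 0.0, 0.0]]))[0]
            exact = C / (79.0 * r)
            assert abs(phi - exact) / exact < 0.03

    def test_born_solvation_within_5_percent(self):
        s, q = _single_ion(radius=3.0)
        kwargs = dict(spacing=0.4, padding=12.0, ionic_strength=0.0,
                      probe=0.0, tol=1e-7)
        solv = solve_pb(s, q, PBOptions(eps_in=2.0, eps_out=79.0, **kwargs))
        ref = solve_pb(s, q, PBOptions(eps_in=2.0, eps_out=2.0, **kwargs))
        dG = grid_energy(solv, s.coords(), q.charges) \
            - grid_energy(ref, s.coords(), q.charges)
        born = -0.5 * en.COULOMB_KJMOL_A * (1 / 2.0 - 1 / 79.0) / 3.0
        assert abs(dG - born) / abs(born) < 0.05

    def test_zero_charges_zero_potential(self):
        s = StructureModel(atoms=[make_atom(1, "NA", "NA", 1, [0, 0, 0],
                                            het=True)])
        q = ChargeModel(charges=np.array([0.0]), radii=np.array([1.0]))
        grid = solve_pb(s, q, PBOptions(spacing=1.0, padding=6.0))
        assert np.all(grid.phi == 0.0)

    def test_salt_screens_potential(self):
        s, q = _single_ion()
        kwargs = dict(spacing=0.6, padding=15.0, eps_in=79.0, eps_out=79.0,
                      tol=1e-7)
        bare = solve_pb(s, q, PBOptions(ionic_strength=0.0, **kwargs))
        salty = solve_pb(s, q, PBOptions(ionic_strength=0.1, **kwargs))
        pt = np.array([[10.0, 0.0, 0.0]])
        assert salty.interpolate(pt)[0] < 0.6 * bare.interpolate(pt)[0]


# ---------------------------------------------------------------------------
# thermodynamic cycle
# ---------------------------------------------------------------------------

def _dipole_system(with_charge):
    """A 3-point water near an optional +2 ion, positive end toward the ion."""
    atoms = [make_atom(1, "O", "HOH", 501, [0.0, 0.0, 0.0], het=True),
             make_atom(2, "H1", "HOH", 501, [0.59, 0.76, 0.0], het=True,
                       element="H"),
             make_atom(3, "H2", "HOH", 501, [0.59, -0.76, 0.0], het=True,
                       element="H"),
             make_atom(4, "ND1", "HIS", 10, [-6.0, 0.0, 0.0])]
    if with_charge:
        atoms.append(make_atom(5, "CA", "CA", 402, [4.0, 0.0, 0.0], het=True))
    return StructureModel(atoms=atoms)


class TestWaterCycle:
    OPT = PBOptions(spacing=0.7, padding=8.0)

    def test_null_water_gives_zero_ddg(self, state_centers):
        # zero out the water charges via a table override
        table = {("HOH", n): 0.0 for n in ("O", "H1", "H2")}
        res = water_binding_ddg(state_centers, water_key=("A", 501),
                                options=self.OPT, charge_table=table)
        assert res["ddg_Ca1_Ca0"] == pytest.approx(0.0, abs=1e-9)
        assert res["ddg_Ca2_Ca1"] == pytest.approx(0.0, abs=1e-9)

    def test_toy_dipole_sign_matches_coulomb_oracle(self):
        s0, s1 = _dipole_system(False), _dipole_system(True)
        opt = PBOptions(spacing=0.5, padding=10.0, eps_in=79.0, eps_out=79.0,
                        ionic_strength=0.0, tol=1e-7)
        dg0 = binding_energy(s0, water_key=("A", 501), options=opt)
        dg1 = binding_energy(s1, water_key=("A", 501), options=opt)
        ddg = dg1 - dg0
        # Coulomb oracle: interaction of the ion with the water charges
        C = en.COULOMB_KJMOL_A / 79.0
        wq = {"O": -0.8476, "H1": 0.4238, "H2": 0.4238}
        ion = np.array([4.0, 0.0, 0.0])
        pos = {"O": np.array([0.0, 0, 0]), "H1": np.array([0.59, 0.76, 0]),
               "H2": np.array([0.59, -0.76, 0])}
        oracle = sum(C * 2.0 * q / np.linalg.norm(ion - pos[n])
                     for n, q in wq.items())
        assert oracle > 0
        assert np.sign(ddg) == np.sign(oracle)
        assert ddg == pytest.approx(oracle, rel=0.15)

    def test_cycle_closes_algebraically(self, state_centers):
        res = water_binding_ddg(state_centers, water_key=("A", 501),
                                options=self.OPT)
        assert res["ddg_Ca2_Ca0"] == pytest.approx(
            res["ddg_Ca1_Ca0"] + res["ddg_Ca2_Ca1"], abs=1e-9)

    def test_each_added_calcium_destabilizes_water(self, state_centers):
        res = water_binding_ddg(state_centers, water_key=("A", 501),
                                options=self.OPT)
        assert res["ddg_Ca1_Ca0"] > 0
        assert res["ddg_Ca2_Ca1"] > 0

    def test_halved_spacing_stable_within_10_percent(self):
        s0, s1 = _dipole_system(False), _dipole_system(True)
        vals = []
        for spacing in (0.8, 0.4):
            opt = PBOptions(spacing=spacing, padding=10.0, eps_in=79.0,
                            eps_out=79.0, ionic_strength=0.0, tol=1e-7)
            vals.append(binding_energy(s1, ("A", 501), options=opt)
                        - binding_energy(s0, ("A", 501), options=opt))
        assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.10

    def test_mismatched_states_raise(self, state_centers):
        bad = state_centers["Ca1"].copy()
        bad.atoms.pop(0)
        with pytest.raises(ComparabilityError):
            water_binding_ddg({"Ca0": state_centers["Ca0"], "Ca1": bad},
                              water_key=("A", 501), options=self.OPT)


# ---------------------------------------------------------------------------
# surface potential
# ---------------------------------------------------------------------------

class TestSurfacePotential:
    def test_zero_charges_zero_surface(self):
        s = StructureModel(atoms=[make_atom(1, "NA", "NA", 1, [0, 0, 0],
                                            het=True)])
        q = ChargeModel(charges=np.array([0.0]), radii=np.array([1.5]))
        pts, vals, _ = surface_potential(
            s, q, options=PBOptions(spacing=1.0, padding=6.0))
        assert len(pts) > 0
        assert np.allclose(vals, 0.0)

    def test_added_cation_raises_patch_mean(self):
        base_atoms = [make_atom(1, "ND1", "HIS", 10, [0, 0, 0])]
        s0 = StructureModel(atoms=[a.copy() for a in base_atoms])
        atoms1 = [a.copy() for a in base_atoms]
        atoms1.append(make_atom(2, "CA", "CA", 402, [3.0, 0, 0], het=True))
        s1 = StructureModel(atoms=atoms1)
        opt = PBOptions(spacing=0.6, padding=8.0)
        patches = {"site": [("A", 10, "ND1")]}
        _, _, p0 = surface_potential(s0, assign_charges(s0), options=opt,
                                     patches=patches)
        _, _, p1 = surface_potential(s1, assign_charges(s1), options=opt,
                                     patches=patches)
        assert p1["site"] > p0["site"]

    def test_zinc_patch_potential_increases_with_calcium(self, state_centers):
        opt = PBOptions(spacing=0.8, padding=8.0)
        patches = {"zinc": [("A", 401, "ZN")]}
        means = []
        for lab in ("Ca0", "Ca1", "Ca2"):
            s = state_centers[lab]
            _, _, p = surface_potential(s, assign_charges(s), options=opt,
                                        patches=patches)
            means.append(p["zinc"])
        assert means[0] < means[1] < means[2]

    def test_empty_patch_raises(self, state_centers):
        s = state_centers["Ca0"]
        with pytest.raises(ValueError):
            surface_potential(s, assign_charges(s),
                              options=PBOptions(spacing=1.0, padding=6.0),
                              patches={"empty": []})
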