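"""Free-energy machinery: minimizer contract, KB score, GB/SA, entropy."""

import numpy as np
import pytest
import scipy.constants as sc

from liddock.analysis import Trajectory
from liddock.energy import COULOMB_CONSTANT
from liddock.freeenergy import (GB_OFFSET, GB_RADII, GBSABreakdown,
                                GBSAParams, KBScoreBreakdown, PreconditionError,
                                default_energy_function, gb_polar_energy,
                                kb_score, minimize_structure, mm_energy,
                                mmgbsa_binding, normal_mode_entropy,
                                sasa_nonpolar, sasa_per_atom)
from liddock.remc import KB
from liddock.structure import (Atom, Residue, Structure,
                               assign_atom_classes)
from liddock.synthetic import make_harmonic_system


def _ion(q=-1.0, element="O"):
    s = Structure([Residue("ION", 1, "A",
                           [Atom(element, element, [0, 0, 0],
                                 partial_charge=q,
                                 hbond_class="acceptor")])])
    return s


class TestMinimizer:
    def test_already_minimal_diatomic_unchanged(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        out, rep = minimize_structure(s, max_steps=0)
        assert rep.converged
        assert rep.steps == 0
        np.testing.assert_array_equal(out.get_coords(), s.get_coords())

    def test_displaced_diatomic_converges_to_equilibrium(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        c = s.get_coords()
        c[1, 0] += 0.5
        s.set_coords(c)
        out, rep = minimize_structure(s)
        assert rep.converged
        assert rep.max_gradient <= 0.1
        r = np.linalg.norm(out.get_coords()[1] - out.get_coords()[0])
        assert r == pytest.approx(1.5, abs=1e-4)

    def test_zero_budget_on_nonminimal_input_reports_failure(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        c = s.get_coords()
        c[1, 0] += 0.5
        s.set_coords(c)
        _, rep = minimize_structure(s, max_steps=0)
        assert not rep.converged

    def test_energy_never_increases(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            s = make_harmonic_system([120.0, 80.0], [12.0, 14.0, 16.0])
            s.set_coords(s.get_coords() + rng.normal(scale=0.3, size=(3, 3)))
            fun = default_energy_function(s)
            e0 = fun(s.get_coords().ravel())
            out, rep = minimize_structure(s)
            assert rep.energy_final <= e0 + 1e-12


class TestKbScore:
    def _parts(self, separation):
        rec = assign_atom_classes(Structure([Residue(
            "GLY", 1, "R", [Atom("CA", "C", [0, 0, 0]),
                            Atom("O", "O", [1.3, 0, 0])])]))
        lig = assign_atom_classes(Structure([Residue(
            "GLY", 2, "L", [Atom("CA", "C", [separation, 0, 0]),
                            Atom("N", "N", [separation + 1.3, 0, 0])])]))
        return rec, lig

    def test_separated_ligand_leaves_only_entropy(self):
        rec, lig = self._parts(500.0)
        bd = kb_score(rec, lig)
        assert bd.dG_hydrophobic == 0.0
        assert bd.dG_hydrogen_bond == 0.0
        assert bd.dG_vdW == 0.0
        assert bd.dG_electrostatic == 0.0
        assert bd.dG_desolvation == 0.0
        assert bd.dG_total == pytest.approx(bd.dG_entropy, abs=1e-12)

    def test_total_is_weighted_sum(self):
        rec, lig = self._parts(4.0)
        bd = kb_score(rec, lig)
        s = (bd.dG_hydrophobic + bd.dG_hydrogen_bond + bd.dG_vdW
             + bd.dG_electrostatic + bd.dG_desolvation + bd.dG_entropy)
        assert bd.dG_total == pytest.approx(s, abs=1e-9)

    def test_doubling_weights_doubles_total(self):
        from liddock.freeenergy import DEFAULT_KB_WEIGHTS
        rec, lig = self._parts(4.0)
        w2 = {k: 2 * v for k, v in DEFAULT_KB_WEIGHTS.items()}
        assert kb_score(rec, lig, weights=w2).dG_total == pytest.approx(
            2 * kb_score(rec, lig).dG_total, rel=1e-9)

    def test_unknown_weight_key_rejected(self):
        rec, lig = self._parts(4.0)
        with pytest.raises(ValueError):
            kb_score(rec, lig, weights={"bogus": 1.0})

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(ValueError):
            KBScoreBreakdown(1, 0, 0, 0, 0, 0, dG_total=99.0)


def _three_residue_toy(gaps=(9.0, 21.0)):
    """CA-only residues at controlled inter-residue separations."""
    xs = [0.0, gaps[0], gaps[0] + gaps[1]]
    residues = [Residue("GLY", i + 1, "A",
                        [Atom("CA", "C", [x, 0, 0], partial_charge=0.3,
                              epsilon=0.1)])
                for i, x in enumerate(xs)]
    return assign_atom_classes(Structure(residues))


class TestMmEnergy:
    def test_residue_cutoff_bands(self):
        # pair at 9 A: beyond 8 A vdw cutoff, inside 20 A ele cutoff
        s = _three_residue_toy(gaps=(9.0, 21.0))
        ele, vdw, _ = mm_energy(s)
        pair_9 = COULOMB_CONSTANT * 0.09 / 9.0
        assert vdw == 0.0
        assert ele == pytest.approx(pair_9, rel=1e-12)  # 21 and 30 A excluded

    def test_beyond_electrostatic_cutoff_zero(self):
        s = _three_residue_toy(gaps=(21.0, 21.0))
        ele, vdw, _ = mm_energy(s)
        assert ele == 0.0 and vdw == 0.0

    def test_matches_brute_force_with_cutoff_logic(self):
        rng = np.random.default_rng(17)
        residues = []
        for i in range(3):
            base = rng.uniform(0, 12, 3)
            atoms = [Atom(f"C{k}", "C", base + rng.uniform(-1, 1, 3),
                          partial_charge=rng.uniform(-0.4, 0.4), epsilon=0.1)
                     for k in range(3)]
            residues.append(Residue("GLY", i + 1, "A", atoms))
        s = assign_atom_classes(Structure(residues))
        p = GBSAParams()
        ele, vdw, _ = mm_energy(s, p)
        coords = s.get_coords()
        atoms = s.atoms
        exp_ele = exp_vdw = 0.0
        for gi in range(3):
            for gj in range(gi + 1, 3):
                ai = [gi * 3 + k for k in range(3)]
                aj = [gj * 3 + k for k in range(3)]
                dmin = min(np.linalg.norm(coords[i] - coords[j])
                           for i in ai for j in aj)
                for i in ai:
                    for j in aj:
                        r = np.linalg.norm(coords[i] - coords[j])
                        if dmin <= p.vdw_cutoff:
                            e = np.sqrt(atoms[i].epsilon * atoms[j].epsilon)
                            sr6 = (0.5 * (atoms[i].sigma + atoms[j].sigma)
                                   / r) ** 6
                            exp_vdw += 4 * e * (sr6 ** 2 - sr6)
                        if dmin <= p.ele_cutoff:
                            exp_ele += (COULOMB_CONSTANT
                                        * atoms[i].partial_charge
                                        * atoms[j].partial_charge / r)
        assert vdw == pytest.approx(exp_vdw, abs=1e-9)
        assert ele == pytest.approx(exp_ele, abs=1e-9)


class TestGbPolar:
    def test_single_ion_matches_born_equation(self):
        g = gb_polar_energy(_ion())
        r_born = GB_RADII["O"] - GB_OFFSET
        born = -0.5 * COULOMB_CONSTANT * (1 / 2 - 1 / 80) / r_born
        assert g == pytest.approx(born, rel=1e-6)

    def test_zero_charges_zero_energy(self):
        assert gb_polar_energy(_ion(q=0.0)) == 0.0

    def test_more_negative_with_rising_exterior_dielectric(self):
        vals = [gb_polar_energy(_ion(), GBSAParams(eps_exterior=e))
                for e in (2.0 + 1e-9, 4.0, 20.0, 80.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_vanishes_as_dielectrics_equalize(self):
        g = gb_polar_energy(_ion(), GBSAParams(eps_interior=80.0,
                                               eps_exterior=80.0))
        assert g == pytest.approx(0.0, abs=1e-12)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area, dg = sasa_nonpolar(_ion())
        exact = 4 * np.pi * (GB_RADII["O"] + 1.4) ** 2
        assert area == pytest.approx(exact, rel=1e-3)

    def test_nonpolar_term_is_tension_times_area(self):
        area, dg = sasa_nonpolar(_ion())
        assert dg == pytest.approx(0.0072 * area, rel=1e-12)

    def test_overlapping_spheres_occlude(self):
        one = sasa_per_atom(np.array([[0.0, 0, 0]]), np.array([1.7]))
        two = sasa_per_atom(np.array([[0.0, 0, 0], [0.5, 0, 0]]),
                            np.array([1.7, 1.7]))
        assert two[0] < one[0]

    def test_monte_carlo_oracle_agreement(self):
        # independent randomized surface-point estimate of a two-sphere SASA
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.7, 1.5]) + 1.4
        ours = sasa_per_atom(coords, np.array([1.7, 1.5]), 1.4, 960)
        rng = np.random.default_rng(0)
        for i in range(2):
            pts = rng.normal(size=(40_000, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            surf = coords[i] + radii[i] * pts
            j = 1 - i
            frac = np.mean(np.linalg.norm(surf - coords[j], axis=1) >= radii[j])
            mc = frac * 4 * np.pi * radii[i] ** 2
            assert ours[i] == pytest.approx(mc, rel=0.02)


class TestNormalModeEntropy:
    def test_diatomic_vibrational_closed_form(self):
        k, m = 100.0, 12.0
        s = make_harmonic_system([k], [m, m])
        ts_trans, ts_rot, ts_vib, ts_total = normal_mode_entropy(s, 300.0)
        omega_si = np.sqrt(k / (m / 2)) * np.sqrt(4.184e26)
        expected = 300.0 * KB * (1 + np.log(sc.k * 300.0 / (sc.hbar * omega_si)))
        assert ts_vib == pytest.approx(expected, rel=1e-4)
        assert ts_total == pytest.approx(ts_trans + ts_rot + ts_vib, abs=1e-12)

    def test_temperature_dependence_follows_closed_form(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        ts300 = normal_mode_entropy(s, 300.0)[2]
        ts600 = normal_mode_entropy(s, 600.0)[2]
        omega_si = np.sqrt(100.0 / 6.0) * np.sqrt(4.184e26)
        for t, val in ((300.0, ts300), (600.0, ts600)):
            expected = t * KB * (1 + np.log(sc.k * t / (sc.hbar * omega_si)))
            assert val == pytest.approx(expected, rel=1e-4)

    def test_invariant_under_rigid_translation(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        ref = normal_mode_entropy(s, 300.0)
        s2 = s.copy()
        s2.set_coords(s.get_coords() + np.array([7.0, -2.0, 3.0]))
        moved = normal_mode_entropy(s2, 300.0)
        np.testing.assert_allclose(moved, ref, rtol=1e-9)

    def test_unminimized_input_rejected(self):
        s = make_harmonic_system([100.0], [12.0, 12.0])
        c = s.get_coords()
        c[1, 0] += 0.5
        s.set_coords(c)
        with pytest.raises(PreconditionError):
            normal_mode_entropy(s, 300.0)


def _complex_topology(separation=30.0):
    """Two-residue 'complex': receptor residue + ligand residue, far apart."""
    residues = [
        Residue("GLY", 1, "R", [Atom("CA", "C", [0, 0, 0], partial_charge=0.2,
                                     epsilon=0.1),
                                Atom("O", "O", [1.3, 0, 0],
                                     partial_charge=-0.2)]),
        Residue("GLY", 2, "L", [Atom("CA", "C", [separation, 0, 0],
                                     partial_charge=-0.1, epsilon=0.1),
                                Atom("N", "N", [separation + 1.3, 0, 0],
                                     partial_charge=0.1)]),
    ]
    return assign_atom_classes(Structure(residues))


class TestMmgbsa:
    def test_breakdown_identities(self):
        with pytest.raises(ValueError):
            GBSABreakdown(1, 1, 1, 99, 0, 0, 0, 0, 0)
        bd = GBSABreakdown.build(1.0, 2.0, 3.0, 0.5, -4.0, 1.5)
        assert bd.dE_MM_gas == 6.0
        assert bd.dG_gb_total == -3.5
        assert bd.dG_total == pytest.approx(6.0 - 3.5 + 1.5)

    def test_separated_parts_cancel_without_minimization(self):
        top = _complex_topology(separation=30.0)
        traj = Trajectory(top, [top.get_coords()], [0.0])
        bd = mmgbsa_binding(traj, [0], [1], minimize_parts=False)
        assert bd.dE_ele == pytest.approx(0.0, abs=1e-9)
        assert bd.dE_vdw == pytest.approx(0.0, abs=1e-9)
        assert bd.dE_int == pytest.approx(0.0, abs=1e-9)

    def test_identical_frames_equal_single_frame(self):
        top = _complex_topology(separation=6.0)
        c = top.get_coords()
        one = mmgbsa_binding(Trajectory(top, [c], [0.0]), [0], [1])
        three = mmgbsa_binding(Trajectory(top, [c, c, c], [0.0, 1.0, 2.0]),
                               [0], [1])
        assert three.dG_total == pytest.approx(one.dG_total, abs=1e-9)

    def test_frame_order_permutation_invariant(self):
        top = _complex_topology(separation=6.0)
        rng = np.random.default_rng(4)
        frames = [top.get_coords() + rng.normal(scale=0.05, size=(4, 3))
                  for _ in range(4)]
        a = mmgbsa_binding(Trajectory(top, frames, np.arange(4.0)), [0], [1])
        b = mmgbsa_binding(Trajectory(top, frames[::-1], np.arange(4.0)),
                           [0], [1])
        assert a.dG_total == pytest.approx(b.dG_total, abs=1e-9)

    def test_missing_part_rejected(self):
        top = _complex_topology()
        traj = Trajectory(top, [top.get_coords()], [0.0])
        with pytest.raises(ValueError):
            mmgbsa_binding(traj, [0], [5])

    def test_reduces_to_gas_interaction_with_solvation_disabled(self):
        # with no charges/solvation and close contact, dG == dE_MM_gas == dE_vdw
        residues = [
            Residue("GLY", 1, "R", [Atom("CA", "C", [0, 0, 0], epsilon=0.2)]),
            Residue("GLY", 2, "L", [Atom("CA", "C", [3.6, 0, 0], epsilon=0.2)]),
        ]
        top = assign_atom_classes(Structure(residues))
        params = GBSAParams(surface_tension=0.0)
        traj = Trajectory(top, [top.get_coords()], [0.0])
        bd = mmgbsa_binding(traj, [0], [1], params=params)
        sr6 = (3.2 / 3.6) ** 6
        lj = 4 * 0.2 * (sr6 ** 2 - sr6)
        assert bd.dE_vdw == pytest.approx(lj, rel=1e-9)
        assert bd.dG_total == pytest.approx(lj, abs=1e-9)
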