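import numpy as np
import pytest

import oracles
from conftest import make_atom
from coagdesign.core import Structure, Trajectory, ValidationError
from coagdesign.energetics import (
    COULOMB_CONSTANT,
    EnergeticsConfig,
    binding_free_energy,
    born_radii,
    coulomb_energy,
    difference_map,
    gb_polar_energy,
    interface_pairs,
    lj_energy,
    nonpolar_energy,
    per_residue_decomposition,
    sasa,
)
from coagdesign.params import vdw_radius

SIGMA_FOR_RADIUS_2 = 2 * 2.0 / 2 ** (1 / 6)  # lj_sigma giving vdW radius 2 A


def _two_atoms(r, q1=1.0, q2=-1.0, sigma=3.0, eps=0.5):
    atoms = [make_atom("A", "O", 1, "GLY", "A", charge=q1, sigma=sigma, epsilon=eps),
             make_atom("B", "O", 2, "GLY", "A", charge=q2, sigma=sigma, epsilon=eps)]
    return Structure(atoms, np.array([[0, 0, 0], [r, 0, 0.]]))


class TestCoulomb:
    def test_unit_charges_5A_eps2(self):
        s = _two_atoms(5.0)
        assert coulomb_energy(s, [(0, 1)], eps_in=2.0) == \
            pytest.approx(-COULOMB_CONSTANT / 10.0)  # = -138.935458

    def test_zero_charges(self):
        s = _two_atoms(5.0, q1=0.0, q2=0.0)
        assert coulomb_energy(s, [(0, 1)], 2.0) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        atoms = [make_atom(f"A{i}", "O", i + 1, "GLY", "A",
                           charge=rng.uniform(-1, 1)) for i in range(4)]
        coords = rng.uniform(-5, 5, (4, 3))
        s = Structure(atoms, coords)
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        got = coulomb_energy(s, pairs, 2.0)
        expected = oracles.brute_coulomb([a.partial_charge for a in atoms],
                                         coords, pairs, 2.0)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_singularity_rejected(self):
        s = _two_atoms(5.0)
        s.coords[1] = s.coords[0]
        with pytest.raises(ValidationError):
            coulomb_energy(s, [(0, 1)], 2.0)


class TestLennardJones:
    def test_zero_at_sigma(self):
        s = _two_atoms(3.0)  # r equals combined sigma
        assert lj_energy(s, [(0, 1)]) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_minus_epsilon(self):
        s = _two_atoms(3.0 * 2 ** (1 / 6))
        assert lj_energy(s, [(0, 1)]) == pytest.approx(-0.5, rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        atoms = [make_atom(f"A{i}", "C", i + 1, "GLY", "A",
                           sigma=rng.uniform(2.5, 3.5),
                           epsilon=rng.uniform(0.1, 1.0)) for i in range(3)]
        coords = rng.uniform(-4, 4, (3, 3))
        s = Structure(atoms, coords)
        pairs = [(0, 1), (0, 2), (1, 2)]
        expected = oracles.brute_lj([a.lj_sigma for a in atoms],
                                    [a.lj_epsilon for a in atoms], coords, pairs)
        assert lj_energy(s, pairs) == pytest.approx(expected, rel=1e-9)


class TestGeneralizedBorn:
    def test_single_ion_closed_form(self):
        ion = Structure([make_atom("I", "O", 1, "GLY", "A", charge=1.0,
                                   sigma=SIGMA_FOR_RADIUS_2)], np.zeros((1, 3)))
        assert vdw_radius(ion.atoms[0]) == pytest.approx(2.0)
        expected = -0.5 * (1 / 2 - 1 / 80) * COULOMB_CONSTANT / 2.0  # -169.33
        got = gb_polar_energy(ion, EnergeticsConfig(eps_in=2.0, eps_out=80.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-169.3, abs=0.05)

    def test_zero_charges(self):
        s = _two_atoms(6.0, q1=0.0, q2=0.0)
        assert gb_polar_energy(s) == 0.0

    def test_eps_equal_limit_vanishes(self):
        s = _two_atoms(6.0)
        cfg = EnergeticsConfig(eps_in=10.0, eps_out=10.0)
        assert gb_polar_energy(s, cfg) == 0.0

    def test_two_ion_matches_scalar_oracle(self):
        s = _two_atoms(6.0, q1=1.0, q2=-1.0, sigma=SIGMA_FOR_RADIUS_2)
        radii = [vdw_radius(a) for a in s.atoms]
        expected = oracles.scalar_gb_energy([1.0, -1.0], s.coords, radii, 2.0, 80.0)
        got = gb_polar_energy(s, EnergeticsConfig())
        assert got == pytest.approx(expected, rel=1e-9)

    def test_born_radii_match_scalar_oracle(self, glucagon_helix):
        sub = Structure(glucagon_helix.atoms[:30], glucagon_helix.coords[:30])
        got = born_radii(sub)
        radii = [vdw_radius(a) for a in sub.atoms]
        expected = oracles.scalar_born_radii(sub.coords, radii)
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = Structure([make_atom("S", "C", 1, "GLY", "A",
                                 sigma=1.6 * 2 / 2 ** (1 / 6))], np.zeros((1, 3)))
        area = sasa(s, probe=1.4)[0]
        assert area == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.02)

    def test_coincident_spheres_count_once(self):
        # two identical fully overlapping spheres expose one sphere's area
        atoms = [make_atom("A", "C", 1, "GLY", "A", sigma=3.0),
                 make_atom("B", "C", 2, "GLY", "A", sigma=3.0)]
        s = Structure(atoms, np.array([[0, 0, 0], [1e-4, 0, 0.]]))
        r = vdw_radius(atoms[0]) + 1.4
        assert sasa(s, 1.4).sum() == pytest.approx(4 * np.pi * r ** 2, rel=0.02)

    def test_three_sphere_matches_fine_grid(self):
        rng = np.random.default_rng(4)
        atoms = [make_atom(f"A{i}", "C", i + 1, "GLY", "A",
                           sigma=rng.uniform(2.8, 3.4)) for i in range(3)]
        coords = np.array([[0, 0, 0], [2.5, 0, 0], [1.0, 2.2, 0.]])
        s = Structure(atoms, coords)
        got = sasa(s, 1.4)
        radii = np.array([vdw_radius(a) for a in atoms])
        expected = oracles.fine_grid_sasa(coords, radii, 1.4)
        np.testing.assert_allclose(got, expected, rtol=0.02)


class TestBindingFreeEnergy:
    def _noninteracting(self):
        # zero charges, ligand 30 A from receptor, LJ negligible at range
        atoms, coords = [], []
        for chain, offset in (("P", 0.0), ("R", 40.0)):
            for r in (1, 2):
                atoms.append(make_atom("CA", "C", r, "GLY", chain,
                                       charge=0.0, epsilon=0.0))
                coords.append([offset + r * 4.0, 0, 0])
        cfg = EnergeticsConfig(gamma_sasa=0.0)
        s = Structure(atoms, np.array(coords, dtype=float))
        return Trajectory(s.atoms, s.coords[None]), cfg

    def test_noninteracting_limit_zero(self):
        traj, cfg = self._noninteracting()
        dec = binding_free_energy(traj, [("P", 1), ("P", 2)],
                                  [("R", 1), ("R", 2)], cfg)
        assert abs(dec.totals["total"]) < 1e-6

    def test_salt_bridge_lowers_elec_monotonically(self, glucagon):
        from coagdesign.pipeline import make_demo_system

        elec = []
        for dist in (4.0, 3.5, 3.0):
            traj, cx, _, _ = make_demo_system(
                glucagon, n_frames=2, seed=2, fluctuation_sigma=0.0,
                saltbridge_distance=dist, saltbridge_occupancy=1.0)
            lig = [k for k in cx.residue_keys() if k[0] == "P"]
            rec = [k for k in cx.residue_keys() if k[0] == "R"]
            dec = per_residue_decomposition(traj, lig, rec,
                                            EnergeticsConfig(frame_stride=2))
            elec.append(dec.totals["elec"])
        assert elec[0] > elec[1] > elec[2]

    def test_two_frame_average_matches_brute_force(self):
        rng = np.random.default_rng(6)
        atoms = []
        coords = []
        for chain, base in (("P", [0, 0, 0]), ("R", [7, 0, 0])):
            for r in (1, 2):
                atoms.append(make_atom("CA", "C", r, "GLY", chain,
                                       charge=rng.uniform(-0.5, 0.5),
                                       sigma=3.0, epsilon=0.3))
                coords.append(np.array(base) + [0, r * 3.0, 0])
        base = np.array(coords, dtype=float)
        frames = np.stack([base, base + rng.normal(0, 0.3, base.shape)])
        traj = Trajectory(atoms, frames)
        cfg = EnergeticsConfig()
        dec = binding_free_energy(traj, [("P", 1), ("P", 2)],
                                  [("R", 1), ("R", 2)], cfg)

        lig_idx, rec_idx = [0, 1], [2, 3]
        pairs = interface_pairs(lig_idx, rec_idx)
        per_frame = []
        for f in frames:
            q = [a.partial_charge for a in atoms]
            sig = [a.lj_sigma for a in atoms]
            epsv = [a.lj_epsilon for a in atoms]
            elec = oracles.brute_coulomb(q, f, pairs, cfg.eps_in)
            vdw = oracles.brute_lj(sig, epsv, f, pairs)
            radii = [vdw_radius(a) for a in atoms]
            gb_cx = oracles.scalar_gb_energy(q, f, radii, cfg.eps_in, cfg.eps_out)
            gb_l = oracles.scalar_gb_energy([q[i] for i in lig_idx],
                                            f[lig_idx], [radii[i] for i in lig_idx],
                                            cfg.eps_in, cfg.eps_out)
            gb_r = oracles.scalar_gb_energy([q[i] for i in rec_idx],
                                            f[rec_idx], [radii[i] for i in rec_idx],
                                            cfg.eps_in, cfg.eps_out)
            sas_cx = sasa(Structure(atoms, f), cfg.probe_radius).sum()
            sas_l = sasa(Structure([atoms[i] for i in lig_idx], f[lig_idx]),
                         cfg.probe_radius).sum()
            sas_r = sasa(Structure([atoms[i] for i in rec_idx], f[rec_idx]),
                         cfg.probe_radius).sum()
            nonpolar = cfg.gamma_sasa * (sas_cx - sas_l - sas_r)
            per_frame.append(elec + vdw + (gb_cx - gb_l - gb_r) + nonpolar)
        assert dec.totals["total"] == pytest.approx(np.mean(per_frame), rel=1e-9)

    def test_rigid_motion_invariance(self, glucagon):
        from scipy.spatial.transform import Rotation

        from coagdesign.pipeline import make_demo_system

        traj, cx, _, _ = make_demo_system(glucagon, n_frames=2, seed=3,
                                          fluctuation_sigma=0.1)
        lig = [k for k in cx.residue_keys() if k[0] == "P"]
        rec = [k for k in cx.residue_keys() if k[0] == "R"]
        cfg = EnergeticsConfig(frame_stride=2)
        a = per_residue_decomposition(traj, lig, rec, cfg).totals
        rot = Rotation.random(random_state=np.random.default_rng(0)).as_matrix()
        moved = Trajectory(traj.topology, traj.frames @ rot.T + 11.0)
        b = per_residue_decomposition(moved, lig, rec, cfg).totals
        # analytic terms are exactly invariant; the SASA term only up to
        # the orientation discretization of the 960-point sphere grid
        for c in ("elec", "vdw", "polar_solv"):
            assert a[c] == pytest.approx(b[c], rel=1e-6, abs=1e-6)
        assert a["nonpolar_solv"] == pytest.approx(b["nonpolar_solv"], rel=5e-3)
        assert a["total"] == pytest.approx(b["total"], rel=5e-3, abs=0.05)

    def test_empty_selection_rejected(self):
        traj, cfg = self._noninteracting()
        with pytest.raises(ValidationError):
            binding_free_energy(traj, [], [("R", 1), ("R", 2)], cfg)


class TestDecompositionConservation:
    def test_column_sums_equal_totals(self, demo_system):
        traj, cx, _, _ = demo_system
        lig = [k for k in cx.residue_keys() if k[0] == "P"]
        rec = [k for k in cx.residue_keys() if k[0] == "R"]
        dec = per_residue_decomposition(
            Trajectory(traj.topology, traj.frames[:4]), lig, rec,
            EnergeticsConfig(frame_stride=2))
        tot = dec.totals
        for comp in ("elec", "vdw", "polar_solv", "nonpolar_solv"):
            col = sum(v[comp] for v in dec.per_residue.values())
            assert col == pytest.approx(tot[comp], rel=1e-6, abs=1e-9)
        for v in dec.per_residue.values():
            assert v["total"] == pytest.approx(
                v["elec"] + v["vdw"] + v["polar_solv"] + v["nonpolar_solv"],
                rel=1e-9, abs=1e-12)

    def test_symmetric_interface_splits_equally(self):
        atoms = [make_atom("CA", "C", 1, "GLY", "P", charge=0.5, epsilon=0.0),
                 make_atom("CA", "C", 1, "GLY", "R", charge=0.5, epsilon=0.0)]
        coords = np.array([[0, 0, 0], [6.0, 0, 0]])
        traj = Trajectory(atoms, coords[None])
        cfg = EnergeticsConfig(gamma_sasa=0.0, eps_out=2.0)  # MM terms only
        dec = per_residue_decomposition(traj, [("P", 1)], [("R", 1)], cfg)
        assert dec.per_residue[("P", 1)]["elec"] == \
            pytest.approx(dec.per_residue[("R", 1)]["elec"], rel=1e-12)

    def test_zero_charges_zero_elec_column(self, demo_system):
        traj, cx, _, _ = demo_system
        import dataclasses

        atoms = [dataclasses.replace(a, partial_charge=0.0) for a in traj.topology]
        t2 = Trajectory(atoms, traj.frames[:2])
        lig = [k for k in cx.residue_keys() if k[0] == "P"]
        rec = [k for k in cx.residue_keys() if k[0] == "R"]
        dec = per_residue_decomposition(t2, lig, rec,
                                        EnergeticsConfig(frame_stride=2))
        assert all(v["elec"] == 0.0 for v in dec.per_residue.values())


class TestDifferenceMap:
    def _dec(self, totals):
        per = {}
        for key, t in totals.items():
            per[key] = {"elec": t, "vdw": 0.0, "polar_solv": 0.0,
                        "nonpolar_solv": 0.0, "total": t}
        from coagdesign.energetics import EnergyDecomposition

        return EnergyDecomposition(per)

    def test_identical_is_zero(self):
        a = self._dec({("P", i): -float(i) for i in range(1, 5)})
        d = difference_map(a, a)
        assert all(v == 0.0 for v in d["delta"].values())

    def test_shift_at_one_position(self):
        a = self._dec({("P", 15): -10.0, ("P", 16): -20.0})
        b = self._dec({("P", 15): -10.0, ("P", 16): -15.0})
        d = difference_map(a, b)
        assert d["delta"][("P", 16)] == pytest.approx(-5.0)
        assert d["delta"][("P", 15)] == 0.0

    def test_missing_positions_reported_not_zeroed(self):
        a = self._dec({("P", 1): -1.0, ("P", 2): -2.0})
        b = self._dec({("P", 2): -2.0, ("P", 3): -3.0})
        d = difference_map(a, b)
        assert d["only_a"] == [("P", 1)] and d["only_b"] == [("P", 3)]
        assert set(d["delta"]) == {("P", 2)}

    def test_disjoint_rejected(self):
        a = self._dec({("P", 1): -1.0})
        b = self._dec({("P", 2): -2.0})
        with pytest.raises(ValidationError):
            difference_map(a, b)

    def test_random_pair_matches_elementwise(self):
        rng = np.random.default_rng(9)
        keys = [("P", i) for i in range(1, 8)]
        ta = {k: rng.normal() for k in keys}
        tb = {k: rng.normal() for k in keys}
        d = difference_map(self._dec(ta), self._dec(tb))
        for k in keys:
            assert d["delta"][k] == pytest.approx(ta[k] - tb[k], rel=1e-12)
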