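"""Potential-energy terms: closed-form oracles, analytic forces, rigid-body
invariance, Newton's third law."""

import math

import numpy as np
import pytest

import forkcg
from forkcg import units
from forkcg.energy import (debye_huckel_energy, excluded_volume_energy,
                           go_energy, numerical_gradient, total_energy_forces)
from forkcg.model import ChainRecord, ChargeTable, ContactSet, Topology
from forkcg.system import ElectrostaticParams, compile_system


def _pair_coords(r):
    return np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])


class TestGoEnergy:
    def test_two_contacts_at_native_distance(self):
        """Each pair contributes −σε at r = r0 (5 − 6 = −1)."""
        cs = ContactSet([(0, 1, 5.0, 1.0), (2, 3, 5.0, 1.0)], sigma=0.7)
        coords = np.array([[0, 0, 0], [5.0, 0, 0], [0, 20, 0], [5.0, 20, 0]],
                          dtype=float)
        e, _ = go_energy(coords, cs)
        assert e == pytest.approx(-1.4, abs=1e-12)

    def test_decay_at_long_range(self):
        cs = ContactSet([(0, 1, 5.0, 1.0)], sigma=1.0)
        e, _ = go_energy(_pair_coords(50.0), cs)
        assert abs(e) < 1e-6

    def test_matches_direct_scalar_evaluation(self):
        r0, r = 5.0, 4.5
        cs = ContactSet([(0, 1, r0, 1.0)], sigma=1.0)
        e, _ = go_energy(_pair_coords(r), cs)
        q = r0 / r
        assert e == pytest.approx(5 * q**12 - 6 * q**10, rel=1e-12)

    def test_minimum_exactly_at_native_distance(self):
        cs = ContactSet([(0, 1, 5.0, 1.0)], sigma=1.0)
        _, f = go_energy(_pair_coords(5.0), cs)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_zero_distance_errors(self):
        cs = ContactSet([(0, 1, 5.0, 1.0)], sigma=1.0)
        with pytest.raises(ValueError):
            go_energy(np.zeros((2, 3)), cs)


class TestDebyeHuckel:
    def _charges(self, q, n=2, dna=False):
        arr = np.full(n, q, dtype=float)
        return ChargeTable(arr, arr, np.full(n, dna))

    def test_closed_form_oracle(self):
        """Unit charges at 10 Å in 300 mM / ε 78 / 300 K screened Coulomb."""
        p = ElectrostaticParams(cutoff=None)
        lam = p.debye_length
        assert lam == pytest.approx(5.55, abs=0.01)
        ch = ChargeTable(np.array([1.0, -1.0]), np.array([1.0, -1.0]),
                         np.zeros(2, bool))
        e, _ = debye_huckel_energy(_pair_coords(10.0), ch, p)
        expect = units.COULOMB / 78.0 * (-1.0) * math.exp(-10.0 / lam) / 10.0
        assert e == pytest.approx(expect, rel=1e-12)

    def test_zero_charge_contributes_nothing(self):
        ch = ChargeTable(np.array([0.0, -1.0]), np.array([0.0, -1.0]),
                         np.zeros(2, bool))
        e, f = debye_huckel_energy(_pair_coords(8.0), ch)
        assert e == 0.0 and np.all(f == 0.0)

    def test_phosphate_context_dependence(self):
        """DNA/DNA pairs use −0.6e², protein/DNA pairs −1.0e."""
        p = ElectrostaticParams(cutoff=None)
        q_intra = np.array([-0.6, -0.6])
        q_cross = np.array([-1.0, -1.0])
        dna_pair = ChargeTable(q_intra, q_cross, np.array([True, True]))
        mixed = ChargeTable(np.array([-0.6, 1.0]), np.array([-1.0, 1.0]),
                            np.array([True, False]))
        e_dna, _ = debye_huckel_energy(_pair_coords(10.0), dna_pair, p)
        e_mix, _ = debye_huckel_energy(_pair_coords(10.0), mixed, p)
        base = units.COULOMB / 78.0 * math.exp(-10.0 / p.debye_length) / 10.0
        assert e_dna == pytest.approx(0.36 * base, rel=1e-12)
        assert e_mix == pytest.approx(-1.0 * base, rel=1e-12)

    def test_debye_length_inverse_sqrt_ionic_strength(self):
        l1 = units.debye_length(0.3, 78.0, 300.0)
        l2 = units.debye_length(0.15, 78.0, 300.0)
        assert l2 / l1 == pytest.approx(math.sqrt(2.0), rel=1e-12)


class TestExcludedVolume:
    def test_zero_beyond_contact_distance(self):
        e, f = excluded_volume_energy(_pair_coords(5.1), [2.5, 2.5])
        assert e == 0.0 and np.all(f == 0.0)

    def test_shifted_to_zero_at_contact(self):
        e, _ = excluded_volume_energy(_pair_coords(5.0), [2.5, 2.5])
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        d, r = 5.0, 4.0
        e, _ = excluded_volume_energy(_pair_coords(r), [2.5, 2.5], eps_ev=0.6)
        assert e == pytest.approx(0.6 * ((d / r)**12 - 1.0), rel=1e-12)


class TestTotalEnergyForces:
    def test_forces_match_central_difference(self, duplex_system, duplex):
        rng = np.random.default_rng(11)
        pert = duplex.coords + rng.normal(scale=0.2, size=duplex.coords.shape)
        _, forces = total_energy_forces(pert, duplex_system)
        grad = numerical_gradient(pert, duplex_system)
        err = np.abs(forces + grad).max() / np.abs(forces).max()
        assert err < 1e-4

    def test_sigma_change_touches_only_its_label(self, small_toy):
        system = small_toy.system()
        e1, _ = total_energy_forces(small_toy.coords, system)
        e2, _ = total_energy_forces(small_toy.coords,
                                    system.set_sigma("cargo_tail", 2.0))
        assert e2.go_native["cargo_tail"] == pytest.approx(
            2.0 * e1.go_native["cargo_tail"], rel=1e-12)
        assert e2.go_native["ring_fold"] == pytest.approx(
            e1.go_native["ring_fold"], rel=1e-12)
        assert e2.electrostatic == pytest.approx(e1.electrostatic, rel=1e-12)

    def test_isolated_bead_all_zero(self):
        top = Topology()
        top.add_bead("A", "residue", "A", 0, 2.5, 1)
        top.chains = [ChainRecord("A", "protein", 0, 1)]
        s = compile_system(top, np.zeros((1, 3)))
        e, f = total_energy_forces(np.zeros((1, 3)), s)
        assert e.total == 0.0 and np.all(f == 0.0)

    def test_rigid_body_invariance(self, duplex_system, duplex):
        from scipy.spatial.transform import Rotation

        e1, _ = total_energy_forces(duplex.coords, duplex_system)
        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = duplex.coords @ R.T + np.array([7.0, -3.0, 11.0])
        e2, _ = total_energy_forces(moved, duplex_system)
        assert e2.total == pytest.approx(e1.total, abs=1e-8)

    def test_newtons_third_law(self, duplex_system, duplex):
        rng = np.random.default_rng(2)
        pert = duplex.coords + rng.normal(scale=0.3, size=duplex.coords.shape)
        _, f = total_energy_forces(pert, duplex_system)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8)
        torque = np.cross(pert, f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-7)

    def test_breakdown_total_is_component_sum(self, small_toy):
        e, _ = total_energy_forces(small_toy.coords, small_toy.system())
        parts = (e.bonded + sum(e.go_native.values()) + e.excluded_volume
                 + e.electrostatic + e.confinement + e.restraint)
        assert e.total == pytest.approx(parts, rel=1e-9)
        assert "term" in e.to_table()
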