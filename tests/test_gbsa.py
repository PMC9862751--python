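"""MM/GBSA energetics: Coulomb, Lennard-Jones, Born radii, GB, SASA."""

import numpy as np
import pytest

from poseval.gbsa import (
    COULOMB_CONST,
    GBParams,
    born_radii,
    coulomb_energy,
    delta_delta_g,
    delta_g_bind,
    free_energy,
    gb_polar_energy,
    lj_energy,
    sasa,
)

from conftest import make_structure


def _ion(charge=1.0, radius=1.5, xyz=(0, 0, 0)):
    return ("O", xyz, {"charge": charge, "gb_radius": radius})


class TestCoulomb:
    def test_closed_form_pair(self):
        s = make_structure([_ion(1.0), _ion(-1.0, xyz=(3.32, 0, 0))])
        assert coulomb_energy(s) == pytest.approx(-COULOMB_CONST / 3.32)
        assert coulomb_energy(s) == pytest.approx(-100.02, abs=0.01)

    def test_zero_charges(self):
        s = make_structure([("C", [0, 0, 0]), ("C", [3, 0, 0])], charge=0.0)
        assert coulomb_energy(s) == 0.0

    def test_four_atom_pair_sum_oracle(self, rng):
        xyz = rng.normal(scale=3.0, size=(4, 3))
        q = rng.uniform(-1, 1, 4)
        s = make_structure([("C", xyz[i], {"charge": q[i]}) for i in range(4)])
        expected = sum(
            COULOMB_CONST * q[i] * q[j] / np.linalg.norm(xyz[i] - xyz[j])
            for i in range(4) for j in range(i + 1, 4))
        assert coulomb_energy(s) == pytest.approx(expected, rel=1e-12)

    def test_missing_charge_lists_serials(self):
        s = make_structure([("C", [0, 0, 0]), ("C", [3, 0, 0])])
        s.atoms[1].charge = None
        with pytest.raises(ValueError, match="2"):
            coulomb_energy(s)


class TestLennardJones:
    def test_zero_crossing_and_minimum(self):
        sigma, eps = 3.4, 0.1
        at_sigma = make_structure(
            [("C", [0, 0, 0]), ("C", [sigma, 0, 0])],
            lj_sigma=sigma, lj_epsilon=eps)
        assert lj_energy(at_sigma) == pytest.approx(0.0, abs=1e-12)
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        at_min = make_structure(
            [("C", [0, 0, 0]), ("C", [rmin, 0, 0])],
            lj_sigma=sigma, lj_epsilon=eps)
        assert lj_energy(at_min) == pytest.approx(-eps, rel=1e-12)

    def test_three_atom_term_sum(self, rng):
        xyz = rng.normal(scale=4.0, size=(3, 3))
        sig = [3.0, 3.4, 3.8]
        eps = [0.05, 0.1, 0.2]
        s = make_structure([
            ("C", xyz[i], {"lj_sigma": sig[i], "lj_epsilon": eps[i]})
            for i in range(3)
        ])
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                sij = (sig[i] + sig[j]) / 2
                eij = np.sqrt(eps[i] * eps[j])
                r = np.linalg.norm(xyz[i] - xyz[j])
                expected += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
        assert lj_energy(s) == pytest.approx(expected, rel=1e-12)


class TestBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        s = make_structure([_ion(radius=1.5)])
        assert born_radii(s)[0] == pytest.approx(1.5, rel=1e-6)

    def test_radii_grow_as_atoms_approach(self):
        prev = None
        for d in np.linspace(8.0, 2.0, 10):
            s = make_structure([_ion(), _ion(xyz=(d, 0, 0))])
            r = born_radii(s)[0]
            if prev is not None:
                assert r >= prev - 1e-12
            prev = r

    def test_buried_atom_exceeds_surface_atom(self):
        """Center of a 20-atom shell is more descreened than the shell."""
        phi = np.pi * (1 + 5 ** 0.5) * (np.arange(20) + 0.5)
        cosang = 1 - 2 * (np.arange(20) + 0.5) / 20
        shell = 3.0 * np.column_stack([
            np.cos(phi) * np.sqrt(1 - cosang ** 2),
            np.sin(phi) * np.sqrt(1 - cosang ** 2), cosang])
        s = make_structure([_ion()] + [_ion(xyz=p) for p in shell])
        radii = born_radii(s)
        assert radii[0] > radii[1:].max()

    def test_nonpositive_radius_errors(self):
        s = make_structure([_ion(radius=1.0)])
        s.atoms[0].gb_radius = -0.5
        with pytest.raises(ValueError):
            born_radii(s)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        q, a = 1.0, 1.5
        s = make_structure([_ion(charge=q, radius=a)])
        e = gb_polar_energy(s, born_radii(s))
        born = -0.5 * COULOMB_CONST * (1 - 1 / 78.5) * q ** 2 / a
        assert e == pytest.approx(born, rel=1e-6)

    def test_zero_charges(self):
        s = make_structure([("C", [0, 0, 0]), ("C", [4, 0, 0])], charge=0.0)
        assert gb_polar_energy(s, born_radii(s)) == 0.0

    def test_two_ion_direct_formula(self):
        s = make_structure([_ion(1.0, 1.5), _ion(-1.0, 2.0, xyz=(4.0, 0, 0))])
        radii = born_radii(s)
        e = gb_polar_energy(s, radii)
        pref = -0.5 * COULOMB_CONST * (1 - 1 / 78.5)
        q = np.array([1.0, -1.0])
        expected = 0.0
        for i in range(2):
            for j in range(2):
                r2 = 16.0 if i != j else 0.0
                rr = radii[i] * radii[j]
                fgb = np.sqrt(r2 + rr * np.exp(-r2 / (4 * rr)))
                expected += pref * q[i] * q[j] / fgb
        assert e == pytest.approx(expected, rel=1e-12)


class TestSASA:
    def test_isolated_sphere_quadrature(self):
        s = make_structure([("C", [0, 0, 0], {"gb_radius": 1.6})])
        _, total = sasa(s, probe=1.4)
        assert total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.01)

    def test_coincident_spheres_count_once(self):
        s = make_structure([("C", [0, 0, 0], {"gb_radius": 1.6}),
                            ("C", [0, 0, 0], {"gb_radius": 1.6})])
        _, total = sasa(s)
        assert total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.01)

    def test_partial_overlap_matches_analytic_lens(self):
        r1 = r2 = 1.6 + 1.4
        d = 2.5
        s = make_structure([("C", [0, 0, 0], {"gb_radius": 1.6}),
                            ("C", [d, 0, 0], {"gb_radius": 1.6})])
        _, total = sasa(s)
        # analytic: each sphere loses a cap of height h = r - d/2
        h = r1 - d / 2
        expected = 2 * (4 * np.pi * r1 ** 2 - 2 * np.pi * r1 * h)
        assert total == pytest.approx(expected, rel=0.02)

    def test_never_exceeds_isolated_sum(self, rng):
        xyz = rng.uniform(0, 4, size=(5, 3))
        s = make_structure([("C", p, {"gb_radius": 1.7}) for p in xyz])
        per_atom, total = sasa(s)
        isolated = 5 * 4 * np.pi * (1.7 + 1.4) ** 2
        assert total <= isolated + 1e-9
        assert np.all(per_atom >= 0)


class TestDeltaG:
    def _dimer(self, separation, charges=(0.0, 0.0)):
        return make_structure(
            [("C", [0, 0, 0], {"charge": charges[0]}),
             ("C", [separation, 0, 0], {"charge": charges[1]})],
            roles=["receptor", "ligand"],
        )

    def test_vanishes_at_full_separation(self):
        for sep in (50.0, 100.0):
            dg, _ = delta_g_bind(self._dimer(sep))
            assert abs(dg) < 0.01

    def test_charged_pair_with_counterions_vanishes_at_distance(self):
        s = make_structure(
            [("N", [0, 0, 0], {"charge": 0.5}),
             ("O", [1.2, 0, 0], {"charge": -0.5}),
             ("N", [100.0, 0, 0], {"charge": 0.5}),
             ("O", [101.2, 0, 0], {"charge": -0.5})],
            roles=["receptor", "receptor", "ligand", "ligand"],
        )
        dg, _ = delta_g_bind(s)
        assert abs(dg) < 0.01

    def test_lj_dimer_minimum_binds(self):
        rmin = 2.0 ** (1.0 / 6.0) * 3.4
        dg, parts = delta_g_bind(self._dimer(rmin))
        assert dg < 0.0
        assert parts["delta"].e_lj == pytest.approx(-0.1, rel=1e-9)

    def test_overlapping_roles_error(self):
        s = self._dimer(4.0)
        s.role_mask = ["receptor", "other"]
        with pytest.raises(ValueError):
            delta_g_bind(s)

    def test_components_double_for_two_copies(self):
        base = make_structure(
            [("N", [0, 0, 0], {"charge": 0.4}),
             ("O", [3.0, 0, 0], {"charge": -0.4}),
             ("C", [1.5, 2.5, 0], {"charge": 0.0})])
        far = 1.0e6
        double = make_structure(
            [(a.element, a.xyz, {"charge": a.charge}) for a in base.atoms]
            + [(a.element, a.xyz + np.array([far, 0, 0]), {"charge": a.charge})
               for a in base.atoms])
        g1 = free_energy(base)
        g2 = free_energy(double)
        for comp in ("e_coulomb", "e_lj", "g_gb", "g_sa"):
            assert getattr(g2, comp) == pytest.approx(
                2 * getattr(g1, comp), abs=1e-8)


def test_delta_delta_g_published_pairs():
    assert delta_delta_g(-97.84, -118.15) == pytest.approx(20.31)
    assert delta_delta_g(-81.32, -91.97) == pytest.approx(10.65)
    assert delta_delta_g(-55.5, -55.5) == 0.0


def test_gb_params_validation():
    with pytest.raises(ValueError):
        GBParams(eps_in=2.0, eps_out=1.5)
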