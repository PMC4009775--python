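"""GBSA energy tests: analytic limits, numerical-integration oracles,
rigid-motion invariance and extensivity."""

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import make_atom
from confe.exceptions import EnergyError
from confe.gbsa import (
    GBParameters,
    SASAParameters,
    asa_energy,
    effective_born_radii,
    ensemble_average,
    gb_polar_energy,
    mm_energy,
    sasa,
    snapshot_energy,
)
from confe.structure import (
    AngleTerm,
    Atom,
    BondTerm,
    ConformationEnsemble,
    Topology,
    TorsionTerm,
)
from confe import synthetic

KE = 332.06
EPS_W = 78.5


def descreen_integral_oracle(rho_i, s_j, d):
    """Numerical Coulomb-field integral of the descreened neighbor volume:
    I = (1/4pi) int_{V_j, |x|>rho_i} |x|^-4 dV, reduced to 1-D quadrature
    over shells around atom i."""
    lo, hi = max(rho_i, d - s_j), d + s_j
    if hi <= lo:
        return 0.0

    def f(x):
        c = (x * x + d * d - s_j * s_j) / (2 * x * d)
        c = min(1.0, max(-1.0, c))
        return (1 - c) / 2 / (x * x)

    val, _ = quad(f, lo, hi, limit=200)
    return val


class TestBornRadii:
    def test_isolated_atom_reduced_radius(self):
        topo = Topology([make_atom(gb_radius=1.5)])
        r = effective_born_radii(topo, np.zeros((1, 3)))
        assert r[0] == pytest.approx(1.41, abs=1e-12)

    def test_distant_pair_no_descreening(self):
        topo = Topology([make_atom(gb_radius=1.5),
                         make_atom(gb_radius=1.7)])
        frame = np.array([[0, 0, 0], [1e4, 0, 0.0]])
        r = effective_born_radii(topo, frame)
        np.testing.assert_allclose(r, [1.41, 1.61], atol=1e-6)

    @pytest.mark.parametrize("d", [2.5, 3.0, 4.0, 6.0])
    def test_matches_numerical_integration(self, d):
        topo = Topology([make_atom(gb_radius=1.5, gb_screen=0.8),
                         make_atom(gb_radius=1.7, gb_screen=0.72)])
        frame = np.array([[0, 0, 0], [d, 0, 0.0]])
        r = effective_born_radii(topo, frame)
        rho = np.array([1.5, 1.7]) - 0.09
        s = np.array([0.8, 0.72]) * rho
        for i, j in ((0, 1), (1, 0)):
            inv = 1 / rho[i] - descreen_integral_oracle(rho[i], s[j], d)
            assert r[i] == pytest.approx(1 / inv, rel=0.02)

    def test_positive_even_when_clamped(self, rng):
        # a small atom crowded by many large screened neighbors drives the
        # inverse radius negative; it must be clamped, warned, and flagged
        atoms = [make_atom(gb_radius=1.2, gb_screen=0.9)] + \
                [make_atom(gb_radius=2.2, gb_screen=1.0) for _ in range(12)]
        topo = Topology(atoms)
        v = rng.normal(size=(12, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frame = np.vstack([[0.0, 0.0, 0.0], v * 1.6])
        with pytest.warns(UserWarning, match="clamped"):
            r, n_clamped = effective_born_radii(topo, frame, with_flags=True)
        assert np.all(r > 0)
        assert n_clamped > 0


class TestGBEnergy:
    def test_single_ion_born_formula(self):
        topo = Topology([make_atom(charge=1.0)])
        e = gb_polar_energy(topo, np.zeros((1, 3)), np.array([2.0]))
        born = -0.5 * KE * (1 - 1 / EPS_W) * 1.0 / 2.0
        assert e == pytest.approx(born, rel=1e-12)

    def test_zero_charges_zero_energy(self, rng):
        topo = Topology([make_atom(charge=0.0) for _ in range(5)])
        frame = rng.normal(size=(5, 3)) * 3
        radii = effective_born_radii(topo, frame)
        assert gb_polar_energy(topo, frame, radii) == pytest.approx(0.0)

    def test_two_distant_ions_screened_coulomb(self):
        topo = Topology([make_atom(charge=1.0), make_atom(charge=1.0)])
        frame = np.array([[0, 0, 0], [100.0, 0, 0]])
        e = gb_polar_energy(topo, frame, np.array([2.0, 2.0]))
        expect = (2 * (-0.5 * KE * (1 - 1 / EPS_W) / 2.0)
                  - KE * (1 - 1 / EPS_W) / 100.0)
        assert e == pytest.approx(expect, rel=1e-3)

    def test_contact_limit_formula_evaluation(self):
        # r -> 0 of two +1 charges approaches a q=2 ion with the
        # geometric-mean radius; check against direct formula evaluation
        topo = Topology([make_atom(charge=1.0), make_atom(charge=1.0)])
        radii = np.array([2.0, 3.0])
        r = 1e-6
        frame = np.array([[0, 0, 0], [r, 0, 0.0]])
        e = gb_polar_energy(topo, frame, radii)
        f = np.sqrt(r ** 2 + 6.0 * np.exp(-r ** 2 / 24.0))
        expect = -0.5 * KE * (1 - 1 / EPS_W) * (1 / 2 + 1 / 3 + 2 / f)
        assert e == pytest.approx(expect, rel=1e-9)

    def test_radii_length_mismatch(self):
        topo = Topology([make_atom(charge=1.0)])
        with pytest.raises(EnergyError):
            gb_polar_energy(topo, np.zeros((1, 3)), np.ones(2))


def two_sphere_sasa_analytic(r1, r2, d, probe):
    """Exposed area of two intersecting solvent-expanded spheres."""
    a, b = r1 + probe, r2 + probe
    if d >= a + b:
        return 4 * np.pi * (a * a + b * b)
    if d + min(a, b) <= max(a, b):
        big = max(a, b)
        return 4 * np.pi * big * big
    xa = (d * d + a * a - b * b) / (2 * d)
    xb = (d * d + b * b - a * a) / (2 * d)
    return 2 * np.pi * a * (a + xa) + 2 * np.pi * b * (b + xb)


class TestSasa:
    def test_single_sphere(self):
        topo = Topology([make_atom(rmin_half=1.9)])
        _, total = sasa(topo, np.zeros((1, 3)))
        exact = 4 * np.pi * 3.3 ** 2
        assert abs(total - exact) / exact < 0.01

    def test_distant_pair_additive(self):
        topo = Topology([make_atom(rmin_half=1.9), make_atom(rmin_half=1.5)])
        frame = np.array([[0, 0, 0], [100.0, 0, 0]])
        per_atom, total = sasa(topo, frame)
        exact = 4 * np.pi * (3.3 ** 2 + 2.9 ** 2)
        assert total == pytest.approx(exact, rel=0.01)

    def test_buried_atom_zero(self):
        topo = Topology([make_atom(rmin_half=0.5), make_atom(rmin_half=3.0)])
        frame = np.zeros((2, 3))
        per_atom, _ = sasa(topo, frame)
        assert per_atom[0] == 0.0

    @pytest.mark.parametrize("d", np.linspace(0.5, 6.5, 21))
    def test_two_sphere_overlap_analytic(self, d):
        topo = Topology([make_atom(rmin_half=1.9), make_atom(rmin_half=1.5)])
        frame = np.array([[0, 0, 0], [d, 0, 0.0]])
        _, total = sasa(topo, frame)
        exact = two_sphere_sasa_analytic(1.9, 1.5, d, 1.4)
        assert abs(total - exact) / exact < 0.01

    def test_asa_energy_linear(self):
        assert asa_energy(1000.0) == pytest.approx(5.0)
        assert asa_energy(500.0, SASAParameters(gamma=0.0)) == 0.0
        assert asa_energy(136.85, SASAParameters(gamma=0.0072)) == \
            pytest.approx(0.98532, abs=1e-5)


class TestMMEnergy:
    def test_bond_term(self):
        atoms = [make_atom(), make_atom()]
        topo = Topology(atoms, [BondTerm(0, 1, 300.0, 1.0)])
        frame = np.array([[0, 0, 0], [1.1, 0, 0.0]])
        dec = mm_energy(topo, frame)
        assert dec.bond == pytest.approx(3.0, abs=1e-9)

    def test_lj_minimum(self):
        atoms = [make_atom(charge=0.0, rmin_half=1.8, epsilon=0.2)
                 for _ in range(2)]
        topo = Topology(atoms)
        frame = np.array([[0, 0, 0], [3.6, 0, 0.0]])  # r = Rmin
        dec = mm_energy(topo, frame)
        assert dec.lj == pytest.approx(-0.2, abs=1e-12)

    def test_coulomb_value(self):
        atoms = [make_atom(charge=1.0, epsilon=0.0),
                 make_atom(charge=-1.0, epsilon=0.0)]
        topo = Topology(atoms)
        frame = np.array([[0, 0, 0], [3.3206, 0, 0.0]])
        dec = mm_energy(topo, frame)
        assert dec.coulomb == pytest.approx(-100.0, abs=1e-9)

    def test_angle_and_torsion_terms(self):
        atoms = [make_atom(charge=0.0, epsilon=0.0) for _ in range(4)]
        topo = Topology(
            atoms,
            bonds=[BondTerm(0, 1, 0.0, 1.5), BondTerm(1, 2, 0.0, 1.5),
                   BondTerm(2, 3, 0.0, 1.5)],
            angles=[AngleTerm(0, 1, 2, 40.0, 90.0)],
            torsions=[TorsionTerm(0, 1, 2, 3, 2.0, 1, 0.0)])
        # 90-degree angle bent to 120; torsion at 180 (cos = -1 -> 0)
        frame = np.array([
            [0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        dec = mm_energy(topo, frame)
        assert dec.angle == pytest.approx(0.0, abs=1e-9)
        assert dec.torsion == pytest.approx(0.0, abs=1e-12)
        frame2 = frame.copy()
        frame2[3] = [1, 1, 0]  # torsion 0 -> (V/2)(1+1) = 2
        assert mm_energy(topo, frame2).torsion == pytest.approx(2.0)

    def test_exclusions_and_14_scaling(self):
        topo = synthetic.make_toy_topology(4, atoms_per_residue=1)
        coords = synthetic.build_coordinates_from_torsions(
            topo, np.array([60.0]))
        dec = mm_energy(topo, coords, scale14_elec=0.0, scale14_lj=0.0)
        # with 1-4 zeroed there are no nonbonded pairs left in a 4-chain
        assert dec.lj == 0.0 and dec.coulomb == 0.0

    def test_missing_parameter_named(self):
        atoms = [make_atom(), make_atom()]
        topo = Topology(atoms, [BondTerm(0, 1)])  # no k/b0
        with pytest.raises(EnergyError, match="bond"):
            mm_energy(topo, np.zeros((2, 3)))


class TestSnapshotEnergy:
    def test_component_sum_identity(self, rng):
        topo = synthetic.make_toy_topology(4, atoms_per_residue=4)
        coords = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 10))
        dec = snapshot_energy(topo, coords)
        total = (dec.bond + dec.angle + dec.torsion + dec.lj
                 + dec.coulomb + dec.gb + dec.offset)
        assert dec.e_mm == pytest.approx(total, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        from test_geometry import rotation

        topo = synthetic.make_toy_topology(3, atoms_per_residue=4)
        coords = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 7))
        d1 = snapshot_energy(topo, coords)
        moved = coords @ rotation(rng.normal(size=3), 77.0).T + 5.0
        d2 = snapshot_energy(topo, moved)
        for attr in ("bond", "angle", "torsion", "lj", "coulomb", "gb"):
            assert getattr(d1, attr) == pytest.approx(
                getattr(d2, attr), abs=1e-6)
        assert d1.e_mm == pytest.approx(d2.e_mm, abs=1e-6)
        # surface areas from a fixed finite point grid are rotation
        # invariant only to quadrature resolution (~1% per-atom area)
        assert d1.e_asa == pytest.approx(d2.e_asa, abs=0.05)

    def test_extensivity_far_copy(self, rng):
        topo1 = synthetic.make_toy_topology(3, atoms_per_residue=4)
        coords = synthetic.build_coordinates_from_torsions(
            topo1, rng.uniform(-170, 170, 7))
        d1 = snapshot_energy(topo1, coords)
        # duplicate the chain far away
        from dataclasses import replace as dreplace

        atoms2 = [dreplace(a) for a in topo1.atoms] + \
                 [dreplace(a) for a in topo1.atoms]
        n = topo1.n_atoms
        bonds2 = ([BondTerm(b.i, b.j, b.k, b.b0) for b in topo1.bonds] +
                  [BondTerm(b.i + n, b.j + n, b.k, b.b0)
                   for b in topo1.bonds])
        angles2 = ([AngleTerm(a.i, a.j, a.k, a.force, a.theta0)
                    for a in topo1.angles] +
                   [AngleTerm(a.i + n, a.j + n, a.k + n, a.force, a.theta0)
                    for a in topo1.angles])
        tors2 = ([TorsionTerm(t.i, t.j, t.k, t.l, t.barrier, t.periodicity,
                              t.phase) for t in topo1.torsions] +
                 [TorsionTerm(t.i + n, t.j + n, t.k + n, t.l + n, t.barrier,
                              t.periodicity, t.phase)
                  for t in topo1.torsions])
        topo2 = Topology(atoms2, bonds2, angles2, tors2)
        coords2 = np.vstack([coords, coords + np.array([5e3, 0, 0])])
        d2 = snapshot_energy(topo2, coords2)
        for attr in ("bond", "angle", "torsion", "lj", "gb", "e_asa"):
            assert getattr(d2, attr) == pytest.approx(
                2 * getattr(d1, attr), abs=2e-5), attr

    def test_energy_offset_added(self, rng):
        topo = synthetic.make_toy_topology(5, atoms_per_residue=1,
                                           interacting=False)
        coords = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 2))
        e0 = snapshot_energy(topo, coords).e_mm
        topo.energy_offset = 12.5
        assert snapshot_energy(topo, coords).e_mm == pytest.approx(
            e0 + 12.5, abs=1e-9)


class TestEnsembleAverage:
    def test_identical_frames(self, rng):
        topo = synthetic.make_toy_topology(4, atoms_per_residue=1)
        c = synthetic.build_coordinates_from_torsions(topo,
                                                      np.array([45.0]))
        ens = ConformationEnsemble(topo, np.repeat(c[None], 3, axis=0))
        e_mm, e_asa, df = ensemble_average(ens)
        single = snapshot_energy(topo, c)
        assert e_mm == pytest.approx(single.e_mm, abs=1e-9)
        assert e_asa == pytest.approx(single.e_asa, abs=1e-9)
        assert len(df) == 3

    def test_mean_of_two(self, rng):
        topo = synthetic.make_toy_topology(6, atoms_per_residue=1)
        coords = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, (2, 3)))
        ens = ConformationEnsemble(topo, coords)
        e_mm, _, df = ensemble_average(ens)
        assert e_mm == pytest.approx(df["e_mm"].mean(), abs=1e-12)

    def test_stride_subsamples(self, rng):
        topo = synthetic.make_toy_topology(6, atoms_per_residue=1)
        coords = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, (10, 3)))
        ens = ConformationEnsemble(topo, coords)
        _, _, df = ensemble_average(ens, stride=5)
        assert list(df.index) == [0, 5]

    def test_empty_errors(self, chain_topology):
        with pytest.raises(Exception):
            ensemble_average(
                ConformationEnsemble(chain_topology,
                                     np.empty((0, 8, 3))))
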