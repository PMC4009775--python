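"""Superposition, RMSD, dihedral, torsion enumeration and contact tests.

Independent oracles: quaternion-method superposition, vector-triple-product
dihedral sign, brute-force all-pairs contact scan.
"""

import numpy as np
import pytest

from confe import synthetic
from confe.exceptions import GeometryError, SelectionError
from confe.geometry import (
    count_contacts,
    dihedral,
    dihedrals,
    enumerate_torsions,
    kabsch_superpose,
    region_rmsd_table,
    rmsd,
)
from confe.structure import AtomSelection, ConformationEnsemble, select


def quaternion_superpose(mobile, reference):
    """Independent quaternion-method (Horn) rotation + translation."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, -1]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rc - rot @ mc


def quaternion_superpose_rmsd(mobile, reference):
    """Independent quaternion-method (Horn) superposition oracle."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (m ** 2).sum() + (r ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / len(m))
    return np.sqrt(msd)


def rotation(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self, rng):
        x = rng.normal(size=(10, 3))
        y = x @ rotation([0, 0, 1], 37.0).T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(x, y)
        assert res.rmsd <= 1e-10
        np.testing.assert_allclose(res.apply(x), y, atol=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-9)

    def test_orthonormal_proper_rotation(self, rng):
        a, b = rng.normal(size=(2, 8, 3))
        r = kabsch_superpose(a, b).rotation
        np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(GeometryError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRmsd:
    def test_identical_zero(self, rng):
        x = rng.normal(size=(12, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_displacement(self, rng):
        # immobile fit subset; measured atoms displaced by 1 A
        fit_x = rng.normal(size=(6, 3))
        meas_x = rng.normal(size=(4, 3))
        a = np.vstack([fit_x, meas_x])
        b = np.vstack([fit_x, meas_x + np.array([0, 0, 1.0])])
        fit = AtomSelection(np.arange(6), "fit")
        meas = AtomSelection(np.arange(6, 10), "meas")
        assert rmsd(a, b, measure=meas, fit=fit) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_symmetry_and_bruteforce(self, rng):
        for _ in range(20):
            a = rng.normal(size=(9, 3))
            b = rng.normal(size=(9, 3))
            v = rmsd(a, b)
            assert v == pytest.approx(rmsd(b, a), abs=1e-9)
            assert v == pytest.approx(quaternion_superpose_rmsd(a, b),
                                      abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        r = rotation(rng.normal(size=3), 63.0)
        t = rng.normal(size=3)
        assert rmsd(a @ r.T + t, b @ r.T + t) == pytest.approx(
            rmsd(a, b), abs=1e-9)

    def test_empty_measure_errors(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(SelectionError):
            rmsd(x, x, measure=AtomSelection(np.array([], dtype=int), "e"))


class TestDihedral:
    def test_planar_cases(self):
        trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert dihedral(trans, (0, 1, 2, 3)) == pytest.approx(180.0)
        assert dihedral(cis, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_sign_convention_against_triple_product(self, rng):
        # sign(phi) must equal sign((b1 x b2) . b3) for the IUPAC convention
        for _ in range(50):
            p = rng.normal(size=(4, 3))
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            oracle = np.dot(np.cross(b1, b2), b3)
            ang = dihedral(p, (0, 1, 2, 3))
            if abs(ang) > 1e-6 and abs(abs(ang) - 180) > 1e-6:
                assert np.sign(ang) == np.sign(oracle)

    def test_constructed_plus_90(self):
        p = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1.0]])
        assert dihedral(p, (0, 1, 2, 3)) == pytest.approx(90.0)

    def test_rigid_invariance_and_mirror_flip(self, rng):
        p = rng.normal(size=(4, 3))
        ang = dihedral(p, (0, 1, 2, 3))
        r = rotation(rng.normal(size=3), 41.0)
        assert dihedral(p @ r.T + 2.0, (0, 1, 2, 3)) == pytest.approx(
            ang, abs=1e-9)
        mirror = p * np.array([1, 1, -1.0])
        assert dihedral(mirror, (0, 1, 2, 3)) == pytest.approx(-ang, abs=1e-9)

    def test_collinear_errors(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(GeometryError):
            dihedral(p, (0, 1, 2, 3))

    def test_range_half_open(self):
        trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        assert dihedral(trans, (0, 1, 2, 3)) == 180.0  # +180, never -180


class TestEnumerateTorsions:
    @pytest.mark.parametrize("n", [4, 5, 9, 20])
    def test_linear_chain_count(self, n):
        topo = synthetic.make_toy_topology(n, atoms_per_residue=1)
        ts = enumerate_torsions(topo)
        assert ts.nd == n - 3
        # brute force: non-terminal bonds
        adj = topo.bonded_neighbors()
        brute = sum(1 for b in topo.bonds
                    if len(adj[b.i]) > 1 and len(adj[b.j]) > 1)
        assert ts.nd == brute

    def test_terminal_bonds_excluded(self):
        topo = synthetic.make_toy_topology(4, atoms_per_residue=1)
        ts = enumerate_torsions(topo)
        central = {tuple(sorted((q[1], q[2]))) for q in ts.quads}
        assert (0, 1) not in central and (2, 3) not in central

    def test_flanking_atoms_lowest_index(self, peptide_topology):
        ts = enumerate_torsions(peptide_topology)
        adj = peptide_topology.bonded_neighbors()
        for a, b, c, d in ts.quads:
            assert a == min(x for x in adj[b] if x != c)
            assert d == min(x for x in adj[c] if x != b)

    def test_no_bonds_warns_empty(self, single_atom_topology):
        with pytest.warns(UserWarning):
            ts = enumerate_torsions(single_atom_topology)
        assert ts.nd == 0


class TestContacts:
    def _site(self, dists):
        from conftest import make_atom
        from confe.structure import Topology

        atoms = [make_atom("ZN", "Zn", "ZN", 1)]
        coords = [[0.0, 0.0, 0.0]]
        for k, d in enumerate(dists):
            atoms.append(make_atom("O", "O", "WAT", 2 + k))
            coords.append([d, 0.0, 0.0])
        topo = Topology(atoms)
        return topo, np.array(coords)[None]

    def test_single_frame_counts(self):
        topo, coords = self._site([2.1, 2.9, 3.4])
        ens = ConformationEnsemble(topo, coords)
        series = count_contacts(ens, select(topo, "element=Zn"),
                                select(topo, "water"), cutoff=3.0)
        assert series.counts.tolist() == [2]

    def test_average_is_mean(self):
        topo, c1 = self._site([2.0, 5.0])
        c2 = c1.copy()
        c2[0, 1, 0] = 4.0  # both waters out
        ens = ConformationEnsemble(topo, np.vstack([c1, c2]))
        series = count_contacts(ens, select(topo, "element=Zn"),
                                select(topo, "water"), cutoff=3.0)
        assert series.counts.tolist() == [1, 0]
        assert series.average == pytest.approx(0.5)

    def test_matches_bruteforce_scan(self, rng):
        from conftest import make_atom
        from confe.structure import Topology

        atoms = ([make_atom("ZN", "Zn", "ZN", 1)] +
                 [make_atom("O", "O", "WAT", 2 + k) for k in range(12)])
        topo = Topology(atoms)
        coords = rng.uniform(-4, 4, size=(100, 13, 3))
        ens = ConformationEnsemble(topo, coords)
        center = select(topo, "element=Zn")
        partners = select(topo, "water")
        series = count_contacts(ens, center, partners, cutoff=3.0)
        for f in range(100):
            brute = 0
            for j in partners.indices:
                if any(np.linalg.norm(coords[f, j] - coords[f, i]) <= 3.0
                       for i in center.indices):
                    brute += 1
            assert series.counts[f] == brute


class TestRegionRmsdTable:
    def test_identity_and_consistency(self, rng):
        topo = synthetic.make_toy_topology(20, atoms_per_residue=4)
        base = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 3 * 20 - 2))
        ens = ConformationEnsemble(topo, base[None])
        mc = select(topo, "main-chain")
        table = region_rmsd_table(ens, {"self": base}, [mc], fit=mc)
        assert table.loc[mc.label, "self"] == pytest.approx(0.0, abs=1e-9)
        # whole-main-chain region equals plain rmsd with fit = measure
        other = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 3 * 20 - 2))
        t2 = region_rmsd_table(ens, {"other": other}, [mc], fit=mc)
        assert t2.loc[mc.label, "other"] == pytest.approx(
            rmsd(base, other, measure=mc, fit=mc), abs=1e-9)

    def test_displaced_region_detected(self, rng):
        topo = synthetic.make_toy_topology(60, atoms_per_residue=4)
        base = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 3 * 60 - 2))
        moved = base.copy()
        region = select(topo, "resid 30-32")
        # displace a small region; the rest anchors the global fit
        moved[region.indices] += np.array([0, 0, 2.0])
        ens = ConformationEnsemble(topo, moved[None])
        mc = select(topo, "main-chain")
        other_region = select(topo, "resid 50-52")
        table = region_rmsd_table(ens, {"ref": base},
                                  [region, other_region], fit=mc)
        # the global fit absorbs a little of the local displacement, so the
        # value sits just below 2 A and far above the undisplaced region
        assert 1.7 < table.loc[region.label, "ref"] <= 2.0
        assert table.loc[other_region.label, "ref"] < 0.3
        # brute-force check: independent quaternion superposition on the
        # fit atoms, then plain RMS deviation over the region atoms
        rot, trans = quaternion_superpose(moved[mc.indices],
                                          base[mc.indices])
        fitted = moved @ rot.T + trans
        for sel in (region, other_region):
            d = fitted[sel.indices] - base[sel.indices]
            brute = np.sqrt(np.mean(np.sum(d * d, axis=1)))
            assert table.loc[sel.label, "ref"] == pytest.approx(brute,
                                                                abs=1e-9)

    def test_missing_region_errors(self, rng):
        topo = synthetic.make_toy_topology(5, atoms_per_residue=4)
        base = synthetic.build_coordinates_from_torsions(
            topo, rng.uniform(-170, 170, 13))
        ens = ConformationEnsemble(topo, base[None])
        mc = select(topo, "main-chain")
        empty = select(topo, "resid 100-120")
        with pytest.raises(SelectionError):
            region_rmsd_table(ens, {"ref": base}, [empty], fit=mc)
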