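"""Energy-engine contracts: dihedral geometry, the AMBER functional form
against a brute-force pairwise oracle, exact gradients, and the restrained
minimizer."""

import numpy as np
import pytest

from torsionsmith.ffcore import (COULOMB_CONSTANT, AtomRecord, BondTerm,
                                 Conformation, DegenerateGeometryError,
                                 DihedralRestraint, FourierComponent,
                                 MoleculeTopology, Pair14, SingularityError,
                                 TorsionTerm, dihedral_angle, gradient,
                                 restrained_minimize, set_dihedral,
                                 total_energy, wrap_angle)
from torsionsmith.synthetic import build_topology, zigzag_chain


def _random_topology(seed, n=6):
    rng = np.random.default_rng(seed)
    charges = rng.normal(0.0, 0.1, n)
    charges -= charges.mean()
    return build_topology(["C"] * n, [(i, i + 1) for i in range(n - 1)],
                          charges)


def _random_conf(seed, n=6):
    rng = np.random.default_rng(seed + 1000)
    # keep backbone dihedrals away from cis so the chain cannot self-clash
    dihedral = float(rng.choice([-1, 1]) * rng.uniform(75.0, 180.0))
    base = zigzag_chain(n, dihedral=dihedral)
    return Conformation(base + rng.normal(0.0, 0.05, (n, 3)))


def _oracle_energy(top, conf):
    """Naive per-term / per-atom-pair double-loop evaluation of the force
    field, independent of the vectorized engine."""
    xyz = conf.coordinates
    e = 0.0
    for b in top.bonds:
        e += b.k_b * (np.linalg.norm(xyz[b.i] - xyz[b.j]) - b.l0) ** 2
    for a in top.angles:
        u, v = xyz[a.i] - xyz[a.j], xyz[a.k] - xyz[a.j]
        th = np.arccos(np.clip(np.dot(u, v) /
                               (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        e += a.k_a * (th - np.deg2rad(a.theta0)) ** 2
    for t in top.torsions:
        w = np.deg2rad(dihedral_angle(conf, t.quad))
        for c in t.components:
            e += 0.5 * c.v * (1 + np.cos(c.n * w - np.deg2rad(c.gamma)))
    p14 = {(min(p.i, p.j), max(p.i, p.j)): p for p in top.pairs14}
    n = top.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in top.excluded_pairs:
                continue
            ai, aj = top.atoms[i], top.atoms[j]
            r = np.linalg.norm(xyz[i] - xyz[j])
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            lj = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            coul = COULOMB_CONSTANT * ai.charge * aj.charge / r
            if (i, j) in p14:
                p = p14[(i, j)]
                e += lj / p.scnb + coul / p.scee
            else:
                e += lj + coul
    return e


class TestDihedralAngle:
    def test_planar_cis_is_zero(self):
        xyz = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert dihedral_angle(Conformation(xyz), (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        xyz = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        assert dihedral_angle(Conformation(xyz), (0, 1, 2, 3)) == pytest.approx(180.0)

    @pytest.mark.parametrize("target", [60.0, -60.0, 180.0])
    def test_staggered_matches_plane_normal_oracle(self, target):
        conf = Conformation(zigzag_chain(4, dihedral=target))
        got = dihedral_angle(conf, (0, 1, 2, 3))
        assert got == pytest.approx(target, abs=1e-9)
        # independent oracle: signed angle between the two plane normals
        x = conf.coordinates
        n1 = np.cross(x[1] - x[0], x[2] - x[1])
        n2 = np.cross(x[2] - x[1], x[3] - x[2])
        cosphi = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        sign = -np.sign(np.dot(np.cross(n1, n2), x[2] - x[1]))
        oracle = np.rad2deg(np.arccos(np.clip(cosphi, -1, 1))) * (sign or 1.0)
        assert abs(wrap_angle(got - oracle)) < 1e-7

    def test_reversal_invariance(self, rng):
        conf = _random_conf(5)
        a = dihedral_angle(conf, (0, 1, 2, 3))
        b = dihedral_angle(conf, (3, 2, 1, 0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_collinear_raises(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            dihedral_angle(Conformation(xyz), (0, 1, 2, 3))


class TestTotalEnergy:
    def test_bond_at_equilibrium_is_zero(self):
        top = MoleculeTopology(
            [AtomRecord(0, "C", "c3", 0, 12, 0, 0),
             AtomRecord(1, "C", "c3", 0, 12, 0, 0)],
            [BondTerm(0, 1, 300.0, 1.5)], [], [], {(0, 1)}, [])
        conf = Conformation(np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        assert total_energy(top, conf).bond == pytest.approx(0.0, abs=1e-14)

    def test_lj_pair_minimum_is_minus_epsilon(self):
        top = MoleculeTopology(
            [AtomRecord(0, "C", "c3", 0, 12, 1.9, 0.2),
             AtomRecord(1, "C", "c3", 0, 12, 1.9, 0.2)], [], [], [], set(), [])
        conf = Conformation(np.array([[0, 0, 0], [3.8, 0, 0.0]]))
        assert total_energy(top, conf).lj == pytest.approx(-0.2, abs=1e-12)

    def test_single_torsion_endpoints(self):
        top = MoleculeTopology(
            [AtomRecord(i, "C", "c3", 0, 12, 0, 0) for i in range(4)], [], [],
            [TorsionTerm((0, 1, 2, 3), (FourierComponent(2.0, 1, 0.0),))],
            {(i, j) for i in range(4) for j in range(i + 1, 4)}, [])
        at0 = Conformation(zigzag_chain(4, dihedral=0.0))
        at180 = Conformation(zigzag_chain(4, dihedral=180.0))
        assert total_energy(top, at0).torsion == pytest.approx(2.0)
        assert total_energy(top, at180).torsion == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        top = _random_topology(seed)
        conf = _random_conf(seed)
        assert total_energy(top, conf).total == pytest.approx(
            _oracle_energy(top, conf), abs=1e-10)

    def test_coincident_atoms_raise(self):
        top = _random_topology(0)
        xyz = zigzag_chain(6)
        xyz[5] = xyz[0]
        with pytest.raises(SingularityError):
            total_energy(top, Conformation(xyz))


class TestGradient:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_finite_differences(self, seed):
        top = _random_topology(seed)
        conf = _random_conf(seed)
        g = gradient(top, conf)
        h = 1e-5
        xyz = conf.coordinates
        fd = np.zeros_like(xyz)
        for i in range(xyz.shape[0]):
            for d in range(3):
                xp, xm = xyz.copy(), xyz.copy()
                xp[i, d] += h
                xm[i, d] -= h
                fd[i, d] = (total_energy(top, Conformation(xp)).total -
                            total_energy(top, Conformation(xm)).total) / (2 * h)
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_net_force_is_zero(self):
        g = gradient(_random_topology(3), _random_conf(3))
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-9)

    def test_stationary_at_minimum(self, butane):
        res = restrained_minimize(butane.topology, butane.conformations[0],
                                  convergence=1e-7)
        g = gradient(butane.topology, res.conformation)
        assert np.max(np.abs(g)) <= 1e-6

    def test_translation_invariance(self):
        top, conf = _random_topology(7), _random_conf(7)
        shifted = Conformation(conf.coordinates + np.array([3.0, -2.0, 11.0]))
        assert total_energy(top, shifted).total == pytest.approx(
            total_energy(top, conf).total, abs=1e-9)
        assert np.allclose(gradient(top, shifted), gradient(top, conf),
                           atol=1e-9)


class TestInvariances:
    def test_rotation_invariance(self):
        top, conf = _random_topology(11), _random_conf(11)
        th = 0.73
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = Conformation(conf.coordinates @ rot.T)
        assert abs(total_energy(top, rotated).total -
                   total_energy(top, conf).total) <= 1e-9

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_torsion_periodicity(self, n):
        term = TorsionTerm((0, 1, 2, 3), (FourierComponent(2.5, n, 40.0),))
        w = np.linspace(-180, 180, 37)
        for k in range(1, n + 1):
            assert np.allclose(term.energy_at(w),
                               term.energy_at(w + 360.0 / n * k), atol=1e-10)

    def test_doubling_scee_halves_14_coulomb(self):
        atoms = [AtomRecord(i, "C", "c3", 0.2 if i in (0, 3) else 0.0, 12,
                            0.0, 0.0) for i in range(4)]
        excl = {(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)}
        conf = Conformation(zigzag_chain(4, dihedral=60.0))
        e1 = total_energy(MoleculeTopology(atoms, [], [], [], excl,
                                           [Pair14(0, 3, 1.2, 2.0)]), conf)
        e2 = total_energy(MoleculeTopology(atoms, [], [], [], excl,
                                           [Pair14(0, 3, 2.4, 2.0)]), conf)
        assert e2.coulomb14 == pytest.approx(e1.coulomb14 / 2.0, rel=1e-12)


class TestRestrainedMinimize:
    def test_fixed_point(self, butane):
        top = butane.topology
        first = restrained_minimize(top, butane.conformations[0])
        target = dihedral_angle(first.conformation, (1, 2, 3, 4))
        restr = DihedralRestraint((1, 2, 3, 4), target)
        again = restrained_minimize(top, first.conformation, [restr])
        rmsd = np.sqrt(np.mean((again.conformation.coordinates -
                                first.conformation.coordinates) ** 2))
        assert rmsd < 1e-4

    def test_drives_dihedral_to_target(self, butane):
        top = butane.topology
        start = butane.conformations[1]          # gauche(+) start
        res = restrained_minimize(top, start,
                                  [DihedralRestraint((1, 2, 3, 4), 0.0)])
        assert res.converged
        final = dihedral_angle(res.conformation, (1, 2, 3, 4))
        assert abs(wrap_angle(final - 0.0)) <= 0.5 + 2.0

    def test_zero_force_constant_equals_unrestrained(self, butane):
        top = butane.topology
        null = DihedralRestraint((1, 2, 3, 4), 0.0, k_restraint=0.0)
        a = restrained_minimize(top, butane.conformations[0], [null])
        b = restrained_minimize(top, butane.conformations[0], [])
        assert np.allclose(a.conformation.coordinates,
                           b.conformation.coordinates, atol=1e-8)

    def test_set_dihedral_round_trip(self, butane):
        conf = set_dihedral(butane.topology, butane.conformations[0],
                            (1, 2, 3, 4), -72.5)
        assert dihedral_angle(conf, (1, 2, 3, 4)) == pytest.approx(-72.5,
                                                                   abs=1e-8)
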