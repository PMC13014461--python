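"""Fitting machinery: exact objective gradients, equivalence with the
closed-form linear least-squares solution, parameter recovery for every
basis periodicity, mode contracts, and Boltzmann charge averaging."""

import numpy as np
import pytest

from torsionsmith.conformers import CentroidSet, boltzmann_weights
from torsionsmith.ffcore import (Conformation, FourierComponent, TorsionTerm)
from torsionsmith.io_formats import type_quadruple
from torsionsmith.scan_engine import InternalMMBackend, make_grid, run_scan
from torsionsmith.synthetic import zigzag_chain
from torsionsmith.torsion_fit import (FitSpec, TorsionObjective,
                                      boltzmann_average_charges, fit_torsion,
                                      fit_all, profile_rmse)

QUAD = (1, 2, 3, 4)
GRID = make_grid(20.0)


def _typewide_replace(top, quad, term):
    tq = type_quadruple(top, quad)
    out = top
    for t in top.torsions:
        if not t.is_improper and type_quadruple(top, t.quad) == tq:
            out = out.replace_torsion(
                t.quad, TorsionTerm(t.quad, term.components, term.scee,
                                    term.scnb))
    return out


@pytest.fixture(scope="module")
def butane_scan(fixtures):
    """Reference MM scan of the unmodified topology (geometries reusable)."""
    import warnings
    fx = fixtures["butane_like"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = run_scan(InternalMMBackend(), fx.topology,
                        fx.conformations[0], QUAD, GRID)
    return fx, prof


class TestObjective:
    def test_zero_at_reproducing_parameters(self, butane_scan):
        fx, prof = butane_scan
        obj = TorsionObjective(fx.topology, QUAD, prof.geometries,
                               prof.energies, FitSpec(mode="full"))
        x = obj.initial_vector()
        L, g = obj.value_and_grad(x)
        assert L == pytest.approx(0.0, abs=1e-12)
        assert np.max(np.abs(g)) == pytest.approx(0.0, abs=1e-6)

    def test_gradient_matches_finite_differences(self, butane_scan):
        fx, prof = butane_scan
        ref = prof.energies + np.sin(np.arange(18))   # arbitrary target
        obj = TorsionObjective(fx.topology, QUAD, prof.geometries, ref,
                               FitSpec(mode="full"))
        x = obj.initial_vector() + 0.1
        _, g = obj.value_and_grad(x)
        fd = np.zeros_like(x)
        h = 1e-6
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd[i] = (obj.value_and_grad(xp)[0] -
                     obj.value_and_grad(xm)[0]) / (2 * h)
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_constant_reference_shift_leaves_objective_unchanged(
            self, butane_scan):
        fx, prof = butane_scan
        spec = FitSpec(mode="full")
        ref = prof.energies + np.sin(np.arange(18))
        a = TorsionObjective(fx.topology, QUAD, prof.geometries, ref, spec)
        b = TorsionObjective(fx.topology, QUAD, prof.geometries, ref + 17.3,
                             spec)
        x = a.initial_vector() + 0.05
        assert a.value_and_grad(x)[0] == pytest.approx(
            b.value_and_grad(x)[0], rel=1e-12)


class TestLinearOracle:
    def test_fixed_phase_fit_equals_normal_equations(self, butane_scan):
        """With phases frozen and geometries fixed the loss is quadratic in
        {V_n}; the bounded optimizer must land on the closed-form solution."""
        fx, prof = butane_scan
        truth = TorsionTerm(QUAD, (FourierComponent(2.7, 3, 0.0),
                                   FourierComponent(0.9, 2, 180.0)))
        truth_top = _typewide_replace(fx.topology, QUAD, truth)
        ref = np.array([__import__("torsionsmith.ffcore", fromlist=["x"])
                        .total_energy(truth_top, g).total
                        for g in prof.geometries])
        spec = FitSpec(mode="torsion_only", basis=(1, 2, 3, 4))
        res = fit_torsion(fx.topology, QUAD, _as_profile(ref, prof), spec)
        # independent closed form: design matrix of the mean-centered basis
        obj = TorsionObjective(fx.topology, QUAD, prof.geometries, ref, spec)
        cols = []
        for bi, n in enumerate(spec.basis):
            g0 = np.deg2rad({1: 0.0, 2: 180.0, 3: 0.0, 4: 180.0}[n])
            cols.append(np.sum(0.5 * (1 + np.cos(n * obj.omega - g0)), axis=0))
        A = np.column_stack(cols)
        y = ref - obj.base_energy - obj.c14 / obj.scee0 - obj.l14 / obj.scnb0
        A_c = A - A.mean(axis=0)
        y_c = y - y.mean()
        v_closed, *_ = np.linalg.lstsq(A_c, y_c, rcond=None)
        fitted = {c.n: c.v for c in res.term.components}
        for bi, n in enumerate(spec.basis):
            assert fitted.get(n, 0.0) == pytest.approx(
                max(v_closed[bi], 0.0), abs=1e-6)


def _as_profile(ref_energies, template):
    from torsionsmith.scan_engine import ScanProfile
    e = np.asarray(ref_energies, float)
    return ScanProfile(template.key, template.grid, e - e.min(),
                       list(template.geometries), "test",
                       template.origin_centroid)


class TestRecovery:
    @pytest.mark.parametrize("n,v,gamma", [(1, 2.5, 30.0), (2, 3.0, 180.0),
                                           (3, 1.8, 0.0), (4, 1.2, 90.0)])
    def test_noiseless_single_component_recovery(self, butane_scan, n, v,
                                                 gamma):
        fx, prof = butane_scan
        truth = TorsionTerm(QUAD, (FourierComponent(v, n, gamma),))
        truth_top = _typewide_replace(fx.topology, QUAD, truth)
        from torsionsmith.ffcore import total_energy
        ref = np.array([total_energy(truth_top, g).total
                        for g in prof.geometries])
        res = fit_torsion(fx.topology, QUAD, _as_profile(ref, prof),
                          FitSpec(mode="full"))
        comp = {c.n: c for c in res.term.components}
        assert n in comp
        assert comp[n].v == pytest.approx(v, abs=1e-3)
        dg = abs(((comp[n].gamma - gamma + 180.0) % 360.0) - 180.0)
        assert dg <= 1.0
        assert res.final_rmse < 1e-3

    def test_reference_equal_to_initial_profile_is_noop(self, butane_scan):
        fx, prof = butane_scan
        res = fit_torsion(fx.topology, QUAD, prof, FitSpec(mode="full"))
        assert res.outer_cycles == 1
        assert res.final_rmse < 1e-6
        init = next(t for t in fx.topology.torsions if t.quad == QUAD)
        fitted = {c.n: c.v for c in res.term.components}
        for c in init.components:
            assert fitted.get(c.n, 0.0) == pytest.approx(c.v, abs=1e-4)

    def test_noisy_recovery_distribution(self, butane_scan):
        """sigma = 0.1 kcal/mol Gaussian noise: the recovered V_2 stays
        unbiased across 20 seeded replicates (mean error within 3 sigma of
        the 18-point standard error)."""
        fx, prof = butane_scan
        truth = TorsionTerm(QUAD, (FourierComponent(3.0, 2, 180.0),))
        truth_top = _typewide_replace(fx.topology, QUAD, truth)
        from torsionsmith.ffcore import total_energy
        clean = np.array([total_energy(truth_top, g).total
                          for g in prof.geometries])
        sigma = 0.1
        errors = []
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0.0, sigma, 18)
            res = fit_torsion(fx.topology, QUAD,
                              _as_profile(clean + noise, prof),
                              FitSpec(mode="torsion_only", basis=(2,)))
            v2 = {c.n: c.v for c in res.term.components}.get(2, 0.0)
            errors.append(v2 - 3.0)
        assert abs(np.mean(errors)) <= 3 * sigma / np.sqrt(18)


class TestModes:
    def test_torsion_only_freezes_phase_and_scaling(self, butane_scan):
        fx, prof = butane_scan
        ref = prof.energies + 0.3 * np.cos(np.deg2rad(
            2 * np.array(GRID.angles)))
        res = fit_torsion(fx.topology, QUAD, _as_profile(ref, prof),
                          FitSpec(mode="torsion_only"))
        init = next(t for t in fx.topology.torsions if t.quad == QUAD)
        assert res.term.scee == init.scee
        assert res.term.scnb == init.scnb
        init_gamma = {c.n: c.gamma for c in init.components}
        for c in res.term.components:
            expected = init_gamma.get(c.n, {1: 0.0, 2: 180.0, 3: 0.0,
                                            4: 180.0}[c.n])
            assert c.gamma == expected   # bitwise: never touched

    def test_fit_never_degrades_objective(self, butane_scan):
        fx, prof = butane_scan
        rng = np.random.default_rng(5)
        ref = prof.energies + rng.normal(0, 0.5, 18)
        res = fit_torsion(fx.topology, QUAD, _as_profile(ref, prof),
                          FitSpec(mode="full"))
        assert res.final_rmse <= res.initial_rmse + 1e-12


class TestFitAll:
    def test_order_invariance_and_independence(self, fixtures):
        import warnings
        fx = fixtures["two_region"]
        from torsionsmith.torsion_select import (enumerate_candidates, prune,
                                                 wrapped_dispersion)
        cands = enumerate_candidates(fx.topology)
        disp = {c.canonical: wrapped_dispersion(fx.conformations, c)
                for c in cands}
        sig = [t for t in prune(fx.topology, cands, disp)
               if t.canonical in ((1, 2, 3, 4), (11, 12, 13, 14))]
        assert len(sig) == 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mm = InternalMMBackend()
            refs = {}
            for t in sig:
                truth = TorsionTerm(t.quad, (FourierComponent(2.0, 3, 0.0),))
                ttop = _typewide_replace(fx.topology, t.quad, truth)
                refs[t.canonical] = run_scan(mm, ttop, fx.conformations[0],
                                             t.quad, GRID)
            spec = FitSpec(mode="torsion_only", basis=(3,))
            fwd = fit_all(fx.topology, sig, refs, spec)
            rev = fit_all(fx.topology, list(reversed(sig)), refs, spec)
            solo = fit_torsion(fx.topology, sig[0].quad,
                               refs[sig[0].canonical], spec)
        for k in fwd:
            assert fwd[k].term == rev[k].term
        assert fwd[sig[0].canonical].term == solo.term

    def test_empty_significant_list(self, butane):
        assert fit_all(butane.topology, [], {}) == {}


class TestChargeAveraging:
    def _centroids(self, des):
        conf = Conformation(zigzag_chain(4))
        des = np.array(des, float)
        return CentroidSet([conf] * len(des), des,
                           member_indices=list(range(len(des))))

    def test_identical_sets_unchanged(self):
        q = np.array([0.1, -0.2, 0.05, 0.05])
        out = boltzmann_average_charges([q, q, q], self._centroids([0, 1, 2]))
        assert np.allclose(out, q)

    def test_equal_weights_arithmetic_mean(self):
        cs = self._centroids([0.0, 0.0])
        out = boltzmann_average_charges([np.array([0.1, -0.1]),
                                         np.array([0.3, -0.3])], cs)
        assert out[0] == pytest.approx(0.2)

    def test_weighted_case_matches_direct_summation(self):
        des = [0.0, 0.7, 1.9]
        cs = self._centroids(des)
        rng = np.random.default_rng(2)
        qs = [rng.normal(0, 0.2, 4) for _ in range(3)]
        for q in qs:
            q -= q.mean()   # equal totals
        out = boltzmann_average_charges(qs, cs)
        w = boltzmann_weights(des)
        oracle = sum(wk * qk for wk, qk in zip(w, qs))
        assert np.allclose(out, oracle, atol=1e-12)
        assert out.sum() == pytest.approx(0.0, abs=1e-6)

    def test_total_charge_mismatch_raises(self):
        cs = self._centroids([0.0, 1.0])
        with pytest.raises(ValueError, match="total charge"):
            boltzmann_average_charges([np.array([0.0, 0.0]),
                                       np.array([0.1, 0.0])], cs)
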