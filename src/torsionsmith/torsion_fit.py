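"""Least-squares refitting of Fourier torsion terms against reference profiles.

The objective is the sum of squared differences between the MM and reference
torsional energy profiles, both mean-centered (which eliminates the arbitrary
energy offset analytically and keeps the loss smooth):

    L(p) = sum_g ( [E_MM(theta_g; p) - <E_MM>] - [E_ref(theta_g) - <E_ref>] )^2

Fitting is type-based, matching AMBER semantics: the fitted parameters apply
to every proper torsion sharing the target's atom-type quadruple, and (in
full mode) to the 1-4 pairs those torsions own.  At frozen scan geometries
the MM profile is an explicit function of the parameters

    E_MM(theta_g; p) = E_base,g + sum_q sum_n V_n/2 [1 + cos(n w_qg - g_n)]
                       + C_g / scee + L_g / scnb

so the exact gradient is available in closed form.  The inner minimization is
bounded quasi-Newton (L-BFGS-B); an outer loop re-runs the MM scan with the
updated parameters to refresh the geometries, stopping when the profile RMSD
changes by less than the convergence threshold (default 0.001 kcal/mol).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .conformers import CentroidSet
from .ffcore import (Conformation, FourierComponent, MoleculeTopology,
                     TorsionTerm, dihedral_angle, total_energy)
from .io_formats import type_quadruple
from .scan_engine import ScanGrid, ScanProfile, run_scan

log = logging.getLogger(__name__)

__all__ = [
    "FitSpec", "FitResult", "TorsionObjective", "fit_torsion", "fit_all",
    "boltzmann_average_charges", "profile_rmse",
]

_DEFAULT_GAMMA = {1: 0.0, 2: 180.0, 3: 0.0, 4: 180.0, 5: 0.0, 6: 180.0}


@dataclass(frozen=True)
class FitSpec:
    mode: str = "full"                     # "full" | "torsion_only"
    basis: tuple[int, ...] = (1, 2, 3, 4)  # fitted periodicities
    v_bounds: tuple[float, float] = (0.0, 20.0)
    scee_bounds: tuple[float, float] = (0.5, 3.0)
    scnb_bounds: tuple[float, float] = (0.5, 4.0)
    convergence: float = 0.001             # outer profile-RMSD change, kcal/mol
    max_outer: int = 10
    prune_floor: float = 0.005             # kcal/mol; smaller V_n are dropped
    step_size: float = 0.05                # initial step scale hint (config only)
    retry_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("full", "torsion_only"):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if len(set(self.basis)) != len(self.basis):
            raise ValueError("duplicate basis periodicities")


@dataclass
class FitResult:
    key: tuple[int, int, int, int]
    term: TorsionTerm                  # fitted torsion (post-pruning)
    initial_rmse: float
    final_rmse: float
    outer_cycles: int
    inner_iterations: int
    converged: bool
    trace: list[float] = field(default_factory=list)   # per-cycle RMSE


def profile_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMS difference of two mean-centered profiles."""
    ra = np.asarray(a, float) - np.mean(a)
    rb = np.asarray(b, float) - np.mean(b)
    return float(np.sqrt(np.mean((ra - rb) ** 2)))


class TorsionObjective:
    """Mean-centered SSE between an MM profile and a reference, as an explicit
    differentiable function of one torsion type's parameters at frozen scan
    geometries."""

    def __init__(self, topology: MoleculeTopology, quad, geometries,
                 reference: np.ndarray, spec: FitSpec):
        self.spec = spec
        self.quad = tuple(quad)
        self.type_quad = type_quadruple(topology, quad)
        self.reference = np.asarray(reference, float)
        self.sibling_quads = [t.quad for t in topology.torsions
                              if not t.is_improper
                              and type_quadruple(topology, t.quad) == self.type_quad]
        target = next(t for t in topology.torsions
                      if not t.is_improper and t.quad in (self.quad,
                                                          self.quad[::-1]))
        self.initial_term = target
        self.scee0, self.scnb0 = target.scee, target.scnb

        # strip the fitted type's torsion terms and owned 1-4 scaling from a
        # base topology so their contribution can be re-added analytically
        own_pairs = {(min(q[0], q[3]), max(q[0], q[3]))
                     for q in self.sibling_quads}
        base = topology
        for q in self.sibling_quads:
            base = base.replace_torsion(
                q, TorsionTerm(q, (FourierComponent(0.0, 1, 0.0),), 1.0, 1.0))
        arr_pairs = [(p.i, p.j, p.scee, p.scnb) for p in base.pairs14]
        self.base_energy = np.empty(len(geometries))
        self.c14 = np.zeros(len(geometries))     # unscaled 1-4 Coulomb of owned pairs
        self.l14 = np.zeros(len(geometries))     # unscaled 1-4 LJ of owned pairs
        self.omega = np.empty((len(self.sibling_quads), len(geometries)))
        from .ffcore import COULOMB_CONSTANT
        for g, conf in enumerate(geometries):
            if conf is None:
                raise ValueError("objective needs a geometry at every grid point")
            br = total_energy(base, conf)
            xyz = conf.coordinates
            c = l = 0.0
            for (i, j, pscee, pscnb) in arr_pairs:
                if (min(i, j), max(i, j)) not in own_pairs:
                    continue
                ai, aj = topology.atoms[i], topology.atoms[j]
                r = float(np.linalg.norm(xyz[i] - xyz[j]))
                cc = COULOMB_CONSTANT * ai.charge * aj.charge / r
                rmin = ai.lj_rmin_half + aj.lj_rmin_half
                eps = float(np.sqrt(ai.lj_epsilon * aj.lj_epsilon))
                x6 = (rmin / r) ** 6
                lj = eps * (x6 * x6 - 2.0 * x6)
                # remove the currently scaled contribution, keep raw sums
                c += cc
                l += lj
                br.coulomb14 -= cc / pscee
                br.lj14 -= lj / pscnb
            self.base_energy[g] = br.total
            self.c14[g] = c
            self.l14[g] = l
            for qi, q in enumerate(self.sibling_quads):
                self.omega[qi, g] = np.deg2rad(dihedral_angle(conf, q))

    # --- parameter vector layout ------------------------------------------
    def initial_vector(self) -> np.ndarray:
        v0 = {c.n: c.v for c in self.initial_term.components}
        g0 = {c.n: c.gamma for c in self.initial_term.components}
        vs = [v0.get(n, 0.0) for n in self.spec.basis]
        if self.spec.mode == "torsion_only":
            return np.array(vs)
        gs = [g0.get(n, _DEFAULT_GAMMA[n]) % 360.0 for n in self.spec.basis]
        return np.array(vs + gs + [self.scee0, self.scnb0])

    def bounds(self):
        nb = len(self.spec.basis)
        b = [self.spec.v_bounds] * nb
        if self.spec.mode == "full":
            b += [(0.0, 360.0 - 1e-9)] * nb
            b += [self.spec.scee_bounds, self.spec.scnb_bounds]
        return b

    def unpack(self, x):
        nb = len(self.spec.basis)
        vs = x[:nb]
        if self.spec.mode == "torsion_only":
            g0 = {c.n: c.gamma for c in self.initial_term.components}
            gs = np.array([g0.get(n, _DEFAULT_GAMMA[n]) for n in self.spec.basis])
            return vs, gs, self.scee0, self.scnb0
        return vs, x[nb:2 * nb], float(x[2 * nb]), float(x[2 * nb + 1])

    def term_from_vector(self, x) -> TorsionTerm:
        vs, gs, scee, scnb = self.unpack(x)
        comps = tuple(FourierComponent(float(v), n, float(g) % 360.0)
                      for v, n, g in zip(vs, self.spec.basis, gs))
        return TorsionTerm(self.quad, comps, scee, scnb)

    # --- model and objective ----------------------------------------------
    def mm_profile(self, x) -> np.ndarray:
        vs, gs, scee, scnb = self.unpack(x)
        e = self.base_energy + self.c14 / scee + self.l14 / scnb
        for v, n, g in zip(vs, self.spec.basis, np.deg2rad(gs)):
            e = e + np.sum(0.5 * v * (1.0 + np.cos(n * self.omega - g)), axis=0)
        return e

    def value_and_grad(self, x):
        nb = len(self.spec.basis)
        vs, gs, scee, scnb = self.unpack(x)
        grad = np.zeros_like(x)
        mm = self.mm_profile(x)
        r = (mm - mm.mean()) - (self.reference - self.reference.mean())
        # dL/dp = 2 sum_g r_g (dmm_g/dp - mean(dmm/dp)); r is mean-free so the
        # mean term drops out of the inner product
        for bi, (n, g) in enumerate(zip(self.spec.basis, np.deg2rad(gs))):
            dmm_dv = np.sum(0.5 * (1.0 + np.cos(n * self.omega - g)), axis=0)
            grad[bi] = 2.0 * np.dot(r, dmm_dv)
            if self.spec.mode == "full":
                dmm_dg = np.sum(0.5 * vs[bi] * np.sin(n * self.omega - g),
                                axis=0) * (np.pi / 180.0)
                grad[nb + bi] = 2.0 * np.dot(r, dmm_dg)
        if self.spec.mode == "full":
            grad[2 * nb] = 2.0 * np.dot(r, -self.c14 / scee ** 2)
            grad[2 * nb + 1] = 2.0 * np.dot(r, -self.l14 / scnb ** 2)
        return float(np.dot(r, r)), grad

    def __call__(self, x):
        return self.value_and_grad(x)

    # --- closed-form start for the full mode -------------------------------
    def linear_start(self) -> np.ndarray:
        """Solve the phase-free linearization a_n cos + b_n sin by least
        squares and convert to (V_n, gamma_n); scaling factors start at their
        current values."""
        cols = []
        for n in self.spec.basis:
            cols.append(np.sum(np.cos(n * self.omega), axis=0))
            cols.append(np.sum(np.sin(n * self.omega), axis=0))
        basis = np.column_stack(cols)
        basis = basis - basis.mean(axis=0)
        target = (self.reference - self.reference.mean()) - \
                 (self.base_energy + self.c14 / self.scee0 +
                  self.l14 / self.scnb0)
        target = target - target.mean()
        coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
        vs, gs = [], []
        lo, hi = self.spec.v_bounds
        for bi in range(len(self.spec.basis)):
            a, b = coef[2 * bi], coef[2 * bi + 1]
            v = 2.0 * float(np.hypot(a, b))
            g = float(np.rad2deg(np.arctan2(b, a))) % 360.0
            vs.append(min(max(v, lo), hi))
            gs.append(g)
        if self.spec.mode == "torsion_only":
            return np.array(vs)
        return np.array(vs + gs + [self.scee0, self.scnb0])


def _run_inner(obj: TorsionObjective, x0: np.ndarray):
    res = _scipy_minimize(obj.value_and_grad, x0, jac=True, method="L-BFGS-B",
                          bounds=obj.bounds(),
                          options=dict(maxiter=500, ftol=1e-15, gtol=1e-10))
    return res


def fit_torsion(topology: MoleculeTopology, quad, reference: ScanProfile,
                spec: FitSpec = FitSpec(),
                mm_scan=None, start_conformation: Conformation | None = None
                ) -> FitResult:
    """Fit one torsion type's Fourier components (and, in full mode, its
    scee/scnb) to a reference profile.

    ``mm_scan`` is a callable ``(topology) -> ScanProfile`` used both for the
    initial MM profile/geometries and to refresh geometries in the outer
    alternating loop; if omitted, the reference profile's stored geometries
    are frozen and a single outer cycle is performed.
    """
    quad = tuple(quad)
    ref_e = np.asarray(reference.energies, float)

    def mm_profile_for(top):
        if mm_scan is not None:
            return mm_scan(top)
        if any(g is None for g in reference.geometries):
            raise ValueError("no mm_scan given and reference lacks geometries")
        e = np.array([total_energy(top, g).total for g in reference.geometries])
        return ScanProfile(quad, reference.grid, e - e.min(),
                           list(reference.geometries), "frozen-geometry")

    current = topology
    prof = mm_profile_for(current)
    initial_rmse = profile_rmse(prof.energies, ref_e)
    rmse_prev = initial_rmse
    trace = [initial_rmse]
    best_term = None
    inner_total = 0
    converged = False
    cycles = 0
    for cycle in range(spec.max_outer):
        cycles = cycle + 1
        obj = TorsionObjective(current, quad, prof.geometries, ref_e, spec)
        starts = [obj.initial_vector()]
        if spec.mode == "full":
            starts.append(obj.linear_start())
        results = []
        for x0 in starts:
            try:
                results.append(_run_inner(obj, x0))
            except Exception as err:
                log.warning("inner optimizer failed from a start: %s", err)
        if not results:
            rng = np.random.default_rng(spec.retry_seed)
            jitter = obj.initial_vector()
            jitter[:len(spec.basis)] += rng.uniform(0, 0.5, len(spec.basis))
            try:
                results.append(_run_inner(obj, jitter))
            except Exception:
                warnings.warn(f"fit of {quad} failed; returning initial "
                              "parameters", RuntimeWarning, stacklevel=2)
                return FitResult(quad, obj.initial_term, initial_rmse,
                                 initial_rmse, cycles, inner_total, False,
                                 trace)
        res = min(results, key=lambda r: r.fun)
        inner_total += int(res.nit)
        best_term = obj.term_from_vector(res.x)
        current = topology
        for q in obj.sibling_quads:
            current = current.replace_torsion(q, replace(best_term, quad=q))
        prof = mm_profile_for(current)
        rmse = profile_rmse(prof.energies, ref_e)
        trace.append(rmse)
        if mm_scan is None or abs(rmse_prev - rmse) < spec.convergence:
            converged = True
            rmse_prev = rmse
            break
        rmse_prev = rmse

    final_rmse = trace[-1]
    if final_rmse > initial_rmse:
        warnings.warn(f"fit of {quad} degraded the objective "
                      f"({initial_rmse:.4f} -> {final_rmse:.4f}); returning "
                      "initial parameters", RuntimeWarning, stacklevel=2)
        initial_term = next(t for t in topology.torsions if not t.is_improper
                            and t.quad in (quad, quad[::-1]))
        return FitResult(quad, initial_term, initial_rmse, initial_rmse,
                         cycles, inner_total, False, trace)
    kept = tuple(c for c in best_term.components if c.v >= spec.prune_floor)
    if len(kept) < len(best_term.components):
        log.info("pruned %d sub-floor component(s) of %s",
                 len(best_term.components) - len(kept), quad)
    if not kept:
        kept = (FourierComponent(0.0, 1, 0.0),)
    term = TorsionTerm(quad, kept, best_term.scee, best_term.scnb)
    return FitResult(quad, term, initial_rmse, final_rmse, cycles,
                     inner_total, converged, trace)


def fit_all(topology: MoleculeTopology, significant, references: dict,
            spec: FitSpec = FitSpec(), mm_scan_factory=None) -> dict:
    """Fit each significant torsion independently against its reference.

    ``references`` maps canonical quads to ScanProfiles; ``mm_scan_factory``
    maps a torsion key to the per-torsion ``mm_scan`` callable.  Results are
    keyed by canonical quad and independent of iteration order.
    """
    out = {}
    for key in significant:
        quad = key.quad if hasattr(key, "quad") else tuple(key)
        canon = min(quad, quad[::-1])
        ref = references[canon]
        mm_scan = mm_scan_factory(key) if mm_scan_factory is not None else None
        out[canon] = fit_torsion(topology, quad, ref, spec, mm_scan=mm_scan)
    return out


def boltzmann_average_charges(per_centroid_charges, centroids: CentroidSet,
                              tol: float = 1e-6) -> np.ndarray:
    """Boltzmann-weighted per-atom mean of conformer-specific charge sets,
    q̄_i = sum_k w_k q_i^(k).  Every set must carry the same total molecular
    charge (to ``tol``), which the average then preserves."""
    qs = [np.asarray(q, float) for q in per_centroid_charges]
    if len(qs) != len(centroids):
        raise ValueError("one charge set per centroid required")
    totals = [q.sum() for q in qs]
    if max(totals) - min(totals) > tol:
        raise ValueError(f"total charge differs across conformer charge sets "
                         f"(spread {max(totals) - min(totals):.2e} e)")
    w = centroids.weights
    return np.sum([wk * q for wk, q in zip(w, qs)], axis=0)
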