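"""Molecular-mechanics core: the AMBER functional form and its exact gradient.

The potential implemented here is the standard gas-phase AMBER form

    V = sum_bonds  k_b (l - l0)^2
      + sum_angles k_a (theta - theta0)^2
      + sum_torsions sum_n  V_n/2 [1 + cos(n*omega - gamma_n)]
      + sum_{i<j}  eps_ij [(rmin_ij/r)^12 - 2 (rmin_ij/r)^6]  +  kq * q_i q_j / r

with 1-2 and 1-3 pairs excluded, 1-4 pairs divided by the owning torsion's
``scnb`` (Lennard-Jones) and ``scee`` (electrostatics), and all more distant
pairs unscaled.  Everything is all-pairs, no cutoffs, no periodic boundaries.

Units: kcal/mol, Angstrom, degrees at the API boundary (radians internally
for restraint curvature), elementary charges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.optimize import minimize as _scipy_minimize

# AMBER electrostatic prefactor 1/(4 pi eps0), kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0522173

__all__ = [
    "COULOMB_CONSTANT",
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "FourierComponent",
    "TorsionTerm",
    "MoleculeTopology",
    "Conformation",
    "DihedralRestraint",
    "EnergyBreakdown",
    "DegenerateGeometryError",
    "SingularityError",
    "dihedral_angle",
    "dihedral_gradient",
    "set_dihedral",
    "wrap_angle",
    "total_energy",
    "gradient",
    "restrained_minimize",
]


class DegenerateGeometryError(ValueError):
    """Three consecutive atoms of a dihedral are collinear."""


class SingularityError(ValueError):
    """Two interacting atoms coincide."""


@dataclass(frozen=True)
class AtomRecord:
    index: int
    element: str
    atom_type: str
    charge: float          # elementary charges
    mass: float            # amu
    lj_rmin_half: float    # Angstrom
    lj_epsilon: float      # kcal/mol

    def __post_init__(self):
        if self.lj_epsilon < 0 or self.lj_rmin_half < 0:
            raise ValueError("LJ parameters must be non-negative")


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_b: float   # kcal/mol/A^2
    l0: float    # A
    order: int = 1  # chemical bond order, used by the fragmenter's pattern rules

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if self.k_b <= 0 or self.l0 <= 0:
            raise ValueError("bond parameters must be positive")


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    k_a: float    # kcal/mol/rad^2
    theta0: float  # degrees

    def __post_init__(self):
        if self.k_a <= 0 or not (0.0 < self.theta0 <= 180.0):
            raise ValueError("invalid angle term")


@dataclass(frozen=True)
class FourierComponent:
    v: float          # barrier height V_n, kcal/mol
    n: int            # periodicity
    gamma: float      # phase, degrees

    def __post_init__(self):
        if not (1 <= int(self.n) <= 6):
            raise ValueError("periodicity must be in 1..6")


@dataclass(frozen=True)
class TorsionTerm:
    quad: tuple[int, int, int, int]
    components: tuple[FourierComponent, ...]
    scee: float = 1.2
    scnb: float = 2.0
    is_improper: bool = False

    def __post_init__(self):
        ns = [c.n for c in self.components]
        if len(set(ns)) != len(ns):
            raise ValueError("duplicate periodicities within one torsion term")
        if self.scee <= 0 or self.scnb <= 0:
            raise ValueError("scee and scnb must be positive")

    def energy_at(self, omega_deg: float | np.ndarray) -> float | np.ndarray:
        """Fourier-series torsion energy at dihedral omega (degrees)."""
        w = np.deg2rad(omega_deg)
        out = 0.0
        for c in self.components:
            out = out + 0.5 * c.v * (1.0 + np.cos(c.n * w - np.deg2rad(c.gamma)))
        return out


@dataclass(frozen=True)
class Conformation:
    coordinates: np.ndarray  # (N, 3) Angstrom

    def __post_init__(self):
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", xyz)


@dataclass(frozen=True)
class DihedralRestraint:
    """Flat-bottom dihedral restraint: zero inside +-tolerance of the target,
    k_restraint * (|dw| - tol)^2 beyond, with dw the wrapped deviation in radians."""
    quad: tuple[int, int, int, int]
    target: float            # degrees
    k_restraint: float = 500.0   # kcal/mol/rad^2
    tolerance: float = 0.5       # degrees

    def __post_init__(self):
        if self.k_restraint < 0 or self.tolerance < 0:
            raise ValueError("restraint parameters must be non-negative")


@dataclass
class Pair14:
    """A 1-4 nonbonded pair with the scaling factors of its owning torsion."""
    i: int
    j: int
    scee: float
    scnb: float


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    lj14: float = 0.0
    coulomb14: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.lj + self.coulomb
                + self.lj14 + self.coulomb14 + self.restraint)


@dataclass
class MoleculeTopology:
    """Atoms plus every parameterized interaction of the AMBER form.

    ``excluded_pairs`` holds 1-2 and 1-3 pairs; ``pairs14`` the 1-4 pairs with
    their owning torsion's scaling; any pair in neither interacts fully.
    """
    atoms: list[AtomRecord]
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    torsions: list[TorsionTerm]
    excluded_pairs: set[tuple[int, int]] = field(default_factory=set)
    pairs14: list[Pair14] = field(default_factory=list)

    def __post_init__(self):
        idx = [a.index for a in self.atoms]
        if idx != list(range(len(self.atoms))):
            raise ValueError("atom indices must be 0..N-1 in order")
        self.excluded_pairs = {(min(i, j), max(i, j)) for i, j in self.excluded_pairs}
        self._graph = None
        self._nb = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            for a in self.atoms:
                g.add_node(a.index, element=a.element)
            for b in self.bonds:
                g.add_edge(b.i, b.j, order=b.order)
            self._graph = g
        return self._graph

    def heavy_atoms(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def replace_torsion(self, quad: tuple[int, int, int, int],
                        term: TorsionTerm) -> "MoleculeTopology":
        """Return a copy with the proper torsion on ``quad`` (either reading
        order) replaced and its 1-4 pair rescaled consistently."""
        fq = tuple(quad)
        rq = fq[::-1]
        torsions = []
        hit = False
        for t in self.torsions:
            if not t.is_improper and (t.quad == fq or t.quad == rq):
                torsions.append(replace(term, quad=t.quad, is_improper=False))
                hit = True
            else:
                torsions.append(t)
        if not hit:
            raise KeyError(f"no proper torsion on quad {quad}")
        pkey = (min(fq[0], fq[3]), max(fq[0], fq[3]))
        pairs14 = [Pair14(p.i, p.j, term.scee, term.scnb)
                   if (min(p.i, p.j), max(p.i, p.j)) == pkey else p
                   for p in self.pairs14]
        return MoleculeTopology(self.atoms, self.bonds, self.angles, torsions,
                                set(self.excluded_pairs), pairs14)

    # --- cached index arrays for vectorized energy evaluation -------------
    def _arrays(self):
        if self._nb is not None:
            return self._nb
        n = self.n_atoms
        bidx = np.array([(b.i, b.j) for b in self.bonds], dtype=int).reshape(-1, 2)
        bk = np.array([b.k_b for b in self.bonds])
        bl0 = np.array([b.l0 for b in self.bonds])
        aidx = np.array([(a.i, a.j, a.k) for a in self.angles], dtype=int).reshape(-1, 3)
        ak = np.array([a.k_a for a in self.angles])
        at0 = np.deg2rad(np.array([a.theta0 for a in self.angles]))
        tq, tv, tn, tg = [], [], [], []
        for t in self.torsions:
            for c in t.components:
                tq.append(t.quad)
                tv.append(c.v)
                tn.append(c.n)
                tg.append(np.deg2rad(c.gamma))
        tq = np.array(tq, dtype=int).reshape(-1, 4)
        tv, tn, tg = np.array(tv), np.array(tn, dtype=int), np.array(tg)
        # full nonbonded pair list (i<j) minus exclusions and 1-4s
        p14key = {(min(p.i, p.j), max(p.i, p.j)) for p in self.pairs14}
        full = [(i, j) for i in range(n) for j in range(i + 1, n)
                if (i, j) not in self.excluded_pairs and (i, j) not in p14key]
        full = np.array(full, dtype=int).reshape(-1, 2)
        p14 = np.array([(p.i, p.j) for p in self.pairs14], dtype=int).reshape(-1, 2)
        p14_scee = np.array([p.scee for p in self.pairs14])
        p14_scnb = np.array([p.scnb for p in self.pairs14])
        q = np.array([a.charge for a in self.atoms])
        rmh = np.array([a.lj_rmin_half for a in self.atoms])
        eps = np.array([a.lj_epsilon for a in self.atoms])

        def _ljq(pairs):
            if len(pairs) == 0:
                return (np.zeros(0), np.zeros(0), np.zeros(0))
            i, j = pairs[:, 0], pairs[:, 1]
            rmin = rmh[i] + rmh[j]
            e = np.sqrt(eps[i] * eps[j])
            qq = COULOMB_CONSTANT * q[i] * q[j]
            return rmin, e, qq

        self._nb = dict(
            bidx=bidx, bk=bk, bl0=bl0, aidx=aidx, ak=ak, at0=at0,
            tq=tq, tv=tv, tn=tn, tg=tg,
            full=full, full_lj=_ljq(full),
            p14=p14, p14_lj=_ljq(p14), p14_scee=p14_scee, p14_scnb=p14_scnb,
        )
        return self._nb


# ---------------------------------------------------------------------------
# dihedral geometry
# ---------------------------------------------------------------------------

def wrap_angle(deg):
    """Wrap an angle in degrees to (-180, 180]."""
    w = -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)
    return w


def _dihedral_rad(xyz: np.ndarray, quad) -> float:
    i, j, k, l = quad
    b1 = xyz[j] - xyz[i]
    b2 = xyz[k] - xyz[j]
    b3 = xyz[l] - xyz[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise DegenerateGeometryError(f"collinear atoms in dihedral {tuple(quad)}")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def dihedral_angle(conformation: Conformation, quad: Sequence[int]) -> float:
    """Signed IUPAC dihedral i-j-k-l in degrees, in (-180, 180].

    Sign convention: looking down the j->k axis, a clockwise rotation of the
    k-l bond relative to the i-j bond is positive.  The value is invariant
    under reversal of the quadruple (l,k,j,i).
    """
    if len(set(quad)) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    ang = np.rad2deg(_dihedral_rad(conformation.coordinates, quad))
    return float(wrap_angle(ang))


def dihedral_gradient(xyz: np.ndarray, quad) -> tuple[float, np.ndarray]:
    """Dihedral (radians) and its derivative w.r.t. the four atom positions.

    Returns (phi, dphi) with dphi of shape (4, 3), rows ordered i, j, k, l.
    """
    i, j, k, l = quad
    b1 = xyz[j] - xyz[i]
    b2 = xyz[k] - xyz[j]
    b3 = xyz[l] - xyz[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    b2n = float(np.linalg.norm(b2))
    if n1sq < 1e-20 or n2sq < 1e-20:
        raise DegenerateGeometryError(f"collinear atoms in dihedral {tuple(quad)}")
    phi = np.arctan2(np.dot(np.cross(n1, b2 / b2n), n2), np.dot(n1, n2))
    F = (b2n / n1sq) * n1
    G = -(b2n / n2sq) * n2
    c12 = float(np.dot(b1, b2)) / (b2n * b2n)
    c32 = float(np.dot(b3, b2)) / (b2n * b2n)
    dphi_dj = -(1.0 + c12) * F + c32 * G
    dphi_dk = c12 * F - (1.0 + c32) * G
    return float(phi), np.stack([F, dphi_dj, dphi_dk, G])


def set_dihedral(topology: MoleculeTopology, conformation: Conformation,
                 quad: Sequence[int], target_deg: float) -> Conformation:
    """Rigidly rotate the l-side subtree about the j-k bond so the dihedral
    equals ``target_deg``.  The j-k bond must not be in a ring."""
    i, j, k, l = quad
    g = topology.graph.copy()
    g.remove_edge(j, k)
    if nx.has_path(g, j, k):
        raise ValueError("cannot set a dihedral whose central bond closes a ring")
    moving = nx.node_connected_component(g, k)
    xyz = conformation.coordinates.copy()
    current = dihedral_angle(conformation, quad)
    delta = np.deg2rad(wrap_angle(target_deg - current))
    axis = xyz[k] - xyz[j]
    axis = axis / np.linalg.norm(axis)
    # Rodrigues rotation about axis through atom j; positive dihedral change
    # corresponds to rotating the k-side clockwise viewed down j->k.
    c, s = np.cos(delta), np.sin(delta)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    idx = sorted(moving)
    xyz[idx] = (xyz[idx] - xyz[j]) @ R.T + xyz[j]
    out = Conformation(xyz)
    # the rotation sign depends on the subtree orientation; flip if needed
    if abs(wrap_angle(dihedral_angle(out, quad) - target_deg)) > 1e-6:
        R = np.eye(3) - s * K + (1 - c) * (K @ K)
        xyz = conformation.coordinates.copy()
        xyz[idx] = (xyz[idx] - xyz[j]) @ R.T + xyz[j]
        out = Conformation(xyz)
    return out


# ---------------------------------------------------------------------------
# energy and gradient
# ---------------------------------------------------------------------------

def _restraint_energy_grad(xyz, restraints: Iterable[DihedralRestraint],
                           grad: np.ndarray | None):
    e = 0.0
    for r in restraints:
        if r.k_restraint == 0.0:
            continue
        phi, dphi = dihedral_gradient(xyz, r.quad)
        dev = wrap_angle(np.rad2deg(phi) - r.target)      # degrees
        excess = abs(dev) - r.tolerance
        if excess <= 0.0:
            continue
        excess_rad = np.deg2rad(excess)
        e += r.k_restraint * excess_rad ** 2
        if grad is not None:
            dEdphi = 2.0 * r.k_restraint * excess_rad * np.sign(dev)
            for row, a in zip(dEdphi * dphi, r.quad):
                grad[a] += row
    return e


def _nonbonded(xyz, pairs, ljq, grad, scee=None, scnb=None):
    """LJ + Coulomb over a pair array; returns (lj, coulomb)."""
    if len(pairs) == 0:
        return 0.0, 0.0
    rmin, eps, qq = ljq
    d = xyz[pairs[:, 0]] - xyz[pairs[:, 1]]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < 1e-16):
        raise SingularityError("zero distance in a nonbonded pair")
    r = np.sqrt(r2)
    inv_scee = 1.0 if scee is None else 1.0 / scee
    inv_scnb = 1.0 if scnb is None else 1.0 / scnb
    x6 = (rmin ** 2 / r2) ** 3
    e_lj_pair = eps * (x6 * x6 - 2.0 * x6) * inv_scnb
    e_c_pair = qq / r * inv_scee
    if grad is not None:
        # dE/dr terms
        dlj = eps * (-12.0 * x6 * x6 + 12.0 * x6) / r * inv_scnb
        dc = -qq / r2 * inv_scee
        f = ((dlj + dc) / r)[:, None] * d
        np.add.at(grad, pairs[:, 0], f)
        np.add.at(grad, pairs[:, 1], -f)
    return float(np.sum(e_lj_pair)), float(np.sum(e_c_pair))


def _energy_impl(topology: MoleculeTopology, xyz: np.ndarray,
                 restraints: Sequence[DihedralRestraint] = (),
                 want_grad: bool = False):
    arr = topology._arrays()
    grad = np.zeros_like(xyz) if want_grad else None
    br = EnergyBreakdown()

    if len(arr["bidx"]):
        d = xyz[arr["bidx"][:, 0]] - xyz[arr["bidx"][:, 1]]
        r = np.linalg.norm(d, axis=1)
        dl = r - arr["bl0"]
        br.bond = float(np.sum(arr["bk"] * dl ** 2))
        if want_grad:
            f = (2.0 * arr["bk"] * dl / r)[:, None] * d
            np.add.at(grad, arr["bidx"][:, 0], f)
            np.add.at(grad, arr["bidx"][:, 1], -f)

    if len(arr["aidx"]):
        ai, aj, ak_idx = arr["aidx"][:, 0], arr["aidx"][:, 1], arr["aidx"][:, 2]
        u = xyz[ai] - xyz[aj]
        v = xyz[ak_idx] - xyz[aj]
        p = np.cross(u, v)
        pn = np.linalg.norm(p, axis=1)
        theta = np.arctan2(pn, np.einsum("ij,ij->i", u, v))
        dt = theta - arr["at0"]
        br.angle = float(np.sum(arr["ak"] * dt ** 2))
        if want_grad:
            safe = np.maximum(pn, 1e-12)
            dth_di = np.cross(u, p) / (np.einsum("ij,ij->i", u, u) * safe)[:, None]
            dth_dk = -np.cross(v, p) / (np.einsum("ij,ij->i", v, v) * safe)[:, None]
            coef = (2.0 * arr["ak"] * dt)[:, None]
            np.add.at(grad, ai, coef * dth_di)
            np.add.at(grad, ak_idx, coef * dth_dk)
            np.add.at(grad, aj, -coef * (dth_di + dth_dk))

    if len(arr["tq"]):
        ti, tj, tk, tl = (arr["tq"][:, c] for c in range(4))
        b1 = xyz[tj] - xyz[ti]
        b2 = xyz[tk] - xyz[tj]
        b3 = xyz[tl] - xyz[tk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        b2n = np.linalg.norm(b2, axis=1)
        if np.any(n1sq < 1e-20) or np.any(n2sq < 1e-20):
            raise DegenerateGeometryError("collinear atoms in a torsion")
        m = np.cross(n1, b2 / b2n[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m, n2),
                         np.einsum("ij,ij->i", n1, n2))
        br.torsion = float(np.sum(
            0.5 * arr["tv"] * (1.0 + np.cos(arr["tn"] * phi - arr["tg"]))))
        if want_grad:
            dE = -0.5 * arr["tv"] * arr["tn"] * np.sin(arr["tn"] * phi - arr["tg"])
            F = (b2n / n1sq)[:, None] * n1
            G = -(b2n / n2sq)[:, None] * n2
            c12 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
            c32 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
            dE = dE[:, None]
            np.add.at(grad, ti, dE * F)
            np.add.at(grad, tj, dE * (-(1.0 + c12) * F + c32 * G))
            np.add.at(grad, tk, dE * (c12 * F - (1.0 + c32) * G))
            np.add.at(grad, tl, dE * G)

    br.lj, br.coulomb = _nonbonded(xyz, arr["full"], arr["full_lj"], grad)
    br.lj14, br.coulomb14 = _nonbonded(xyz, arr["p14"], arr["p14_lj"], grad,
                                       scee=arr["p14_scee"], scnb=arr["p14_scnb"])
    br.restraint = _restraint_energy_grad(xyz, restraints, grad)
    return br, grad


def total_energy(topology: MoleculeTopology, conformation: Conformation,
                 restraints: Sequence[DihedralRestraint] = ()) -> EnergyBreakdown:
    """Evaluate the AMBER energy, component by component."""
    br, _ = _energy_impl(topology, conformation.coordinates, restraints, False)
    return br


def gradient(topology: MoleculeTopology, conformation: Conformation,
             restraints: Sequence[DihedralRestraint] = ()) -> np.ndarray:
    """Exact Cartesian energy gradient, shape (N, 3), kcal/mol/A."""
    _, g = _energy_impl(topology, conformation.coordinates, restraints, True)
    return g


@dataclass
class MinimizeResult:
    conformation: Conformation
    energy: float
    converged: bool
    max_grad: float
    n_iter: int


def restrained_minimize(topology: MoleculeTopology, conformation: Conformation,
                        restraints: Sequence[DihedralRestraint] = (),
                        convergence: float = 1e-4,
                        max_iter: int = 4000) -> MinimizeResult:
    """Cartesian local minimization under flat-bottom dihedral restraints.

    Limited-memory quasi-Newton (L-BFGS-B); converged when the largest
    gradient component (restraint forces included) falls below ``convergence``
    in kcal/mol/A.  On non-convergence the best geometry found is returned
    with a warning and ``converged=False``.
    """
    n = topology.n_atoms
    restraints = tuple(restraints)

    def fun(x):
        br, g = _energy_impl(topology, x.reshape(n, 3), restraints, True)
        return br.total, g.ravel()

    res = _scipy_minimize(fun, conformation.coordinates.ravel(), jac=True,
                          method="L-BFGS-B",
                          options=dict(maxiter=max_iter, ftol=1e-14,
                                       gtol=convergence * 0.1, maxcor=20))
    xyz = res.x.reshape(n, 3)
    br, g = _energy_impl(topology, xyz, restraints, True)
    max_grad = float(np.max(np.abs(g))) if n else 0.0
    converged = max_grad <= convergence
    if not converged:
        warnings.warn(f"minimization did not reach max|grad| <= {convergence} "
                      f"(got {max_grad:.3g}); returning best geometry",
                      RuntimeWarning, stacklevel=2)
    return MinimizeResult(Conformation(xyz), float(br.total), converged,
                          max_grad, int(res.nit))
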