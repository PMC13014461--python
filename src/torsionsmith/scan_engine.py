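"""Restrained 360-degree torsion scans and smoothness-based profile selection.

A scan visits every point of a uniform dihedral grid, restraining the scanned
torsion to each target with a flat-bottom dihedral restraint (default
500 kcal/mol/rad^2, +-0.5 deg) and relaxing everything else.  The walk is
sequential around the circle, each point seeded from its neighbour's relaxed
geometry, which suppresses the discontinuities the smoothness score exists to
catch.  Scans are launched from every centroid; the profile that is best
described by a low-order Fourier series and has the least point-to-point
roughness wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .ffcore import (Conformation, DihedralRestraint, MoleculeTopology,
                     dihedral_angle, restrained_minimize, set_dihedral,
                     total_energy, wrap_angle)

__all__ = [
    "ScanGrid", "ScanPoint", "ScanProfile", "SmoothnessScore", "ScanBackend",
    "InternalMMBackend", "SyntheticOracleBackend", "make_grid", "run_scan",
    "smoothness", "select_best_profile", "read_profile", "write_profile",
]


@dataclass(frozen=True)
class ScanGrid:
    spacing: float
    angles: tuple[float, ...]   # ordered, in (-180, 180]


def make_grid(spacing: float = 20.0) -> ScanGrid:
    """Uniform dihedral grid covering a full rotation; 20 deg -> 18 points."""
    if spacing <= 0 or abs(360.0 / spacing - round(360.0 / spacing)) > 1e-9:
        raise ValueError(f"grid spacing {spacing} must divide 360")
    n = int(round(360.0 / spacing))
    angles = tuple(float(wrap_angle(-180.0 + spacing * (k + 1))) for k in range(n))
    return ScanGrid(float(spacing), angles)


@dataclass
class ScanPoint:
    angle: float
    energy: float
    conformation: Conformation | None
    converged: bool = True


class ScanBackend(Protocol):
    """A source of constrained-minimum energies on a dihedral grid."""
    name: str

    def scan_point(self, topology: MoleculeTopology, conformation: Conformation,
                   quad: Sequence[int], target_deg: float) -> ScanPoint: ...


@dataclass
class InternalMMBackend:
    """Relaxed scan under the package's own AMBER engine.

    The reported energy is the unrestrained force-field energy at the
    restrained minimum (the restraint does work only outside its tolerance
    band, so at convergence its contribution is ~0 anyway).
    """
    k_restraint: float = 500.0
    tolerance: float = 0.5
    convergence: float = 1e-4
    name: str = "internal-mm"

    def scan_point(self, topology, conformation, quad, target_deg) -> ScanPoint:
        restr = DihedralRestraint(tuple(quad), float(target_deg),
                                  self.k_restraint, self.tolerance)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = restrained_minimize(topology, conformation, [restr],
                                      convergence=self.convergence)
        e = total_energy(topology, res.conformation).total
        return ScanPoint(float(target_deg), float(e), res.conformation,
                         res.converged)


@dataclass
class SyntheticOracleBackend:
    """Closed-form Fourier reference E(theta) = sum V_n/2 (1 + cos(n theta - gamma_n)).

    Geometries are produced by rigidly setting the scanned dihedral, so the
    backend is exact, instantaneous, and has a known ground truth.
    """
    components: tuple   # of ffcore.FourierComponent
    noise_sigma: float = 0.0
    seed: int = 0
    name: str = "synthetic-oracle"

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def energy_at(self, theta_deg: float) -> float:
        th = np.deg2rad(theta_deg)
        e = sum(0.5 * c.v * (1.0 + np.cos(c.n * th - np.deg2rad(c.gamma)))
                for c in self.components)
        if self.noise_sigma > 0:
            e += self._rng.normal(0.0, self.noise_sigma)
        return float(e)

    def scan_point(self, topology, conformation, quad, target_deg) -> ScanPoint:
        try:
            geo = set_dihedral(topology, conformation, quad, target_deg)
        except ValueError:
            geo = conformation
        return ScanPoint(float(target_deg), self.energy_at(target_deg), geo)


@dataclass
class ScanProfile:
    key: tuple[int, int, int, int]
    grid: ScanGrid
    energies: np.ndarray              # kcal/mol, shifted so min == 0
    geometries: list[Conformation | None]
    backend: str
    origin_centroid: int = 0
    degraded: bool = False
    raw_minimum: float = 0.0          # energy that was subtracted in the shift

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.grid.angles):
            raise ValueError("profile length must match grid")

    def energy_at(self, angle: float) -> float:
        i = int(np.argmin(np.abs(wrap_angle(np.array(self.grid.angles) - angle))))
        return float(self.energies[i])


def run_scan(backend: ScanBackend, topology: MoleculeTopology,
             start_conformation: Conformation, quad: Sequence[int],
             grid: ScanGrid, origin_centroid: int = 0) -> ScanProfile:
    """Drive one full-rotation scan of ``quad`` starting near the input geometry.

    The walk starts at the grid point nearest the starting dihedral and
    proceeds sequentially around the circle, seeding each constrained
    minimization with the previous point's relaxed geometry.  A failed point
    is linearly interpolated from its neighbours and the profile is marked
    degraded.
    """
    angles = np.array(grid.angles)
    start = dihedral_angle(start_conformation, quad)
    first = int(np.argmin(np.abs(wrap_angle(angles - start))))
    order = [(first + s) % len(angles) for s in range(len(angles))]

    energies = np.full(len(angles), np.nan)
    geometries: list[Conformation | None] = [None] * len(angles)
    failed = []
    seed = start_conformation
    for idx in order:
        pt = backend.scan_point(topology, seed, tuple(quad), angles[idx])
        if pt.conformation is not None:
            seed = pt.conformation
        if pt.converged and np.isfinite(pt.energy):
            energies[idx] = pt.energy
            geometries[idx] = pt.conformation
        else:
            failed.append(idx)

    degraded = bool(failed)
    if degraded:
        ok = np.where(np.isfinite(energies))[0]
        if len(ok) == 0:
            raise RuntimeError("every scan point failed")
        for idx in failed:   # circular linear interpolation between neighbours
            lo = max(o for o in ok) if idx < ok.min() else ok[ok < idx].max(initial=ok.max())
            hi = ok[ok > idx].min() if np.any(ok > idx) else ok.min()
            energies[idx] = 0.5 * (energies[lo] + energies[hi])

    emin = float(np.min(energies))
    return ScanProfile(tuple(quad), grid, energies - emin, geometries,
                       getattr(backend, "name", "unknown"), origin_centroid,
                       degraded, emin)


@dataclass(frozen=True)
class SmoothnessScore:
    fourier_residual: float   # RMS residual of a low-order Fourier fit
    max_jump: float           # largest |dE| between circularly consecutive points
    jaggedness: float         # RMS circular second difference
    composite: float


def smoothness(profile: ScanProfile, fourier_order: int = 4,
               w_jump: float = 0.5, w_curv: float = 0.5) -> SmoothnessScore:
    """Composite roughness score; lower is smoother.

    composite = fourier_residual + w_jump * max_jump + w_curv * jaggedness.
    All components scale linearly with the profile's energies.
    """
    th = np.deg2rad(np.array(profile.grid.angles))
    e = profile.energies
    cols = [np.ones_like(th)]
    for n in range(1, fourier_order + 1):
        cols += [np.cos(n * th), np.sin(n * th)]
    basis = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(basis, e, rcond=None)
    resid = e - basis @ coef
    fr = float(np.sqrt(np.mean(resid ** 2)))
    de = np.diff(np.concatenate([e, e[:1]]))
    mj = float(np.max(np.abs(de))) if len(de) else 0.0
    d2 = np.roll(e, -1) - 2 * e + np.roll(e, 1)
    jag = float(np.sqrt(np.mean(d2 ** 2)))
    return SmoothnessScore(fr, mj, jag, fr + w_jump * mj + w_curv * jag)


def select_best_profile(profiles: Sequence[ScanProfile],
                        fourier_order: int = 4) -> ScanProfile:
    """Smoothest profile wins; ties go to the lowest origin centroid, and a
    degraded profile loses every tie."""
    if not profiles:
        raise ValueError("no candidate profiles")
    scored = [(smoothness(p, fourier_order).composite, p.degraded,
               p.origin_centroid, i) for i, p in enumerate(profiles)]
    scored.sort()
    return profiles[scored[0][3]]


# --- tabulated-profile interchange (two-column text) -----------------------

def write_profile(path, profile: ScanProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"# torsion {'-'.join(map(str, profile.key))} "
                 f"backend={profile.backend} centroid={profile.origin_centroid}\n")
        fh.write("# angle_deg  energy_kcal_mol\n")
        for a, e in zip(profile.grid.angles, profile.energies):
            fh.write(f"{a:10.3f}  {e:16.8f}\n")


def read_profile(path, key=(0, 1, 2, 3)) -> ScanProfile:
    data = np.loadtxt(path, comments="#", ndmin=2)
    angles = data[:, 0]
    spacing = float(np.min(np.diff(np.sort(angles)))) if len(angles) > 1 else 360.0
    grid = make_grid(spacing)
    order = np.argsort([grid.angles.index(float(wrap_angle(a))) for a in angles])
    e = data[order, 1]
    e = e - e.min()
    return ScanProfile(tuple(key), grid, e, [None] * len(e), "tabulated")
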