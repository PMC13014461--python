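"""Seeded synthetic fixtures: toy molecules with fully explicit AMBER-style
parameters, deterministic conformer sets, closed-form reference profiles, and
a mock quantum backend with an exactly known ground truth.

The force-field constants used here are physically plausible round numbers
(they do not need to match any real GAFF2 assignment):

    bond      C-C 300 kcal/mol/A^2 @ 1.526 A   (order 2 / aromatic: 450 @ 1.40)
              C-H 340 @ 1.09, C-N 330 @ 1.38, C=O 570 @ 1.23, N-H 430 @ 1.01
    angle     40 kcal/mol/rad^2, 109.5 deg at sp3 centres, 120 deg at sp2
    torsion   X-C-C-X (1.4, n=3, 0 deg); around a double/aromatic bond
              (6.0, n=2, 180 deg); involving H (0.16, n=3, 0 deg)
    LJ        C 1.9/0.109, H 1.387/0.0157, N 1.824/0.17, O 1.661/0.21
    scaling   scee 1.2, scnb 2.0 on every 1-4 pair
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx

from .ffcore import (AngleTerm, AtomRecord, BondTerm, Conformation,
                     FourierComponent, MoleculeTopology, Pair14, TorsionTerm,
                     dihedral_angle, set_dihedral)
from .scan_engine import (InternalMMBackend, ScanGrid, ScanPoint, ScanProfile)

__all__ = [
    "FixtureMolecule", "SyntheticReferenceSpec", "make_fixture",
    "build_topology", "synthetic_reference", "MockQMBackend", "mock_qm_backend",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("butane_like", "biphenyl_like", "amide_chain", "two_region",
                 "rigid_ring")

_LJ = {"C": (1.9, 0.109), "H": (1.387, 0.0157), "N": (1.824, 0.17),
       "O": (1.661, 0.21), "S": (2.0, 0.25)}
_MASS = {"C": 12.01, "H": 1.008, "N": 14.01, "O": 16.0, "S": 32.06}
_BONDS = {("C", "C", 1): (300.0, 1.526), ("C", "C", 2): (450.0, 1.40),
          ("C", "H", 1): (340.0, 1.09), ("C", "N", 1): (330.0, 1.38),
          ("C", "O", 1): (320.0, 1.43), ("C", "O", 2): (570.0, 1.23),
          ("H", "N", 1): (430.0, 1.01)}


@dataclass
class FixtureMolecule:
    name: str
    topology: MoleculeTopology
    conformations: list[Conformation]
    charge_sets: list[np.ndarray] | None = None


@dataclass(frozen=True)
class SyntheticReferenceSpec:
    components: tuple[FourierComponent, ...]
    sigma: float = 0.0      # Gaussian noise, kcal/mol
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = angle and the signed
    dihedral a-b-c-d equals ``dihedral_deg`` under :func:`dihedral_angle`'s
    convention."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(theta),
                   bond * np.sin(theta) * np.cos(phi),
                   -bond * np.sin(theta) * np.sin(phi)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def zigzag_chain(n: int, bond: float = 1.526, angle: float = 109.5,
                 dihedral: float = 180.0) -> np.ndarray:
    """All-``dihedral`` chain of n atoms (trans zigzag by default)."""
    xyz = np.zeros((n, 3))
    if n > 1:
        xyz[1] = [bond, 0.0, 0.0]
    if n > 2:
        th = np.deg2rad(180.0 - angle)
        xyz[2] = xyz[1] + bond * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(3, n):
        xyz[i] = nerf_place(xyz[i - 3], xyz[i - 2], xyz[i - 1],
                            bond, angle, dihedral)
    return xyz


def hexagon(center: np.ndarray, side: float = 1.40, phase_deg: float = 0.0) -> np.ndarray:
    ang = np.deg2rad(phase_deg + 60.0 * np.arange(6))
    return center[None, :] + side * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(6)])


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def _bond_params(e1: str, e2: str, order: int):
    key = tuple(sorted((e1, e2))) + (order,)
    return _BONDS.get(key, (300.0, 1.5))


def _torsion_components(elements, quad, order_jk):
    i, j, k, l = quad
    if order_jk >= 2:
        return (FourierComponent(6.0, 2, 180.0),)
    if elements[i] == "H" or elements[l] == "H":
        return (FourierComponent(0.16, 3, 0.0),)
    return (FourierComponent(1.4, 3, 0.0),)


def build_topology(elements: Sequence[str],
                   bond_list: Sequence[tuple],
                   charges: Sequence[float] | None = None,
                   sp2_atoms: set[int] | None = None,
                   scee: float = 1.2, scnb: float = 2.0,
                   torsion_overrides: dict | None = None,
                   atom_types: Sequence[str] | None = None) -> MoleculeTopology:
    """Assemble a fully parameterized topology from elements and a bond list.

    ``bond_list`` entries are (i, j) or (i, j, order).  Angles, proper
    torsions, 1-2/1-3 exclusions and 1-4 pairs are generated from the graph;
    parameters come from the fixture tables above.  ``torsion_overrides`` maps
    a canonical quad to a components tuple.
    """
    n = len(elements)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    sp2 = set() if sp2_atoms is None else set(sp2_atoms)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    bonds = []
    for entry in bond_list:
        i, j, *rest = entry
        order = rest[0] if rest else 1
        kb, l0 = _bond_params(elements[i], elements[j], order)
        bonds.append(BondTerm(i, j, kb, l0, order))
        g.add_edge(i, j, order=order)
        if order >= 2:
            sp2.update((i, j))
    if atom_types is None:
        atom_types = [f"{e.lower()}x" for e in elements]
    atoms = [AtomRecord(i, elements[i], atom_types[i],
                        float(charges[i]), _MASS.get(elements[i], 12.0),
                        *_LJ.get(elements[i], (1.8, 0.1))) for i in range(n)]
    angles = []
    for j in g.nodes:
        nbrs = sorted(g.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                theta0 = 120.0 if j in sp2 else 109.5
                angles.append(AngleTerm(nbrs[a], j, nbrs[b], 40.0, theta0))
    # proper torsions: one per bonded path i-j-k-l, canonical orientation
    quads = set()
    for j, k in g.edges:
        for jj, kk in ((j, k), (k, j)):
            for i in g.neighbors(jj):
                if i == kk:
                    continue
                for l in g.neighbors(kk):
                    if l == jj or l == i:
                        continue
                    q = (i, jj, kk, l)
                    if q[::-1] in quads:
                        continue
                    quads.add(q)
    torsion_overrides = torsion_overrides or {}
    torsions = []
    for q in sorted(quads):
        comps = torsion_overrides.get(q) or torsion_overrides.get(q[::-1]) \
            or _torsion_components(elements, q, g.edges[q[1], q[2]]["order"])
        torsions.append(TorsionTerm(q, tuple(comps), scee, scnb))
    # exclusions and 1-4 pairs
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    excluded = {(min(i, j), max(i, j))
                for i in range(n) for j, d in dist[i].items()
                if i < j and d in (1, 2)}
    pairs14, seen = [], set()
    for t in torsions:
        i, l = t.quad[0], t.quad[3]
        key = (min(i, l), max(i, l))
        if key in excluded or key in seen:
            continue
        if dist[key[0]].get(key[1]) != 3:   # ring short-circuit
            continue
        seen.add(key)
        pairs14.append(Pair14(key[0], key[1], t.scee, t.scnb))
    return MoleculeTopology(atoms, bonds, angles, torsions, excluded, pairs14)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _conformers_by_dihedral(top, base, settings):
    out = []
    for s in settings:
        conf = base
        for quad, ang in s:
            conf = set_dihedral(top, conf, quad, ang)
        out.append(conf)
    return out


def _butane_like() -> FixtureMolecule:
    elements = ["C"] * 6
    bonds = [(i, i + 1) for i in range(5)]
    charges = [0.05, -0.05, 0.05, -0.05, 0.05, -0.05]
    top = build_topology(elements, bonds, charges)
    base = Conformation(zigzag_chain(6))
    confs = _conformers_by_dihedral(top, base, [
        [((1, 2, 3, 4), 180.0)],
        [((1, 2, 3, 4), 65.0)],
        [((1, 2, 3, 4), -65.0)],
    ])
    qs = []
    for d in (0.0, 0.01, -0.01):
        q = np.array(charges, float)
        q[0] += d
        q[5] -= d
        qs.append(q)
    return FixtureMolecule("butane_like", top, confs, qs)


def _rigid_ring() -> FixtureMolecule:
    elements = ["C"] * 6
    bonds = [(i, (i + 1) % 6, 2 - i % 2) for i in range(6)]
    top = build_topology(elements, bonds)
    base = hexagon(np.zeros(3))
    confs = []
    for ang in (0.0, 25.0, 50.0):   # rigid rotations only
        c, s = np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        confs.append(Conformation(base @ rot.T))
    return FixtureMolecule("rigid_ring", top, confs)


def _biphenyl_like() -> FixtureMolecule:
    elements = ["C"] * 12
    bonds = [(i, (i + 1) % 6, 2 - i % 2) for i in range(6)]
    bonds += [(6 + i, 6 + (i + 1) % 6, 2 - i % 2) for i in range(6)]
    bonds += [(0, 6, 1)]
    top = build_topology(elements, bonds, atom_types=["ca"] * 6 + ["cb"] * 6)
    ring_a = hexagon(np.array([-1.40, 0.0, 0.0]))          # atom 0 at origin
    ring_b = hexagon(np.array([2.88, 0.0, 0.0]), phase_deg=180.0)
    base = Conformation(np.vstack([ring_a, ring_b]))
    confs = _conformers_by_dihedral(top, base, [
        [((1, 0, 6, 7), 40.0)],
        [((1, 0, 6, 7), 90.0)],
        [((1, 0, 6, 7), 140.0)],
    ])
    return FixtureMolecule("biphenyl_like", top, confs)


def _amide_chain() -> FixtureMolecule:
    #  C0-C1-C2-C3-C4(=O5)-N6(-H7)-C8-C9-C10-C11
    elements = ["C", "C", "C", "C", "C", "O", "N", "H", "C", "C", "C", "C"]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5, 2), (4, 6), (6, 7),
             (6, 8), (8, 9), (9, 10), (10, 11)]
    charges = [0.0, 0.0, 0.0, 0.1, 0.5, -0.5, -0.4, 0.3, 0.0, 0.0, 0.0, 0.0]
    # the amide bond itself is rigid (planar, high barrier)
    top = build_topology(elements, bonds, charges, sp2_atoms={4, 6},
                         torsion_overrides={(3, 4, 6, 8): (FourierComponent(10.0, 2, 180.0),),
                                            (5, 4, 6, 8): (FourierComponent(10.0, 2, 180.0),),
                                            (3, 4, 6, 7): (FourierComponent(2.0, 2, 180.0),),
                                            (5, 4, 6, 7): (FourierComponent(2.0, 2, 180.0),)})
    heavy_chain = [0, 1, 2, 3, 4, 6, 8, 9, 10, 11]
    xyz = np.zeros((12, 3))
    cxyz = zigzag_chain(len(heavy_chain))
    for pos, a in enumerate(heavy_chain):
        xyz[a] = cxyz[pos]
    xyz[5] = nerf_place(xyz[2], xyz[3], xyz[4], 1.23, 120.0, 60.0)
    xyz[7] = nerf_place(xyz[3], xyz[4], xyz[6], 1.01, 120.0, 180.0)
    base = Conformation(xyz)
    confs = _conformers_by_dihedral(top, base, [
        [((1, 2, 3, 4), 180.0), ((6, 8, 9, 10), 180.0)],
        [((1, 2, 3, 4), 65.0), ((6, 8, 9, 10), -65.0)],
        [((1, 2, 3, 4), -65.0), ((6, 8, 9, 10), 65.0)],
    ])
    return FixtureMolecule("amide_chain", top, confs)


def _two_region() -> FixtureMolecule:
    # C0..C4 - ring(5..10) - C11..C15, chains para-attached at ring atoms 5 and 8
    elements = ["C"] * 16
    ring = [(5 + i, 5 + (i + 1) % 6, 2 - i % 2) for i in range(6)]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)] + ring + \
            [(8, 11), (11, 12), (12, 13), (13, 14), (14, 15)]
    types = ["ca", "cb", "cc", "cd", "ce"] + ["cr"] * 6 + \
            ["cf", "cg", "ch", "ci", "cj"]
    top = build_topology(elements, bonds, atom_types=types)
    ring_xyz = hexagon(np.zeros(3))            # atoms 5..10; 5 at +x, 8 at -x
    xyz = np.zeros((16, 3))
    xyz[5:11] = ring_xyz
    left = zigzag_chain(7)                      # template for 5 chain atoms
    # attach C4 to ring atom 5 along +x, then walk outward
    xyz[4] = ring_xyz[0] + np.array([1.5, 0.0, 0.0])
    for a, prev3 in zip((3, 2, 1, 0), range(4)):
        ref = {3: (ring_xyz[1], ring_xyz[0], xyz[4]),
               2: (ring_xyz[0], xyz[4], xyz[3]),
               1: (xyz[4], xyz[3], xyz[2]),
               0: (xyz[3], xyz[2], xyz[1])}[a]
        xyz[a] = nerf_place(*ref, 1.526, 109.5 if a < 3 else 120.0, 180.0)
    xyz[11] = ring_xyz[3] + np.array([-1.5, 0.0, 0.0])
    refs = {12: (ring_xyz[4], ring_xyz[3], xyz[11]),
            13: None, 14: None, 15: None}
    xyz[12] = nerf_place(ring_xyz[4], ring_xyz[3], xyz[11], 1.526, 120.0, 180.0)
    xyz[13] = nerf_place(ring_xyz[3], xyz[11], xyz[12], 1.526, 109.5, 180.0)
    xyz[14] = nerf_place(xyz[11], xyz[12], xyz[13], 1.526, 109.5, 180.0)
    xyz[15] = nerf_place(xyz[12], xyz[13], xyz[14], 1.526, 109.5, 180.0)
    base = Conformation(xyz)
    confs = _conformers_by_dihedral(top, base, [
        [((1, 2, 3, 4), 180.0), ((11, 12, 13, 14), 180.0)],
        [((1, 2, 3, 4), 65.0), ((11, 12, 13, 14), -65.0)],
        [((1, 2, 3, 4), -65.0), ((11, 12, 13, 14), 65.0)],
    ])
    return FixtureMolecule("two_region", top, confs)


_BUILDERS = {"butane_like": _butane_like, "rigid_ring": _rigid_ring,
             "biphenyl_like": _biphenyl_like, "amide_chain": _amide_chain,
             "two_region": _two_region}


def make_fixture(name: str) -> FixtureMolecule:
    """Deterministic toy molecule with explicit parameters and conformers."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return _BUILDERS[name]()


# ---------------------------------------------------------------------------
# synthetic reference profiles and the mock quantum backend
# ---------------------------------------------------------------------------

def synthetic_reference(spec: SyntheticReferenceSpec, grid: ScanGrid,
                        key=(0, 1, 2, 3)) -> ScanProfile:
    """Closed-form Fourier profile E(theta) = sum V/2 (1+cos(n theta - gamma))
    plus seeded Gaussian noise, shifted so its minimum is zero."""
    th = np.deg2rad(np.array(grid.angles))
    e = np.zeros_like(th)
    for c in spec.components:
        e += 0.5 * c.v * (1.0 + np.cos(c.n * th - np.deg2rad(c.gamma)))
    if spec.sigma > 0:
        e = e + np.random.default_rng(spec.seed).normal(0.0, spec.sigma, len(e))
    emin = float(e.min())
    return ScanProfile(tuple(key), grid, e - emin, [None] * len(e),
                       "synthetic-reference", raw_minimum=emin)


@dataclass
class MockQMBackend:
    """Reference backend that is secretly the internal MM engine running on a
    seeded, torsion-perturbed copy of the topology — so every fit against it
    has an exactly known ground truth."""
    topology: MoleculeTopology           # the *perturbed* topology
    truth: dict                          # quad -> TorsionTerm ground truth
    name: str = "mock-qm"
    mm: InternalMMBackend = field(default_factory=InternalMMBackend)

    def scan_point(self, topology, conformation, quad, target_deg) -> ScanPoint:
        return self.mm.scan_point(self.topology, conformation, quad, target_deg)


def mock_qm_backend(topology: MoleculeTopology, perturbation_seed: int = 0,
                    target_quads: Sequence[tuple] | None = None,
                    dv_range: tuple[float, float] = (1.0, 2.5)) -> MockQMBackend:
    """Perturb torsion barrier heights by a seeded uniform draw and wrap the
    MM engine around the perturbed topology.

    The perturbation is drawn once per atom-type quadruple and applied to
    every proper torsion of that type (AMBER parameters are type-based, so
    this is the only kind of change a refit could ever express exactly).
    ``truth`` is keyed by quad for every perturbed torsion."""
    import zlib

    from .io_formats import type_quadruple
    if target_quads is None:
        target_quads = [t.quad for t in topology.torsions if not t.is_improper]
    wanted_types = {type_quadruple(topology, q) for q in target_quads}
    # one draw per type, seeded by (seed, stable type hash) so that a fragment
    # and its parent see identical perturbations on shared types
    deltas = {}
    for tq in sorted(wanted_types):
        h = zlib.crc32("-".join(tq).encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([perturbation_seed, h])
        deltas[tq] = float(rng.uniform(*dv_range))
    perturbed = topology
    truth = {}
    for t in topology.torsions:
        if t.is_improper:
            continue
        tq = type_quadruple(topology, t.quad)
        if tq not in deltas:
            continue
        comps = tuple(FourierComponent(c.v + deltas[tq], c.n, c.gamma)
                      for c in t.components)
        term = TorsionTerm(t.quad, comps, t.scee, t.scnb)
        perturbed = perturbed.replace_torsion(t.quad, term)
        truth[t.quad] = term
    return MockQMBackend(perturbed, truth)
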