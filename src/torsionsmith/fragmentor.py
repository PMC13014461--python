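"""Torsion-focused fragmentation: decide whether a molecule should be cut
down before scanning, partition significant torsions into connected regions,
select legal cleavage bonds, and build methyl-capped fragments with bijective
atom maps back to the parent.

Cleavage rules protect the chemistry that defines a torsion's profile: only
acyclic single bonds outside the torsion region are cut, at least two bonds
away from every region central bond (so every 1-4 environment of the fitted
torsions survives intact), never inside a protected functional group (amide,
ester, sulfonamide, nitro, carboxylate, guanidinium by default), and never
next to an exocyclic double bond on a ring atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from .ffcore import (AngleTerm, AtomRecord, BondTerm, Conformation,
                     FourierComponent, MoleculeTopology, TorsionTerm)
from .io_formats import AtomMap
from .torsion_select import TorsionKey, ring_systems

log = logging.getLogger(__name__)

__all__ = [
    "TorsionRegion", "FragmentSpec", "FragmentationDecision",
    "decide_fragmentation", "partition_regions", "select_cleavage_bonds",
    "build_fragment", "plan_fragments", "PROTECTED_GROUP_PATTERNS",
]


@dataclass
class TorsionRegion:
    torsions: list[TorsionKey]
    atoms: set[int]                  # union of member quadruples
    central_bonds: set[tuple[int, int]]


@dataclass
class FragmentSpec:
    topology: MoleculeTopology
    conformation: Conformation       # seed coordinates inherited from parent
    atom_map: AtomMap
    cleaved_bonds: list[tuple[int, int]]   # parent-index bonds that were cut
    region: TorsionRegion
    # per cut: (cap C fragment index, inside parent index, outside parent
    # index, [cap H fragment indices]) - lets cap geometry be rebuilt from any
    # parent conformer
    cap_info: list[tuple[int, int, int, list[int]]] = field(default_factory=list)

    def map_quad(self, parent_quad) -> tuple[int, int, int, int]:
        return tuple(self.atom_map.to_fragment(a) for a in parent_quad)


@dataclass
class FragmentationDecision:
    fragment: bool
    n_regions: int
    rationale: str


# Protected functional groups as (elements, bonds-with-order) subgraph
# patterns; every bond between matched atoms is exempt from cleavage.  These
# operationalize the standard SMARTS inventory (amide C(=O)N, ester C(=O)OC,
# sulfonamide S(=O)(=O)N, nitro N(=O)O, carboxylate C(=O)O, guanidinium
# NC(=N)N) on bare topology graphs.
PROTECTED_GROUP_PATTERNS: dict[str, tuple[list[str], list[tuple[int, int, int]]]] = {
    "amide": (["C", "O", "N"], [(0, 1, 2), (0, 2, 1)]),
    "ester": (["C", "O", "O", "C"], [(0, 1, 2), (0, 2, 1), (2, 3, 1)]),
    "sulfonamide": (["S", "O", "O", "N"], [(0, 1, 2), (0, 2, 2), (0, 3, 1)]),
    "nitro": (["N", "O", "O"], [(0, 1, 2), (0, 2, 1)]),
    "carboxylate": (["C", "O", "O"], [(0, 1, 2), (0, 2, 1)]),
    "guanidinium": (["C", "N", "N", "N"], [(0, 1, 2), (0, 2, 1), (0, 3, 1)]),
}


def _protected_bonds(g: nx.Graph, patterns=PROTECTED_GROUP_PATTERNS) -> set:
    out = set()
    for name, (els, bonds) in patterns.items():
        pat = nx.Graph()
        for i, e in enumerate(els):
            pat.add_node(i, element=e)
        for i, j, order in bonds:
            pat.add_edge(i, j, order=order)
        gm = isomorphism.GraphMatcher(
            g, pat,
            node_match=lambda a, b: a.get("element") == b["element"],
            edge_match=lambda a, b: a.get("order", 1) == b["order"])
        for mapping in gm.subgraph_monomorphisms_iter():
            atoms = set(mapping)          # parent atoms matched to the pattern
            for i, j in g.edges(atoms):
                if i in atoms and j in atoms:
                    out.add((min(i, j), max(i, j)))
    return out


def partition_regions(significant: Sequence[TorsionKey],
                      graph: nx.Graph) -> list[TorsionRegion]:
    """Group significant torsions into regions: connected components of their
    central-bond edge set under shared-atom adjacency."""
    bonds = [t.central for t in significant]
    bg = nx.Graph()
    bg.add_nodes_from(range(len(bonds)))
    for a in range(len(bonds)):
        for b in range(a + 1, len(bonds)):
            if set(bonds[a]) & set(bonds[b]):
                bg.add_edge(a, b)
    regions = []
    for comp in nx.connected_components(bg):
        members = [significant[i] for i in sorted(comp)]
        atoms = set()
        for t in members:
            atoms.update(t.quad)
        regions.append(TorsionRegion(members, atoms,
                                     {t.central for t in members}))
    regions.sort(key=lambda r: min(r.atoms))
    return regions


def decide_fragmentation(topology: MoleculeTopology,
                         significant: Sequence[TorsionKey],
                         size_threshold: int = 35) -> FragmentationDecision:
    """Fragment when the torsions fall into two or more disconnected regions,
    or when the molecule is large and at least one region is localized to
    less than half of its heavy atoms."""
    regions = partition_regions(significant, topology.graph)
    n_heavy = len(topology.heavy_atoms())
    if not significant:
        return FragmentationDecision(False, 0, "no significant torsions")
    if len(regions) >= 2:
        d = FragmentationDecision(True, len(regions),
                                  f"{len(regions)} disconnected torsion regions")
    elif n_heavy > size_threshold and \
            any(len(r.atoms) < n_heavy / 2 for r in regions):
        d = FragmentationDecision(True, len(regions),
                                  f"{n_heavy} heavy atoms with a localized region")
    else:
        d = FragmentationDecision(False, len(regions),
                                  "single region covering the molecule")
    log.info("fragmentation decision: %s (%s)", d.fragment, d.rationale)
    return d


def _edge_distance(g: nx.Graph, bond, central) -> int:
    """Min over endpoint pairs of the shortest-path length (in bonds)."""
    return min(nx.shortest_path_length(g, a, b)
               for a in bond for b in central)


def select_cleavage_bonds(region: TorsionRegion, topology: MoleculeTopology,
                          patterns=PROTECTED_GROUP_PATTERNS
                          ) -> tuple[set[int], list[tuple[int, int]]]:
    """Grow the fragment outward from the region until every boundary bond is
    legal to cut; return (kept parent atoms, cleaved bonds).

    A bond is legal iff it is an acyclic single bond, outside the region's
    atom set, at least two bonds from every region central bond, not inside a
    protected functional group, and not touching a ring atom that carries an
    exocyclic double bond.  If no legal boundary exists the fragment is the
    whole molecule (no cleavage).
    """
    g = topology.graph
    rings = ring_systems(topology)
    ring_atoms = set().union(*rings) if rings else set()
    ring_edges = {(min(i, j), max(i, j)) for r in rings
                  for i, j in g.subgraph(r).edges}
    protected = _protected_bonds(g, patterns)
    exo_double = set()
    for i, j, data in g.edges(data=True):
        if data.get("order", 1) >= 2 and ((i in ring_atoms) ^ (j in ring_atoms)):
            exo_double.update((i, j))

    def legal(i, j):
        e = (min(i, j), max(i, j))
        if e in ring_edges or e in protected:
            return False
        if g.edges[i, j].get("order", 1) != 1:
            return False
        if set(e) & region.atoms:
            return False
        if set(e) & exo_double:
            return False
        return all(_edge_distance(g, e, c) >= 2 for c in region.central_bonds)

    keep = set(region.atoms)
    # grow to include every atom within two bonds of the region (the full 1-4
    # environment of its torsions), then push through illegal boundaries
    frontier = set(keep)
    for _ in range(2):
        frontier = {m for a in frontier for m in g.neighbors(a)} - keep
        keep |= frontier
    changed = True
    while changed:
        changed = False
        for i, j in list(nx.edge_boundary(g, keep)):
            inside, outside = (i, j) if i in keep else (j, i)
            if not legal(inside, outside):
                keep.add(outside)
                changed = True
    cleaved = sorted({(min(i, j), max(i, j))
                      for i, j in nx.edge_boundary(g, keep)})
    if len(keep) == g.number_of_nodes():
        cleaved = []
    return keep, cleaved


# generic parameters for cap atoms (methyl carbon + hydrogens)
_CAP_C = dict(atom_type="c3", charge=0.0, mass=12.01, lj_rmin_half=1.9,
              lj_epsilon=0.109)
_CAP_H = dict(atom_type="hc", charge=0.0, mass=1.008, lj_rmin_half=1.387,
              lj_epsilon=0.0157)
_CC = (300.0, 1.526)
_CH = (340.0, 1.09)


def _tetrahedral_hydrogens(c: np.ndarray, anchor: np.ndarray,
                           length: float = 1.09) -> list[np.ndarray]:
    """Three H positions completing a tetrahedron at cap carbon ``c`` whose
    existing substituent lies at ``anchor``."""
    axis = c - anchor
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for k in range(3):
        ang = np.deg2rad(120.0 * k)
        # 109.47 deg from the anchor direction
        direction = (np.cos(np.deg2rad(180.0 - 109.471)) * (-axis) +
                     np.sin(np.deg2rad(180.0 - 109.471)) *
                     (np.cos(ang) * u + np.sin(ang) * v))
        out.append(c + length * direction / np.linalg.norm(direction))
    return out


def build_fragment(region: TorsionRegion, topology: MoleculeTopology,
                   conformation: Conformation,
                   keep: set[int], cleaved: Sequence[tuple[int, int]],
                   fragment_id: str = "frag0") -> FragmentSpec:
    """Cut the cleavage bonds and complete each severed attachment point into
    a methyl group (1 C + 3 H per cut), inheriting parent coordinates and
    parameters for mapped atoms."""
    parent_atoms = sorted(keep)
    f_index = {p: i for i, p in enumerate(parent_atoms)}
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for p in parent_atoms:
        a = topology.atoms[p]
        atoms.append(AtomRecord(f_index[p], a.element, a.atom_type, a.charge,
                                a.mass, a.lj_rmin_half, a.lj_epsilon))
        coords.append(conformation.coordinates[p])
    bonds = [BondTerm(f_index[b.i], f_index[b.j], b.k_b, b.l0, b.order)
             for b in topology.bonds if b.i in keep and b.j in keep]
    caps: list[int] = []
    cap_info: list[tuple[int, int, int, list[int]]] = []
    for (i, j) in cleaved:
        inside, outside = (i, j) if i in keep else (j, i)
        if outside in keep:
            raise ValueError("cleaved bond does not cross the fragment boundary")
        # cap carbon along the severed bond direction at standard C-C length
        pi = conformation.coordinates[inside]
        po = conformation.coordinates[outside]
        direction = (po - pi) / np.linalg.norm(po - pi)
        c_pos = pi + _CC[1] * direction
        c_idx = len(atoms)
        atoms.append(AtomRecord(c_idx, "C", _CAP_C["atom_type"], 0.0,
                                _CAP_C["mass"], _CAP_C["lj_rmin_half"],
                                _CAP_C["lj_epsilon"]))
        coords.append(c_pos)
        caps.append(c_idx)
        bonds.append(BondTerm(f_index[inside], c_idx, *_CC))
        h_idxs = []
        for hpos in _tetrahedral_hydrogens(c_pos, pi):
            h_idx = len(atoms)
            atoms.append(AtomRecord(h_idx, "H", _CAP_H["atom_type"], 0.0,
                                    _CAP_H["mass"], _CAP_H["lj_rmin_half"],
                                    _CAP_H["lj_epsilon"]))
            coords.append(hpos)
            caps.append(h_idx)
            h_idxs.append(h_idx)
            bonds.append(BondTerm(c_idx, h_idx, *_CH))
        cap_info.append((c_idx, inside, outside, h_idxs))

    # rebuild angles/torsions/exclusions on the fragment graph, copying parent
    # parameters for fully mapped terms and generic ones for cap terms
    from .synthetic import build_topology as _assemble
    elements = [a.element for a in atoms]
    charges = [a.charge for a in atoms]
    bond_list = [(b.i, b.j, b.order) for b in bonds]
    generic = _assemble(elements, bond_list, charges)
    angle_params = {}
    for t in topology.angles:
        if all(x in keep for x in (t.i, t.j, t.k)):
            key = tuple(sorted((f_index[t.i], f_index[t.k]))) + (f_index[t.j],)
            angle_params[key] = (t.k_a, t.theta0)
    angles = []
    for t in generic.angles:
        key = tuple(sorted((t.i, t.k))) + (t.j,)
        if key in angle_params:
            angles.append(AngleTerm(t.i, t.j, t.k, *angle_params[key]))
        else:
            angles.append(t)
    torsion_params = {}
    for t in topology.torsions:
        if not t.is_improper and all(x in keep for x in t.quad):
            q = tuple(f_index[x] for x in t.quad)
            torsion_params[min(q, q[::-1])] = t
    torsions = []
    for t in generic.torsions:
        src = torsion_params.get(min(t.quad, t.quad[::-1]))
        if src is not None:
            torsions.append(TorsionTerm(t.quad, src.components, src.scee,
                                        src.scnb))
        else:
            torsions.append(t)
    # LJ/atom records must keep parent values: rebuild topology from parts
    frag_top = MoleculeTopology(atoms, bonds, angles, torsions,
                                generic.excluded_pairs, generic.pairs14)
    amap = AtomMap(fragment_id, [(f_index[p], p) for p in parent_atoms], caps)
    return FragmentSpec(frag_top, Conformation(np.array(coords)), amap,
                        list(cleaved), region, cap_info)


def fragment_coordinates(frag: FragmentSpec,
                         parent_conformation: Conformation) -> Conformation:
    """Fragment coordinates inherited from an arbitrary parent conformer:
    mapped atoms copy their parent positions, cap methyls are rebuilt along
    each severed bond."""
    n = frag.topology.n_atoms
    xyz = np.zeros((n, 3))
    for f, p in frag.atom_map.pairs:
        xyz[f] = parent_conformation.coordinates[p]
    for c_idx, inside, outside, h_idxs in frag.cap_info:
        pi = parent_conformation.coordinates[inside]
        po = parent_conformation.coordinates[outside]
        direction = (po - pi) / np.linalg.norm(po - pi)
        xyz[c_idx] = pi + _CC[1] * direction
        for h_idx, hpos in zip(h_idxs, _tetrahedral_hydrogens(xyz[c_idx], pi)):
            xyz[h_idx] = hpos
    return Conformation(xyz)


def plan_fragments(topology: MoleculeTopology, conformation: Conformation,
                   significant: Sequence[TorsionKey],
                   size_threshold: int = 35,
                   patterns=PROTECTED_GROUP_PATTERNS) -> list[FragmentSpec]:
    """Full fragmentation pass: decide, partition, cleave, cap.  Returns an
    empty list when fragmentation is not warranted."""
    decision = decide_fragmentation(topology, significant, size_threshold)
    if not decision.fragment:
        return []
    out = []
    for ri, region in enumerate(partition_regions(significant, topology.graph)):
        keep, cleaved = select_cleavage_bonds(region, topology, patterns)
        out.append(build_fragment(region, topology, conformation, keep,
                                  cleaved, fragment_id=f"frag{ri}"))
    return out
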