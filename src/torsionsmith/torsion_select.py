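"""Candidate-torsion enumeration, dispersion screening, and pruning.

A torsion is worth refitting when its dihedral actually varies across the
retained conformer centroids (wrapped dispersion above a cutoff, default
30 degrees) and it survives chemically motivated pruning: torsions involving
terminal atoms are quasi-free rotors, torsions contained in rings are
conformationally constrained, and multiple definitions on one central bond
are collapsed to the most backbone-like one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .ffcore import Conformation, MoleculeTopology, dihedral_angle, wrap_angle

__all__ = [
    "TorsionKey", "enumerate_candidates", "wrapped_dispersion",
    "longest_heavy_chain", "prune", "backbone_connected", "ring_systems",
]


@dataclass(frozen=True)
class TorsionKey:
    quad: tuple[int, int, int, int]
    central: tuple[int, int]            # (j, k) as a sorted bond
    type_quad: tuple[str, str, str, str]
    backbone_depth: int = 0

    @property
    def canonical(self):
        return min(self.quad, self.quad[::-1])


def _terminal_heavy_atoms(g: nx.Graph) -> set[int]:
    """Heavy atoms with at most one heavy neighbour."""
    heavy = {n for n, d in g.nodes(data=True) if d.get("element", "C") != "H"}
    out = set()
    for n in heavy:
        if sum(1 for m in g.neighbors(n) if m in heavy) <= 1:
            out.add(n)
    return out


def _backbone_depth(g: nx.Graph, quad) -> int:
    """Depth of a torsion in the heavy-atom framework: min over its two outer
    atoms of the graph distance to the nearest terminal heavy atom (larger =
    deeper = more backbone-like)."""
    terminals = _terminal_heavy_atoms(g)
    if not terminals:
        return g.number_of_nodes()
    depths = []
    for a in (quad[0], quad[3]):
        lengths = nx.single_source_shortest_path_length(g, a)
        depths.append(min((lengths[t] for t in terminals if t in lengths),
                          default=g.number_of_nodes()))
    return min(depths)


def enumerate_candidates(topology: MoleculeTopology) -> list[TorsionKey]:
    """Every bonded path i-j-k-l, one canonical orientation each."""
    g = topology.graph
    seen = set()
    out = []
    for j, k in g.edges:
        for jj, kk in ((j, k), (k, j)):
            for i in g.neighbors(jj):
                if i == kk:
                    continue
                for l in g.neighbors(kk):
                    if l == jj or l == i:
                        continue
                    quad = (i, jj, kk, l)
                    if quad[::-1] in seen or quad in seen:
                        continue
                    seen.add(quad)
                    tq = tuple(topology.atoms[a].atom_type for a in quad)
                    if tq[::-1] < tq:
                        quad, tq = quad[::-1], tq[::-1]
                    out.append(TorsionKey(quad, (min(jj, kk), max(jj, kk)), tq,
                                          _backbone_depth(g, quad)))
    return sorted(out, key=lambda t: t.quad)


def wrapped_dispersion(centroid_conformations: Sequence[Conformation],
                       key: TorsionKey | Sequence[int]) -> float:
    """Max over centroid pairs of the wrapped angular difference
    d(a, b) = |((a - b + 180) mod 360) - 180|, in degrees."""
    quad = key.quad if isinstance(key, TorsionKey) else tuple(key)
    angles = [dihedral_angle(c, quad) for c in centroid_conformations]
    if len(angles) < 2:
        return 0.0
    return float(max(abs(wrap_angle(a - b))
                     for a, b in combinations(angles, 2)))


def longest_heavy_chain(topology: MoleculeTopology) -> list[int]:
    """A longest simple path on the heavy-atom subgraph, exhaustively searched;
    ties broken by the lexicographically smallest index sequence (each path is
    first canonicalized against its own reversal)."""
    heavy = topology.heavy_atoms()
    g = topology.graph.subgraph(heavy)
    best: list[int] = []

    def consider(path):
        nonlocal best
        cand = min(path, path[::-1])
        if len(cand) > len(best) or (len(cand) == len(best) and cand < best):
            best = list(cand)

    def dfs(path, visited):
        consider(path)
        for nxt in sorted(g.neighbors(path[-1])):
            if nxt not in visited:
                dfs(path + [nxt], visited | {nxt})

    for start in sorted(g.nodes):
        dfs([start], {start})
    return best


def ring_systems(topology: MoleculeTopology) -> list[set[int]]:
    """Smallest set of smallest rings (via networkx minimum cycle basis) on
    the full molecular graph, as atom sets."""
    return [set(c) for c in nx.minimum_cycle_basis(topology.graph)]


def _in_ring(rings, torsion: TorsionKey, ring_edges) -> bool:
    """A torsion is contained in a ring when its central bond is a ring bond
    or some single smallest ring holds all four atoms."""
    if torsion.central in ring_edges:
        return True
    qs = set(torsion.quad)
    return any(qs <= r for r in rings)


def prune(topology: MoleculeTopology, candidates: Sequence[TorsionKey],
          dispersions: dict, cutoff: float = 30.0,
          exclude_terminal: bool = True, exclude_ring: bool = True
          ) -> list[TorsionKey]:
    """Reduce candidates to the significant-torsion list.

    Keeps candidates whose dispersion strictly exceeds ``cutoff``; then drops
    terminal-atom torsions (an outer atom is hydrogen or a heavy atom with a
    single heavy neighbour), drops ring-contained torsions, and per central
    bond keeps only the highest ``backbone_depth`` survivor (ties to the
    lower canonical quad).  Output order is canonical and independent of the
    input ordering.
    """
    g = topology.graph
    keep = [c for c in candidates
            if dispersions[c.canonical] > cutoff]
    if exclude_terminal:
        terminals = _terminal_heavy_atoms(g)
        elements = {a.index: a.element for a in topology.atoms}

        def is_term(a):
            return elements[a] == "H" or a in terminals
        keep = [c for c in keep if not (is_term(c.quad[0]) or is_term(c.quad[3]))]
    if exclude_ring:
        rings = ring_systems(topology)
        ring_edges = set()
        for r in rings:
            for i, j in g.edges(r):
                if i in r and j in r:
                    ring_edges.add((min(i, j), max(i, j)))
        keep = [c for c in keep if not _in_ring(rings, c, ring_edges)]
    by_bond: dict = {}
    for c in keep:
        cur = by_bond.get(c.central)
        if cur is None or (-c.backbone_depth, c.canonical) < \
                          (-cur.backbone_depth, cur.canonical):
            by_bond[c.central] = c
    return sorted(by_bond.values(), key=lambda t: t.quad)


def backbone_connected(significant: Sequence[TorsionKey],
                       chain: Sequence[int]) -> list[TorsionKey]:
    """Torsions whose central bond is an edge of the longest heavy chain."""
    edges = {(min(a, b), max(a, b)) for a, b in zip(chain, chain[1:])}
    return [t for t in significant if t.central in edges]
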