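"""Torsion selection: candidate enumeration against a brute-force path
oracle, wrapped dispersion, longest-chain search, and pruning heuristics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from torsionsmith.ffcore import Conformation, wrap_angle
from torsionsmith.synthetic import build_topology, zigzag_chain
from torsionsmith.torsion_select import (TorsionKey, backbone_connected,
                                         enumerate_candidates,
                                         longest_heavy_chain, prune,
                                         wrapped_dispersion)


def _count_paths3(g):
    """Brute force: simple paths with exactly 3 edges, up to reversal."""
    seen = set()
    for quad in itertools.permutations(g.nodes, 4):
        if all(g.has_edge(a, b) for a, b in zip(quad, quad[1:])):
            seen.add(min(quad, quad[::-1]))
    return len(seen)


class TestEnumerate:
    def test_hexane_backbone_candidate_present(self, butane):
        quads = {t.canonical for t in enumerate_candidates(butane.topology)}
        assert (1, 2, 3, 4) in quads or (4, 3, 2, 1) in quads

    def test_ethane_like_hydrogens(self):
        # H3C-CH3: only H-C-C-H candidates
        elements = ["C", "C"] + ["H"] * 6
        bonds = [(0, 1)] + [(0, i) for i in (2, 3, 4)] + \
                [(1, i) for i in (5, 6, 7)]
        top = build_topology(elements, bonds)
        cands = enumerate_candidates(top)
        assert len(cands) == 9
        assert all(top.atoms[t.quad[0]].element == "H" and
                   top.atoms[t.quad[3]].element == "H" for t in cands)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        g = nx.gnp_random_graph(n, 0.35, seed=seed)
        while not nx.is_connected(g):
            seed += 100
            g = nx.gnp_random_graph(n, 0.45, seed=seed)
        top = build_topology(["C"] * n, [(i, j) for i, j in g.edges])
        assert len(enumerate_candidates(top)) == _count_paths3(g)


class TestWrappedDispersion:
    def _confs_with_angles(self, butane, angles):
        from torsionsmith.ffcore import set_dihedral
        return [set_dihedral(butane.topology, butane.conformations[0],
                             (1, 2, 3, 4), a) for a in angles]

    def test_wrap_symmetry(self, butane):
        confs = self._confs_with_angles(butane, [170.0, -170.0])
        assert wrapped_dispersion(confs, (1, 2, 3, 4)) == pytest.approx(20.0,
                                                                       abs=1e-6)

    def test_antipodal(self, butane):
        confs = self._confs_with_angles(butane, [0.0, 180.0])
        assert wrapped_dispersion(confs, (1, 2, 3, 4)) == pytest.approx(180.0,
                                                                        abs=1e-6)

    def test_single_centroid_zero(self, butane):
        assert wrapped_dispersion(butane.conformations[:1], (1, 2, 3, 4)) == 0.0

    @given(angles=st.lists(st.floats(-180.0, 180.0), min_size=2, max_size=6))
    def test_matches_pairwise_loop(self, fixtures, angles):
        butane = fixtures["butane_like"]
        confs = self._confs_with_angles(butane, angles)
        got = wrapped_dispersion(confs, (1, 2, 3, 4))
        oracle = 0.0
        for a, b in itertools.combinations(angles, 2):
            oracle = max(oracle, abs(((a - b + 180.0) % 360.0) - 180.0))
        assert got == pytest.approx(oracle, abs=1e-6)


def _exhaustive_longest_path(g):
    best = []
    for n_len in range(g.number_of_nodes(), 0, -1):
        paths = []
        for quad in itertools.permutations(g.nodes, n_len):
            if all(g.has_edge(a, b) for a, b in zip(quad, quad[1:])):
                paths.append(min(list(quad), list(quad[::-1])))
        if paths:
            return sorted(paths)[0]
    return best


class TestLongestChain:
    def test_linear_chain(self):
        top = build_topology(["C"] * 5, [(i, i + 1) for i in range(4)])
        assert longest_heavy_chain(top) == [0, 1, 2, 3, 4]

    def test_hydrogens_excluded(self):
        elements = ["C", "C", "C", "H", "H"]
        bonds = [(0, 1), (1, 2), (0, 3), (2, 4)]
        top = build_topology(elements, bonds)
        assert longest_heavy_chain(top) == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        g = nx.random_labeled_tree(8, seed=seed)
        top = build_topology(["C"] * 8, [(i, j) for i, j in g.edges])
        assert longest_heavy_chain(top) == _exhaustive_longest_path(g)

    def test_ring_molecule_matches_oracle(self, fixtures):
        top = fixtures["rigid_ring"].topology
        assert longest_heavy_chain(top) == \
            _exhaustive_longest_path(top.graph)


class TestPrune:
    def _run(self, fx, cutoff=30.0, **kw):
        cands = enumerate_candidates(fx.topology)
        disp = {c.canonical: wrapped_dispersion(fx.conformations, c)
                for c in cands}
        return cands, disp, prune(fx.topology, cands, disp, cutoff, **kw)

    def test_boundary_dispersion_excluded(self, butane):
        cands = enumerate_candidates(butane.topology)
        disp = {c.canonical: 30.0 for c in cands}   # exactly at the cutoff
        assert prune(butane.topology, cands, disp, 30.0) == []

    def test_ring_torsions_excluded(self, fixtures):
        _, disp, sig = self._run(fixtures["rigid_ring"])
        assert sig == []

    def test_biphenyl_inter_ring_survives(self, fixtures):
        _, _, sig = self._run(fixtures["biphenyl_like"])
        assert [t.canonical for t in sig] == [(1, 0, 6, 7)]

    def test_terminal_exclusion_flag(self, butane):
        cands = enumerate_candidates(butane.topology)
        disp = {c.canonical: 90.0 for c in cands}
        with_excl = prune(butane.topology, cands, disp, 30.0)
        without = prune(butane.topology, cands, disp, 30.0,
                        exclude_terminal=False)
        assert len(without) > len(with_excl)

    def test_one_torsion_per_central_bond(self, fixtures):
        fx = fixtures["amide_chain"]
        cands = enumerate_candidates(fx.topology)
        disp = {c.canonical: 90.0 for c in cands}
        sig = prune(fx.topology, cands, disp, 30.0)
        bonds = [t.central for t in sig]
        assert len(bonds) == len(set(bonds))

    def test_monotone_in_cutoff(self, fixtures):
        fx = fixtures["two_region"]
        cands = enumerate_candidates(fx.topology)
        disp = {c.canonical: wrapped_dispersion(fx.conformations, c)
                for c in cands}
        prev = None
        for cutoff in (10.0, 30.0, 60.0, 120.0, 179.0):
            cur = {t.canonical for t in prune(fx.topology, cands, disp, cutoff)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_order_independence(self, fixtures):
        fx = fixtures["two_region"]
        cands = enumerate_candidates(fx.topology)
        disp = {c.canonical: wrapped_dispersion(fx.conformations, c)
                for c in cands}
        a = prune(fx.topology, cands, disp)
        b = prune(fx.topology, list(reversed(cands)), disp)
        assert [t.quad for t in a] == [t.quad for t in b]

    def test_central_bonds_rotatable(self, fixtures):
        for name in ("butane_like", "biphenyl_like", "amide_chain",
                     "two_region"):
            fx = fixtures[name]
            cands = enumerate_candidates(fx.topology)
            disp = {c.canonical: wrapped_dispersion(fx.conformations, c)
                    for c in cands}
            from torsionsmith.torsion_select import ring_systems
            rings = ring_systems(fx.topology)
            ring_edges = {(min(i, j), max(i, j)) for r in rings
                          for i, j in fx.topology.graph.subgraph(r).edges}
            for t in prune(fx.topology, cands, disp):
                assert t.central not in ring_edges


class TestBackboneConnected:
    def test_chain_edge_included_side_chain_excluded(self):
        # chain 0-1-2-3-4 with a branch 2-5-6-7
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6), (6, 7)]
        top = build_topology(["C"] * 8, bonds)
        chain = longest_heavy_chain(top)
        on = TorsionKey((0, 1, 2, 3), (1, 2), ("cx",) * 4)
        off = TorsionKey((2, 5, 6, 7), (5, 6), ("cx",) * 4)
        got = backbone_connected([on, off], chain)
        edges = {(min(a, b), max(a, b)) for a, b in zip(chain, chain[1:])}
        assert [t.quad for t in got] == \
            [t.quad for t in (on, off) if t.central in edges]
        assert on in got
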