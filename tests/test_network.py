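"""Hydrogen-bond detection and network assembly against brute-force oracles."""

import math

import numpy as np
import pytest

from aquanet.network import (ConfigurationError, HBondCriteria, build_network,
                             build_networks, detect_hbonds, find_candidate_pairs)
from aquanet.fixtures import water_pair_structure
from aquanet.structure_io import Atom, Structure

from conftest import brute_force_hbond_edges, random_hydration_structure, waters_structure


def _edge_set(net):
    return {(min(u, v), max(u, v)) for u, v in net.graph.edges()}


class TestCandidatePairs:
    def test_two_close_waters_paired(self):
        s = waters_structure([[0, 0, 0], [3, 0, 0]])
        pairs = find_candidate_pairs(s, HBondCriteria())
        assert pairs == {(1, 2)}

    def test_isolated_water_yields_no_edges(self):
        s = waters_structure([[0, 0, 0], [20, 0, 0]])
        net = build_network(s)
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 2  # isolated waters stay as nodes

    def test_neighbor_k_caps_equidistant_partners(self):
        # 12 protein acceptors on a circle, all 4 Å from a central water;
        # only the water queries the tree, so its candidate list is capped
        atoms = [Atom(1, "O", "O", "HOH", 1, "W", [0.0, 0.0, 0.0], is_water=True)]
        for i in range(12):
            ang = 2 * math.pi * i / 12
            atoms.append(Atom(i + 2, "O", "O", "SER", i + 1, "A",
                              [4 * math.cos(ang), 4 * math.sin(ang), 0.0]))
        s = Structure("ring", atoms)
        pairs = find_candidate_pairs(s, HBondCriteria(neighbor_k=10))
        assert len(pairs) == 10
        assert all(1 in p for p in pairs)

    def test_equals_brute_force_when_under_k(self, rng):
        crit = HBondCriteria()
        for _ in range(20):
            s = random_hydration_structure(rng)
            assert _edge_set(build_network(s, crit)) == brute_force_hbond_edges(s, crit)


class TestDetectHbonds:
    def test_distance_pass_and_fail(self):
        assert len(detect_hbonds(waters_structure([[0, 0, 0], [3, 0, 0]]),
                                 HBondCriteria())) == 1
        assert len(detect_hbonds(waters_structure([[0, 0, 0], [4.5, 0, 0]]),
                                 HBondCriteria())) == 0

    def test_angle_rejects_bent_geometry(self):
        s = water_pair_structure(2.9, with_hydrogens=True, dha_angle=120.0)
        assert detect_hbonds(s, HBondCriteria()) == []
        s2 = water_pair_structure(2.9, with_hydrogens=True, dha_angle=165.0)
        bonds = detect_hbonds(s2, HBondCriteria())
        assert len(bonds) == 1
        assert bonds[0].dha_angle == pytest.approx(165.0, abs=0.5)
        assert bonds[0].donor_serial == 1

    def test_angle_requested_without_hydrogens(self):
        s = waters_structure([[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ConfigurationError):
            detect_hbonds(s, HBondCriteria(use_angle=True))

    def test_protein_site_assignment(self):
        water = Atom(1, "O", "O", "HOH", 1, "W", [0, 0, 0], is_water=True)
        backbone = Atom(2, "O", "O", "SER", 1, "A", [3, 0, 0])
        sidechain = Atom(3, "OG", "O", "SER", 2, "A", [0, 3, 0])
        s = Structure("x", [water, backbone, sidechain])
        sites = {(b.atom_a.serial, b.atom_b.serial): b.protein_site
                 for b in detect_hbonds(s, HBondCriteria())}
        assert sites[(1, 2)] == "backbone"
        assert sites[(1, 3)] == "side-chain"

    def test_carbon_never_a_partner(self):
        water = Atom(1, "O", "O", "HOH", 1, "W", [0, 0, 0], is_water=True)
        carbon = Atom(2, "CA", "C", "SER", 1, "A", [3, 0, 0])
        s = Structure("x", [water, carbon])
        assert detect_hbonds(s, HBondCriteria()) == []


class TestBuildNetwork:
    def test_three_waters_in_line_form_path(self):
        s = waters_structure([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        net = build_network(s)
        assert _edge_set(net) == {(1, 2), (2, 3)}

    def test_water_water_mode_keeps_water_node_without_edges(self):
        water = Atom(1, "O", "O", "HOH", 1, "W", [0, 0, 0], is_water=True)
        prot = Atom(2, "OG", "O", "SER", 1, "A", [3, 0, 0])
        s = Structure("x", [water, prot])
        net = build_network(s, mode="water-water")
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_mode_union_equals_full(self, rng):
        for _ in range(10):
            s = random_hydration_structure(rng)
            full = _edge_set(build_network(s, mode="full"))
            ww = _edge_set(build_network(s, mode="water-water"))
            wp = _edge_set(build_network(s, mode="water-protein"))
            assert ww | wp == full
            assert ww & wp == set()

    def test_distance_monotonicity(self, rng):
        for _ in range(10):
            s = random_hydration_structure(rng)
            small = _edge_set(build_network(s, HBondCriteria(distance_cutoff=3.0)))
            large = _edge_set(build_network(s, HBondCriteria(distance_cutoff=4.5)))
            assert small <= large

    def test_angle_monotonicity(self):
        for ang in (120.0, 140.0, 160.0):
            s = water_pair_structure(2.9, with_hydrogens=True, dha_angle=ang)
            strict = _edge_set(build_network(s, HBondCriteria(angle_cutoff=155.0)))
            loose = _edge_set(build_network(s, HBondCriteria(angle_cutoff=115.0)))
            assert strict <= loose

    def test_deterministic_and_worker_independent(self, rng):
        structures = [random_hydration_structure(rng) for _ in range(4)]
        serial_nets = build_networks(structures, n_jobs=1)
        parallel_nets = build_networks(structures, n_jobs=2)
        for a, b in zip(serial_nets, parallel_nets):
            assert _edge_set(a) == _edge_set(b)
            assert set(a.graph.nodes) == set(b.graph.nodes)

    def test_region_halo_keeps_boundary_bonds(self):
        # center water inside the region, partner water just outside
        atoms = [Atom(1, "CA", "C", "SER", 1, "A", [0, 0, 0])]
        atoms += [Atom(2, "O", "O", "HOH", 1, "W", [8.0, 0, 0], is_water=True),
                  Atom(3, "O", "O", "HOH", 2, "W", [10.5, 0, 0], is_water=True),
                  Atom(4, "O", "O", "HOH", 3, "W", [20.0, 0, 0], is_water=True)]
        s = Structure("halo", atoms)
        from aquanet.structure_io import ActiveRegion
        net = build_network(s, region=ActiveRegion(selection="protein", radius=9.0))
        assert (2, 3) in _edge_set(net)       # boundary bond retained
        assert 4 not in net.graph.nodes        # far water dropped

    def test_directed_orientation_donor_to_acceptor(self):
        s = water_pair_structure(2.9, with_hydrogens=True, dha_angle=175.0)
        net = build_network(s)
        assert net.directed
        assert list(net.graph.edges()) == [(1, 2)]  # water 1 donates
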