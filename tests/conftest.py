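"""Shared fixtures: tiny structures and brute-force reference implementations."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from aquanet.network import HBondCriteria, is_protein_partner
from aquanet.structure_io import Atom, Structure


def make_water(serial: int, resnum: int, coords, hydrogens=()) -> list[Atom]:
    atoms = [Atom(serial, "O", "O", "HOH", resnum, "W", np.asarray(coords, float),
                  is_water=True)]
    for i, h in enumerate(hydrogens, start=1):
        atoms.append(Atom(serial + i, f"H{i}", "H", "HOH", resnum, "W",
                          np.asarray(h, float), is_water=True, is_hydrogen=True))
    return atoms


def waters_structure(positions, structure_id="waters") -> Structure:
    """Structure of bare water oxygens at the given positions."""
    atoms = []
    for i, p in enumerate(positions):
        atoms.extend(make_water(i + 1, i + 1, p))
    return Structure(structure_id, atoms, source="static")


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the library code paths they check)
# ---------------------------------------------------------------------------

def brute_force_hbond_edges(structure: Structure, criteria: HBondCriteria,
                            mode: str = "full") -> set[tuple[int, int]]:
    """Exhaustive O(n²) pairwise H-bond test over the candidate pool."""
    pool = [a for a in structure.atoms
            if (a.is_water and not a.is_hydrogen and a.element == "O")
            or is_protein_partner(a)]
    use_angle = criteria.resolved_use_angle(structure)
    edges: set[tuple[int, int]] = set()
    for a, b in itertools.combinations(pool, 2):
        if not (a.is_water or b.is_water):
            continue
        if np.linalg.norm(a.coords - b.coords) > criteria.distance_cutoff:
            continue
        kind = "water-water" if (a.is_water and b.is_water) else "water-protein"
        if mode != "full" and kind != mode:
            continue
        if use_angle:
            passed = False
            for donor, acceptor in ((a, b), (b, a)):
                hs = [h for h in structure.atoms
                      if h.is_hydrogen and h.residue_key == donor.residue_key
                      and h.is_water == donor.is_water]
                for h in hs:
                    v1 = donor.coords - h.coords
                    v2 = acceptor.coords - h.coords
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                    if ang >= criteria.angle_cutoff:
                        passed = True
            if not passed:
                continue
        edges.add((min(a.serial, b.serial), max(a.serial, b.serial)))
    return edges


def bfs_all_pairs(graph: nx.Graph) -> dict:
    """All-pairs shortest hop counts by explicit breadth-first search."""
    out = {}
    for src in graph.nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[src] = dist
    return out


def brute_force_metrics(graph: nx.Graph) -> dict:
    """Density, entropy and CPLs from first principles (undirected graphs)."""
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    density = 0.0 if n < 2 else 2 * e / (n * (n - 1))

    degs = [d for _, d in graph.degree()]
    entropy = 0.0
    if n:
        for k in set(degs):
            p = degs.count(k) / n
            entropy -= p * math.log(p)

    dist = bfs_all_pairs(graph)
    comps = []
    seen = set()
    for node in graph.nodes:
        if node in seen:
            continue
        comp = set(dist[node])
        seen |= comp
        comps.append(comp)
    cpls = []
    comp_meta = []
    for comp in comps:
        if len(comp) < 2:
            continue
        pair_dists = [dist[u][v] for u in comp for v in comp if u != v]
        cpl = sum(pair_dists) / len(pair_dists)
        cpls.append(cpl)
        n_edges = sum(1 for u, v in graph.edges if u in comp)
        comp_meta.append((len(comp), n_edges, min(comp), cpl))
    cpl_mean = sum(cpls) / len(cpls) if cpls else None
    cpl_largest = None
    if comp_meta:
        comp_meta.sort(key=lambda m: (-m[0], -m[1], m[2]))
        cpl_largest = comp_meta[0][3]
    return {"density": density, "entropy": entropy, "cpl_mean": cpl_mean,
            "cpl_largest": cpl_largest, "n_components": len(comps)}


def random_hydration_structure(rng: np.random.Generator,
                               n_waters: int | None = None,
                               box: float = 25.0,
                               n_residues: int = 4) -> Structure:
    """Random small protein + waters fixture for oracle-equivalence checks.

    The box is large enough that a water rarely has more than a handful of
    partners inside the default cutoff, keeping the k-nearest candidate
    search exhaustive.
    """
    from aquanet.fixtures import protein_template

    n_waters = int(rng.integers(5, 30)) if n_waters is None else n_waters
    atoms = [Atom(a.serial, a.name, a.element, a.residue_name, a.residue_number,
                  a.chain, a.coords + np.array([box / 2 - 3, box / 2, box / 2]))
             for a in protein_template(n_residues)]
    serial = len(atoms) + 1
    for i in range(n_waters):
        pos = rng.uniform(0, box, size=3)
        atoms.append(Atom(serial, "O", "O", "HOH", i + 1, "W", pos, is_water=True))
        serial += 1
    return Structure("random", atoms, source="static")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
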