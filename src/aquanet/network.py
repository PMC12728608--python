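"""Hydrogen-bond detection and water-network graph construction.

A hydrogen bond is a donor–acceptor heavy-atom pair within a distance cutoff
(default 3.8 Å) which, when hydrogen positions are available, also satisfies a
donor–hydrogen–acceptor angle cutoff (default 150°).  Candidate pairs are
found with a k-d tree: each water oxygen is tested against its ``neighbor_k``
(default 10) nearest candidate partners, which keeps network construction
linear in the number of waters while remaining exact whenever no water has
more than ``neighbor_k`` partners inside the cutoff.

Networks are water-centric: edges always involve at least one water oxygen;
protein–protein pairs are never tested.  Protein partners are restricted to
the conventional donor/acceptor heavy atoms (N and O of any residue, plus the
S of Cys/Met).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ActiveRegion, Atom, Structure

__all__ = [
    "HBondCriteria",
    "Interaction",
    "WaterNetwork",
    "ConfigurationError",
    "find_candidate_pairs",
    "detect_hbonds",
    "build_network",
    "dha_angle",
]

#: Residues whose sulfur counts as an H-bond acceptor.
_SULFUR_RESIDUES = frozenset({"CYS", "MET"})
#: Backbone atom names; everything else on a protein residue is side-chain.
_BACKBONE_NAMES = frozenset({"N", "O", "OXT"})


class ConfigurationError(Exception):
    pass


@dataclass
class HBondCriteria:
    """Distance/angle cutoffs and neighbor count defining a hydrogen bond.

    ``use_angle=None`` means auto: the angle test is applied when the
    structure carries water hydrogens.
    """

    distance_cutoff: float = 3.8   # Å, donor–acceptor heavy atoms
    angle_cutoff: float = 150.0    # degrees, D–H···A at the hydrogen
    use_angle: bool | None = None
    neighbor_k: int = 10

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle_cutoff must be in (0, 180]")
        if self.neighbor_k < 1:
            raise ValueError("neighbor_k must be >= 1")

    def resolved_use_angle(self, structure: Structure) -> bool:
        if self.use_angle is None:
            return structure.has_hydrogens
        return self.use_angle


@dataclass
class Interaction:
    """One hydrogen bond between two heavy atoms."""

    atom_a: Atom
    atom_b: Atom
    kind: str                      # "water-water" | "water-protein"
    distance: float                # Å
    dha_angle: float | None = None  # degrees, best passing D–H···A
    donor_serial: int | None = None  # set when hydrogens resolved the direction
    protein_site: str | None = None  # "backbone" | "side-chain" for the protein partner


@dataclass
class WaterNetwork:
    """A graph of water (and optionally protein) atoms joined by H-bonds.

    Node keys are atom serials; node attributes carry coordinates and
    identity, edge attributes the interaction geometry.  Directed graphs
    orient edges donor → acceptor and exist only when hydrogens resolved
    the direction.
    """

    graph: nx.Graph
    mode: str                      # "water-water" | "water-protein" | "full"
    directed: bool
    structure_id: str
    frame_index: int | None = None
    interactions: list[Interaction] = field(default_factory=list)
    atoms: dict[int, Atom] = field(default_factory=dict)

    @property
    def n_ww_interactions(self) -> int:
        return sum(1 for i in self.interactions if i.kind == "water-water")

    @property
    def n_wp_interactions(self) -> int:
        return sum(1 for i in self.interactions if i.kind == "water-protein")

    @property
    def unit(self) -> tuple[str, int | None]:
        """The (structure, frame) identity this network represents."""
        return (self.structure_id, self.frame_index)

    def water_positions(self) -> np.ndarray:
        """(n, 3) coordinates of the water-oxygen nodes."""
        pts = [a.coords for a in self.atoms.values()
               if a.is_water and not a.is_hydrogen]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def water_serials(self) -> list[int]:
        return [s for s, a in self.atoms.items() if a.is_water and not a.is_hydrogen]


def is_protein_partner(atom: Atom) -> bool:
    """True for protein heavy atoms that can donate or accept an H-bond."""
    if atom.is_water or atom.is_hydrogen:
        return False
    if atom.element in ("N", "O"):
        return True
    return atom.element == "S" and atom.residue_name.upper() in _SULFUR_RESIDUES


def protein_site_of(atom: Atom) -> str:
    return "backbone" if atom.name.strip().upper() in _BACKBONE_NAMES else "side-chain"


def _candidate_pool(structure: Structure) -> list[Atom]:
    pool = list(structure.water_oxygens)
    pool.extend(a for a in structure.atoms if is_protein_partner(a))
    return pool


def find_candidate_pairs(structure: Structure,
                         criteria: HBondCriteria) -> set[tuple[int, int]]:
    """Nearest-neighbor candidate pairs for every water oxygen.

    For each water oxygen the ``neighbor_k`` nearest atoms of the combined
    candidate pool (other water oxygens plus protein donor/acceptor heavy
    atoms) are paired with it.  Pairs are deduplicated and returned as sorted
    serial tuples; no distance cutoff is applied here.
    """
    if not structure.atoms:
        raise ValueError("structure is empty")
    pool = _candidate_pool(structure)
    if len(pool) < 2:
        return set()
    coords = np.array([a.coords for a in pool])
    tree = cKDTree(coords)
    waters = [i for i, a in enumerate(pool) if a.is_water]
    k = min(criteria.neighbor_k + 1, len(pool))
    pairs: set[tuple[int, int]] = set()
    for wi in waters:
        dists, idx = tree.query(coords[wi], k=k)
        idx = np.atleast_1d(idx)
        partners = [j for j in idx.tolist() if j != wi][: criteria.neighbor_k]
        for j in partners:
            a, b = pool[wi].serial, pool[j].serial
            pairs.add((a, b) if a < b else (b, a))
    return pairs


def dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    """Donor–hydrogen–acceptor angle in degrees, measured at the hydrogen."""
    v1 = np.asarray(donor, float) - np.asarray(hydrogen, float)
    v2 = np.asarray(acceptor, float) - np.asarray(hydrogen, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate D–H–A geometry")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _angle_test(structure: Structure, a: Atom, b: Atom,
                cutoff: float) -> tuple[bool, float | None, int | None]:
    """Try both donor directions; accept if any D–H···A passes the cutoff.

    Returns (passed, best angle, donor serial).  Only partners with explicit
    hydrogens can act as donor; when both directions pass, the partner with
    the lower serial donates.
    """
    best: dict[int, float] = {}
    for donor, acceptor in ((a, b), (b, a)):
        hydrogens = structure.water_hydrogens_of(donor) if donor.is_water else [
            h for h in structure.atoms
            if h.is_hydrogen and not h.is_water and h.residue_key == donor.residue_key
            and np.linalg.norm(h.coords - donor.coords) < 1.3]
        for h in hydrogens:
            ang = dha_angle(donor.coords, h.coords, acceptor.coords)
            if ang >= cutoff:
                best[donor.serial] = max(best.get(donor.serial, 0.0), ang)
    if not best:
        return False, None, None
    donor_serial = min(best)  # lower serial donates on ties
    return True, best[donor_serial], donor_serial


def detect_hbonds(structure: Structure, criteria: HBondCriteria,
                  mode: str = "full") -> list[Interaction]:
    """All hydrogen bonds of a structure under the given criteria.

    Distance is tested on donor–acceptor heavy atoms; the angle test is
    applied when hydrogens are available (``use_angle``).  ``mode`` restricts
    the interaction kinds returned.
    """
    if mode not in ("water-water", "water-protein", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    use_angle = criteria.resolved_use_angle(structure)
    if use_angle and not structure.has_hydrogens:
        raise ConfigurationError("angle criterion requested but no water hydrogens present")

    by_serial = {a.serial: a for a in structure.atoms}
    out: list[Interaction] = []
    for sa, sb in sorted(find_candidate_pairs(structure, criteria)):
        a, b = by_serial[sa], by_serial[sb]
        kind = "water-water" if (a.is_water and b.is_water) else "water-protein"
        if mode == "water-water" and kind != "water-water":
            continue
        if mode == "water-protein" and kind != "water-protein":
            continue
        dist = a.distance_to(b)
        if dist > criteria.distance_cutoff:
            continue
        angle = None
        donor_serial = None
        if use_angle:
            ok, angle, donor_serial = _angle_test(structure, a, b, criteria.angle_cutoff)
            if not ok:
                continue
        site = None
        if kind == "water-protein":
            site = protein_site_of(b if a.is_water else a)
        out.append(Interaction(a, b, kind, dist, angle, donor_serial, site))
    return out


def build_network(structure: Structure, criteria: HBondCriteria | None = None,
                  mode: str = "full", region: ActiveRegion | None = None) -> WaterNetwork:
    """Assemble the water network graph of one structure or frame.

    With an active region, edges are kept when at least one endpoint is a
    water oxygen inside the region sphere; partners just outside the sphere
    are retained so boundary bonds are not lost.  All in-region water oxygens
    appear as nodes even when isolated.
    """
    criteria = criteria or HBondCriteria()
    use_angle = criteria.resolved_use_angle(structure)
    interactions = detect_hbonds(structure, criteria, mode)

    in_region: set[int] | None = None
    if region is not None:
        center = region.resolve_center(structure)
        in_region = {a.serial for a in structure.water_oxygens
                     if np.linalg.norm(a.coords - center) <= region.radius}
        interactions = [i for i in interactions
                        if (i.atom_a.is_water and i.atom_a.serial in in_region)
                        or (i.atom_b.is_water and i.atom_b.serial in in_region)]

    graph: nx.Graph = nx.DiGraph() if use_angle else nx.Graph()
    atoms: dict[int, Atom] = {}

    def _add_node(atom: Atom) -> None:
        atoms[atom.serial] = atom
        graph.add_node(atom.serial, coords=tuple(atom.coords), is_water=atom.is_water,
                       name=atom.name, residue_name=atom.residue_name,
                       residue_key=atom.residue_key)

    for w in structure.water_oxygens:
        if in_region is None or w.serial in in_region:
            _add_node(w)
    for i in interactions:
        _add_node(i.atom_a)
        _add_node(i.atom_b)
        if use_angle and i.donor_serial is not None:
            donor = i.atom_a if i.atom_a.serial == i.donor_serial else i.atom_b
            acceptor = i.atom_b if donor is i.atom_a else i.atom_a
            u, v = donor.serial, acceptor.serial
        else:
            u, v = i.atom_a.serial, i.atom_b.serial
        graph.add_edge(u, v, distance=i.distance, angle=i.dha_angle,
                       kind=i.kind, protein_site=i.protein_site)

    return WaterNetwork(graph=graph, mode=mode, directed=use_angle,
                        structure_id=structure.id, frame_index=structure.frame_index,
                        interactions=interactions, atoms=atoms)


def build_networks(structures: Sequence[Structure],
                   criteria: HBondCriteria | None = None, mode: str = "full",
                   region: ActiveRegion | None = None,
                   n_jobs: int = 1) -> list[WaterNetwork]:
    """Networks for many structures/frames; results in input order.

    Per-structure tasks are independent, so parallel dispatch (joblib) cannot
    change any result — only wall time.
    """
    if n_jobs == 1:
        return [build_network(s, criteria, mode, region) for s in structures]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_jobs)(
        delayed(build_network)(s, criteria, mode, region) for s in structures)
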