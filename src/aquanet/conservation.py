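"""Conserved-water analysis across structures and trajectory frames.

Water oxygen positions from many superposed structures (or frames) are pooled
and clustered with a density-based algorithm (DBSCAN, HDBSCAN or OPTICS).
Cluster centroids form the *summary network* — the consensus set of hydration
sites.  Against that consensus the module computes:

* a per-cluster conservation value: the fraction of structures with a water
  within a match tolerance (default 1 Å) of the centroid;
* a pairwise conservation value for centroid pairs closer than a cutoff
  (default 2 Å): how often both sites are occupied simultaneously;
* a per-structure conservation score

      S = (1/N_s) Σ_i  a_i / (1 + Σ_j w(a_i)_j)

  where N_s is the number of summary waters, a_i is 1 when the structure has
  a water within the match tolerance of summary water i, and Σ_j w(a_i)_j
  counts the structure's other waters inside a local sphere (default 6 Å)
  around summary water i.  The local-crowding denominator makes the score
  insensitive to how densely solvated a structure happens to be: a perfect,
  uncrowded match of every site gives exactly 1;
* per-residue interaction scores (total water–protein interactions divided
  by the number of structures/frames, with the mean number of simultaneously
  bound waters), split into backbone and side-chain contributions;
* a two-reference-angle descriptor of each water–protein contact, which
  separates distinct water positions around a residue in two dimensions;
* water-occupancy density grids for hotspot visualisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alignment import AlignmentMap
from .network import Interaction, WaterNetwork
from .structure_io import ActiveRegion

__all__ = [
    "ClusterParams",
    "ConservationParams",
    "SummaryNetwork",
    "AngleRecord",
    "InteractionScoreRecord",
    "DensityGrid",
    "GeometryError",
    "DEFAULT_REF1",
    "DEFAULT_REF2",
    "pool_positions",
    "cluster_waters",
    "conservation_score",
    "two_angle_classify",
    "angle_records",
    "interaction_scores",
    "density_hotspots",
]

DEFAULT_REF1 = np.array([0.0, 10.0, 0.0])
DEFAULT_REF2 = np.array([10.0, 0.0, 10.0])


class GeometryError(Exception):
    pass


@dataclass
class ClusterParams:
    """Density-clustering configuration for pooled water positions."""

    algorithm: str = "dbscan"      # dbscan | hdbscan | optics
    eps: float = 1.0               # Å, dbscan neighborhood radius
    min_samples: int = 5
    min_cluster_size: int = 5      # hdbscan

    def __post_init__(self) -> None:
        if self.algorithm not in ("dbscan", "hdbscan", "optics"):
            raise ValueError(f"unknown clustering algorithm {self.algorithm!r}")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.algorithm == "dbscan" and self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class ConservationParams:
    """Distance tolerances of the conservation analyses (Å)."""

    match_distance: float = 1.0    # water-to-centroid match tolerance
    local_sphere: float = 6.0      # crowding sphere around each summary water
    pair_distance: float = 2.0     # centroid pairs closer than this get a pair score

    def __post_init__(self) -> None:
        if min(self.match_distance, self.local_sphere, self.pair_distance) <= 0:
            raise ValueError("all conservation distances must be > 0")


@dataclass
class SummaryNetwork:
    """Consensus hydration sites: cluster centroids with conservation values."""

    centroids: np.ndarray                       # (N_s, 3)
    cluster_sizes: np.ndarray                   # member counts
    cluster_conservation: np.ndarray            # fraction of units occupying each site
    pair_conservation: dict[tuple[int, int], float]
    edges: list[tuple[int, int]]                # centroid pairs within H-bond distance
    labels: np.ndarray                          # per-point cluster label (-1 = noise)
    points: pd.DataFrame                        # the pooled positions that were clustered
    n_units: int                                # structures/frames pooled

    @property
    def n_summary(self) -> int:
        return len(self.centroids)

    def __bool__(self) -> bool:
        return self.n_summary > 0


@dataclass
class AngleRecord:
    """Two-reference-angle descriptor of one water–protein interaction."""

    structure_id: str
    frame_index: int | None
    common_column: int | None
    residue_name: str
    protein_site: str
    angle1: float
    angle2: float


@dataclass
class InteractionScoreRecord:
    """Water-interaction propensity of one residue (one alignment column)."""

    common_column: int
    residue_name: str
    raw_count: int
    score: float
    mean_simultaneous: float | None
    backbone_score: float
    sidechain_score: float


@dataclass
class DensityGrid:
    """Regular-grid occupancy counts of water oxygens."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray       # (nx, ny, nz) int
    n_samples: int           # water observations offered for binning
    n_frames: int            # networks pooled, for occupancy normalisation

    def voxel_center(self, i: int, j: int, k: int) -> np.ndarray:
        return self.origin + (np.array([i, j, k]) + 0.5) * self.spacing


# ---------------------------------------------------------------------------
# pooling and clustering
# ---------------------------------------------------------------------------

def pool_positions(networks: Sequence[WaterNetwork]) -> pd.DataFrame:
    """Pooled water-oxygen coordinates of many superposed networks.

    One row per water oxygen with its provenance (structure id, frame index,
    atom serial).  No deduplication: every observation counts.
    """
    rows = []
    for net in networks:
        for serial in net.water_serials():
            a = net.atoms[serial]
            rows.append((net.structure_id, net.frame_index, serial,
                         a.coords[0], a.coords[1], a.coords[2]))
    df = pd.DataFrame(rows, columns=["structure_id", "frame", "serial", "x", "y", "z"])
    df["unit"] = [f"{s}@{f}" if f is not None else s
                  for s, f in zip(df["structure_id"], df["frame"])]
    return df


def _run_clustering(coords: np.ndarray, params: ClusterParams) -> np.ndarray:
    from sklearn.cluster import DBSCAN, HDBSCAN, OPTICS

    if params.algorithm == "dbscan":
        model = DBSCAN(eps=params.eps, min_samples=params.min_samples)
    elif params.algorithm == "hdbscan":
        model = HDBSCAN(min_cluster_size=params.min_cluster_size,
                        min_samples=params.min_samples)
    else:
        model = OPTICS(min_samples=params.min_samples)
    return model.fit_predict(coords)


def _units_of(points: pd.DataFrame, networks_units: Sequence[str] | None = None) -> list[str]:
    if networks_units is not None:
        return list(networks_units)
    return list(dict.fromkeys(points["unit"]))


def cluster_waters(points: pd.DataFrame,
                   params: ClusterParams | None = None,
                   conservation: ConservationParams | None = None,
                   hbond_distance: float = 3.8,
                   all_units: Sequence[str] | None = None) -> SummaryNetwork:
    """Cluster pooled water positions into a summary network.

    Noise points (label −1) are excluded from centroids.  Per-cluster and
    pairwise conservation are fractions over *all_units* (defaults to the
    units present in *points*; pass the full unit list when some structures
    contributed no waters).  Summary edges join centroids within the H-bond
    distance cutoff.
    """
    params = params or ClusterParams()
    conservation = conservation or ConservationParams()
    units = _units_of(points, all_units)
    n_units = len(units)

    empty = SummaryNetwork(
        centroids=np.empty((0, 3)), cluster_sizes=np.array([], dtype=int),
        cluster_conservation=np.array([]), pair_conservation={}, edges=[],
        labels=np.array([], dtype=int), points=points, n_units=n_units)
    if len(points) == 0:
        warnings.warn("no water positions to cluster")
        return empty
    if len(points) < params.min_samples:
        warnings.warn(f"fewer points ({len(points)}) than min_samples "
                      f"({params.min_samples}); no clusters")
        empty.labels = np.full(len(points), -1)
        return empty

    coords = points[["x", "y", "z"]].to_numpy(dtype=float)
    labels = _run_clustering(coords, params)
    cluster_ids = sorted(set(labels) - {-1})
    if not cluster_ids:
        warnings.warn("all points classified as noise; summary network is empty")
        empty.labels = labels
        return empty

    centroids = np.array([coords[labels == c].mean(axis=0) for c in cluster_ids])
    sizes = np.array([int(np.sum(labels == c)) for c in cluster_ids])

    # per-unit occupancy of each site within the match tolerance
    occupancy = np.zeros((n_units, len(cluster_ids)), dtype=bool)
    unit_index = {u: i for i, u in enumerate(units)}
    for u, grp in points.groupby("unit", sort=False):
        if u not in unit_index:
            continue
        tree = cKDTree(grp[["x", "y", "z"]].to_numpy(dtype=float))
        d, _ = tree.query(centroids, k=1)
        occupancy[unit_index[u]] = d <= conservation.match_distance
    cons = occupancy.mean(axis=0) if n_units else np.zeros(len(cluster_ids))

    pair_cons: dict[tuple[int, int], float] = {}
    edges: list[tuple[int, int]] = []
    for i in range(len(cluster_ids)):
        for j in range(i + 1, len(cluster_ids)):
            d = float(np.linalg.norm(centroids[i] - centroids[j]))
            if d <= hbond_distance:
                edges.append((i, j))
            if d <= conservation.pair_distance:
                both = occupancy[:, i] & occupancy[:, j]
                pair_cons[(i, j)] = float(both.mean()) if n_units else 0.0

    return SummaryNetwork(centroids=centroids, cluster_sizes=sizes,
                          cluster_conservation=cons, pair_conservation=pair_cons,
                          edges=edges, labels=labels, points=points, n_units=n_units)


# ---------------------------------------------------------------------------
# conservation score
# ---------------------------------------------------------------------------

def conservation_score(summary: SummaryNetwork,
                       structure_waters: np.ndarray,
                       params: ConservationParams | None = None) -> float:
    """Per-structure conservation score against the summary network.

    S = (1/N_s) Σ_i a_i / (1 + w_i): a_i is 1 when the structure has a water
    within the match tolerance of summary water i, and w_i counts the
    structure's *other* waters (the matched one excluded) within the local
    sphere of summary water i.  The score is 1 exactly when every summary
    water is matched with no additional local crowding, and 0 when nothing
    matches.
    """
    params = params or ConservationParams()
    if summary.n_summary == 0:
        raise ValueError("summary network is empty; conservation score undefined")
    waters = np.asarray(structure_waters, dtype=float).reshape(-1, 3)
    if len(waters) == 0:
        return 0.0
    tree = cKDTree(waters)
    total = 0.0
    for centroid in summary.centroids:
        dists, idx = tree.query(centroid, k=len(waters))
        dists = np.atleast_1d(dists)
        if dists[0] > params.match_distance:
            continue  # a_i = 0
        # matched water = nearest within tolerance; crowding counts the rest
        w = int(np.sum(dists[1:] <= params.local_sphere))
        total += 1.0 / (1.0 + w)
    return total / summary.n_summary


def conservation_scores(summary: SummaryNetwork,
                        networks: Sequence[WaterNetwork],
                        params: ConservationParams | None = None
                        ) -> pd.DataFrame:
    """Conservation score of every network against one summary network."""
    rows = []
    for net in networks:
        s = conservation_score(summary, net.water_positions(), params)
        rows.append((net.structure_id, net.frame_index, s))
    return pd.DataFrame(rows, columns=["structure_id", "frame", "conservation_score"])


# ---------------------------------------------------------------------------
# two-angle classification
# ---------------------------------------------------------------------------

def _angle_at(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    v1 = p - vertex
    v2 = q - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("water oxygen coincides with the protein atom or a reference point")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def two_angle_classify(interaction: Interaction,
                       amap: AlignmentMap | None = None,
                       structure_id: str | None = None,
                       frame_index: int | None = None,
                       ref1: np.ndarray = DEFAULT_REF1,
                       ref2: np.ndarray = DEFAULT_REF2) -> AngleRecord:
    """Describe a water–protein contact by two angles at the water oxygen.

    Each angle is measured between the vector to the interacting protein atom
    and the vector to a fixed reference point (defaults (0, 10, 0) and
    (10, 0, 10) Å; any Cα position may be substituted).  With all structures
    in one frame, the (angle1, angle2) pair separates distinct water
    positions — including around residues that vary across a family but keep
    the same hydration site.
    """
    if interaction.kind != "water-protein":
        raise ValueError("two-angle classification applies to water–protein interactions")
    water = interaction.atom_a if interaction.atom_a.is_water else interaction.atom_b
    prot = interaction.atom_b if interaction.atom_a.is_water else interaction.atom_a
    a1 = _angle_at(water.coords, prot.coords, np.asarray(ref1, dtype=float))
    a2 = _angle_at(water.coords, prot.coords, np.asarray(ref2, dtype=float))
    column = None
    if amap is not None and structure_id is not None:
        column = amap.column_of(structure_id, prot.residue_key)
    return AngleRecord(structure_id=structure_id or "", frame_index=frame_index,
                       common_column=column, residue_name=prot.residue_name,
                       protein_site=interaction.protein_site or "side-chain",
                       angle1=a1, angle2=a2)


def angle_records(networks: Sequence[WaterNetwork],
                  amap: AlignmentMap | None = None,
                  ref1: np.ndarray = DEFAULT_REF1,
                  ref2: np.ndarray = DEFAULT_REF2) -> pd.DataFrame:
    """Two-angle descriptors for every water–protein interaction."""
    rows = []
    for net in networks:
        for i in net.interactions:
            if i.kind != "water-protein":
                continue
            rec = two_angle_classify(i, amap, net.structure_id, net.frame_index,
                                     ref1, ref2)
            rows.append((rec.structure_id, rec.frame_index, rec.common_column,
                         rec.residue_name, rec.protein_site, rec.angle1, rec.angle2))
    return pd.DataFrame(rows, columns=["structure_id", "frame", "common_column",
                                       "residue_name", "protein_site",
                                       "angle1", "angle2"])


# ---------------------------------------------------------------------------
# interaction scores
# ---------------------------------------------------------------------------

def interaction_scores(networks: Sequence[WaterNetwork],
                       amap: AlignmentMap | None = None
                       ) -> list[InteractionScoreRecord]:
    """Per-residue water-interaction scores over structures or frames.

    score = (total water–protein interactions of the residue) / (number of
    networks).  A residue bound to one water in every frame and a residue
    bound to two waters in half the frames both score 1; the mean number of
    simultaneously interacting waters (over frames with at least one, so
    1.0 vs 2.0 here) disambiguates them.  Residues are keyed by alignment
    column when a map is given, else by (chain, resnum, icode).
    """
    n_units = len(networks)
    if n_units == 0:
        return []

    counts: dict[object, dict[tuple[str, int | None], int]] = {}
    waters_bound: dict[object, dict[tuple[str, int | None], set]] = {}
    site_counts: dict[object, dict[str, int]] = {}
    res_names: dict[object, str] = {}

    for net in networks:
        unit = net.unit
        for i in net.interactions:
            if i.kind != "water-protein":
                continue
            water = i.atom_a if i.atom_a.is_water else i.atom_b
            prot = i.atom_b if i.atom_a.is_water else i.atom_a
            key: object = prot.residue_key
            if amap is not None:
                col = amap.column_of(net.structure_id, prot.residue_key)
                if col is not None:
                    key = col
            counts.setdefault(key, {}).setdefault(unit, 0)
            counts[key][unit] += 1
            waters_bound.setdefault(key, {}).setdefault(unit, set()).add(water.serial)
            site_counts.setdefault(key, {"backbone": 0, "side-chain": 0})
            site_counts[key][i.protein_site or "side-chain"] += 1
            res_names.setdefault(key, prot.residue_name)

    records: list[InteractionScoreRecord] = []
    for key in sorted(counts, key=lambda k: (not isinstance(k, int), str(k))):
        per_unit = counts[key]
        raw = sum(per_unit.values())
        sim = [len(s) for s in waters_bound[key].values() if s]
        records.append(InteractionScoreRecord(
            common_column=key if isinstance(key, int) else -1,
            residue_name=res_names[key],
            raw_count=raw,
            score=raw / n_units,
            mean_simultaneous=float(np.mean(sim)) if sim else None,
            backbone_score=site_counts[key]["backbone"] / n_units,
            sidechain_score=site_counts[key]["side-chain"] / n_units,
        ))
    return records


# ---------------------------------------------------------------------------
# density hotspots
# ---------------------------------------------------------------------------

def density_hotspots(networks: Sequence[WaterNetwork],
                     grid_spacing: float = 0.5,
                     region: ActiveRegion | None = None,
                     center: np.ndarray | None = None,
                     radius: float | None = None) -> DensityGrid:
    """Occupancy grid of water-oxygen positions over superposed networks.

    The grid is axis-aligned in the common reference frame and covers a
    sphere given either by an :class:`ActiveRegion` (resolved against the
    atoms of the first network) or an explicit center and radius.  Counts
    divided by ``n_frames`` give per-voxel occupancy.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    if not networks:
        raise ValueError("no networks given")
    if center is None or radius is None:
        if region is None:
            raise ValueError("give a region, or an explicit center and radius")
        from .structure_io import Structure
        first = networks[0]
        pseudo = Structure(first.structure_id, list(first.atoms.values()),
                           source="static")
        center = region.resolve_center(pseudo)
        radius = region.radius
    center = np.asarray(center, dtype=float)

    n_bins = int(math.ceil(2 * radius / grid_spacing))
    origin = center - radius
    counts = np.zeros((n_bins, n_bins, n_bins), dtype=int)
    n_samples = 0
    for net in networks:
        pts = net.water_positions()
        n_samples += len(pts)
        if len(pts) == 0:
            continue
        d = np.linalg.norm(pts - center, axis=1)
        pts = pts[d <= radius]
        if len(pts) == 0:
            continue
        idx = np.floor((pts - origin) / grid_spacing).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return DensityGrid(origin=origin, spacing=grid_spacing, counts=counts,
                       n_samples=n_samples, n_frames=len(networks))
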