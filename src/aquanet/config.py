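"""Run configuration and the one-shot analysis pipeline.

A run reads a directory of PDB structures (or a topology + trajectory pair),
aligns and superposes everything onto a common reference, builds per-unit
water networks, computes graph metrics, clusters pooled water positions into
a summary network, scores conservation and per-residue interactions, and
writes all tables plus visualisation files into an output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .alignment import AlignmentMap, align_structures, import_alignment, superpose
from .conservation import (ClusterParams, ConservationParams, angle_records,
                           cluster_waters, conservation_scores, density_hotspots,
                           interaction_scores, pool_positions)
from .export import (write_dx, write_edges_csv, write_metrics_csv, write_pml,
                     write_scores_csv, write_summary_csv, write_summary_pdb)
from .metrics import compute_metrics
from .network import HBondCriteria, build_networks
from .structure_io import (DEFAULT_WATER_NAMES, ActiveRegion, Structure,
                           read_frames, read_structure)

__all__ = ["RunConfig", "ConfigError", "run"]


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    """All user-tunable parameters of a run, with the standard defaults."""

    input_dir: str | None = None          # directory of *.pdb structures
    topology: str | None = None           # or: topology + trajectory
    trajectory: str | None = None
    stride: int = 1
    output_dir: str = "aquanet_out"
    mode: str = "full"                    # water-water | water-protein | full
    distance_cutoff: float = 3.8
    angle_cutoff: float = 150.0
    use_angle: bool | None = None
    neighbor_k: int = 10
    water_residue_names: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_WATER_NAMES))
    region_selection: str | None = None   # e.g. "protein"; None = whole system
    region_radius: float = 9.0
    region_center_mode: str = "com"
    alignment_file: str | None = None     # PIR/FASTA MSA; None = built-in aligner
    reference_structure: str | None = None  # id; None = first lexicographically
    max_gap: int = 20
    cluster_algorithm: str = "dbscan"
    cluster_eps: float = 1.0
    cluster_min_samples: int = 5
    cluster_min_cluster_size: int = 5
    match_distance: float = 1.0
    local_sphere: float = 6.0
    pair_distance: float = 2.0
    ref1: list[float] = field(default_factory=lambda: [0.0, 10.0, 0.0])
    ref2: list[float] = field(default_factory=lambda: [10.0, 0.0, 10.0])
    grid_spacing: float = 0.5
    seed: int = 0
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def validate(self) -> None:
        if self.input_dir is None and (self.topology is None or self.trajectory is None):
            raise ConfigError("give input_dir, or topology and trajectory")
        for p in (self.input_dir, self.topology, self.trajectory, self.alignment_file):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")
        if self.mode not in ("water-water", "water-protein", "full"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(distance_cutoff=self.distance_cutoff,
                             angle_cutoff=self.angle_cutoff,
                             use_angle=self.use_angle,
                             neighbor_k=self.neighbor_k)

    def region(self) -> ActiveRegion | None:
        if self.region_selection is None:
            return None
        return ActiveRegion(selection=self.region_selection,
                            radius=self.region_radius,
                            center_mode=self.region_center_mode)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(algorithm=self.cluster_algorithm, eps=self.cluster_eps,
                             min_samples=self.cluster_min_samples,
                             min_cluster_size=self.cluster_min_cluster_size)

    def conservation_params(self) -> ConservationParams:
        return ConservationParams(match_distance=self.match_distance,
                                  local_sphere=self.local_sphere,
                                  pair_distance=self.pair_distance)


def _load_structures(config: RunConfig) -> list[Structure]:
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.pdb"))
        if not paths:
            raise ConfigError(f"no .pdb files in {config.input_dir}")
        return [read_structure(p, config.water_residue_names) for p in paths]
    return list(read_frames(config.topology, config.trajectory, config.stride,
                            config.water_residue_names))


def _align_and_superpose(structures: list[Structure],
                         config: RunConfig) -> tuple[list[Structure], AlignmentMap | None]:
    static = structures[0].source == "static"
    if not static or len({s.id for s in structures}) < 2:
        # frames share one topology: common indexing is the identity
        amap = None
        if config.alignment_file:
            amap = import_alignment(config.alignment_file, structures[:1])
        return structures, amap
    if config.alignment_file:
        amap = import_alignment(config.alignment_file, structures)
    else:
        amap = align_structures(structures, max_gap=config.max_gap)
    ref_id = config.reference_structure or min(s.id for s in structures)
    by_id = {s.id: s for s in structures}
    if ref_id not in by_id:
        raise ConfigError(f"reference structure {ref_id!r} not among inputs")
    reference = by_id[ref_id]
    out = []
    for s in structures:
        if s.id == ref_id:
            out.append(s)
        else:
            moved, _ = superpose(s, reference, amap)
            out.append(moved)
    return out, amap


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline; returns the paths of everything written."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    structures = _stage("read", _load_structures, config)
    structures, amap = _stage("align", _align_and_superpose, structures, config)

    networks = _stage("network", build_networks, structures, config.criteria(),
                      config.mode, config.region(), config.n_jobs)
    write_edges_csv(networks, out / "edges.csv")
    written["edges"] = out / "edges.csv"

    metrics = _stage("metrics", lambda: [compute_metrics(n) for n in networks])
    write_metrics_csv(metrics, out / "metrics.csv", out / "clustering_coefficients.csv")
    written["metrics"] = out / "metrics.csv"
    written["clustering"] = out / "clustering_coefficients.csv"

    def _conserve():
        points = pool_positions(networks)
        units = [f"{s}@{f}" if f is not None else s
                 for s, f in (n.unit for n in networks)]
        summary = cluster_waters(points, config.cluster_params(),
                                 config.conservation_params(),
                                 hbond_distance=config.distance_cutoff,
                                 all_units=units)
        return summary

    summary = _stage("conserve", _conserve)
    if summary.n_summary:
        write_summary_pdb(summary, out / "summary_network.pdb")
        write_summary_csv(summary, out / "summary_clusters.csv",
                          out / "summary_pairs.csv")
        write_pml(summary, out / "summary_network.pml", name="summary")
        scores = conservation_scores(summary, networks, config.conservation_params())
        scores.to_csv(out / "conservation_scores.csv", index=False)
        written["summary_pdb"] = out / "summary_network.pdb"
        written["conservation_scores"] = out / "conservation_scores.csv"

    records = _stage("scores", interaction_scores, networks, amap)
    write_scores_csv(records, out / "interaction_scores.csv")
    written["interaction_scores"] = out / "interaction_scores.csv"

    angles = _stage("angles", angle_records, networks, amap,
                    config.ref1, config.ref2)
    angles.round(4).to_csv(out / "angle_records.csv", index=False)
    written["angles"] = out / "angle_records.csv"

    nonempty = [n for n in networks if n.graph.number_of_nodes() > 0]
    if nonempty:
        write_pml(nonempty[0], out / "first_network.pml")
        written["pml"] = out / "first_network.pml"
        region = config.region() or ActiveRegion(selection="protein",
                                                 radius=config.region_radius)
        center = region.resolve_center(structures[0])
        grid = _stage("density", density_hotspots, nonempty, config.grid_spacing,
                      center=center, radius=region.radius)
        write_dx(grid, out / "water_density.dx")
        written["density"] = out / "water_density.dx"

    log = out / "run_log.txt"
    params = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    log.write_text(
        f"aquanet {__version__}\n"
        f"structures/frames analysed: {len(structures)}\n"
        f"summary waters: {summary.n_summary}\n"
        f"--- effective parameters ---\n{params}")
    written["log"] = log
    return written
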