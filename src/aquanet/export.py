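"""Writers: PyMOL scripts, CSV tables, summary PDB, OpenDX grids.

Every CSV has a header row and a column order that is stable across runs, so
repeated runs with the same configuration produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import DensityGrid, InteractionScoreRecord, SummaryNetwork
from .metrics import NetworkMetrics
from .network import WaterNetwork

__all__ = [
    "write_pml",
    "write_edges_csv",
    "write_metrics_csv",
    "write_clustering_csv",
    "write_summary_pdb",
    "write_summary_csv",
    "write_scores_csv",
    "write_dx",
]

_FLOAT = "%.4f"


def _fmt(x: float) -> str:
    return _FLOAT % x


def _conservation_color(value: float) -> tuple[float, float, float]:
    """Blue (0, unconserved) → red (1, fully conserved)."""
    v = float(np.clip(value, 0.0, 1.0))
    return (v, 0.2, 1.0 - v)


def write_pml(obj: WaterNetwork | SummaryNetwork, path: str | Path,
              name: str = "water_network") -> None:
    """Write a PyMOL .pml script visualising a network or summary network.

    Water nodes become pseudoatoms (spheres); edges become distance objects.
    For a summary network, spheres are colored by conservation (blue → red).
    """
    lines: list[str] = [f"# {name}: water network visualisation", "set sphere_scale, 0.3"]
    if isinstance(obj, SummaryNetwork):
        if obj.n_summary == 0:
            raise ValueError("summary network is empty; nothing to write")
        for i, (c, cons) in enumerate(zip(obj.centroids, obj.cluster_conservation)):
            lines.append(
                f"pseudoatom {name}, pos=[{_fmt(c[0])}, {_fmt(c[1])}, {_fmt(c[2])}], "
                f"name=W{i}, resi={i + 1}, b={_fmt(cons)}")
            r, g, b = _conservation_color(cons)
            lines.append(f"set_color cons_{i}, [{_fmt(r)}, {_fmt(g)}, {_fmt(b)}]")
            lines.append(f"color cons_{i}, {name} and resi {i + 1}")
        for (i, j) in obj.edges:
            lines.append(f"distance {name}_edges, {name} and resi {i + 1}, "
                         f"{name} and resi {j + 1}")
    else:
        if obj.graph.number_of_nodes() == 0:
            raise ValueError("network is empty; nothing to write")
        for serial, atom in sorted(obj.atoms.items()):
            if not atom.is_water:
                continue
            c = atom.coords
            lines.append(
                f"pseudoatom {name}, pos=[{_fmt(c[0])}, {_fmt(c[1])}, {_fmt(c[2])}], "
                f"name=W{serial}, resi={serial}")
        for u, v in sorted(obj.graph.edges()):
            au, av = obj.atoms[u], obj.atoms[v]
            if au.is_water and av.is_water:
                lines.append(f"distance {name}_edges, {name} and resi {u}, "
                             f"{name} and resi {v}")
            else:
                w = u if au.is_water else v
                c = (av if au.is_water else au).coords
                lines.append(
                    f"pseudoatom {name}_prot, pos=[{_fmt(c[0])}, {_fmt(c[1])}, "
                    f"{_fmt(c[2])}], name=P{v if au.is_water else u}, "
                    f"resi={v if au.is_water else u}")
                lines.append(f"distance {name}_edges, {name} and resi {w}, "
                             f"{name}_prot and resi {v if au.is_water else u}")
    lines.append("show spheres")
    lines.append("hide labels")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edges_csv(networks: Sequence[WaterNetwork], path: str | Path) -> None:
    rows = []
    for net in networks:
        for i in net.interactions:
            rows.append((net.structure_id, net.frame_index,
                         i.atom_a.serial, i.atom_b.serial, i.kind,
                         round(i.distance, 4),
                         round(i.dha_angle, 4) if i.dha_angle is not None else "",
                         i.donor_serial if i.donor_serial is not None else ""))
    df = pd.DataFrame(rows, columns=["structure_id", "frame", "atom_a", "atom_b",
                                     "kind", "distance", "angle", "donor"])
    df.to_csv(path, index=False)


def write_metrics_csv(metrics: Sequence[NetworkMetrics], path: str | Path,
                      clustering_path: str | Path | None = None) -> None:
    rows = [{
        "structure_id": m.structure_id, "frame": m.frame_index,
        "n_nodes": m.n_nodes, "n_edges": m.n_edges,
        "density": round(m.density, 6), "entropy": round(m.entropy, 6),
        "cpl_mean": round(m.cpl_mean, 6) if m.cpl_mean is not None else "",
        "cpl_largest": round(m.cpl_largest, 6) if m.cpl_largest is not None else "",
        "n_components": m.n_components,
        "n_ww_interactions": m.n_ww_interactions,
        "n_wp_interactions": m.n_wp_interactions,
    } for m in metrics]
    pd.DataFrame(rows).to_csv(path, index=False)
    if clustering_path is not None:
        write_clustering_csv(metrics, clustering_path)


def write_clustering_csv(metrics: Sequence[NetworkMetrics], path: str | Path) -> None:
    """Per-node clustering coefficients in long format."""
    rows = []
    for m in metrics:
        for node, cc in sorted(m.clustering_coefficients.items()):
            rows.append((m.structure_id, m.frame_index, node, round(cc, 6)))
    pd.DataFrame(rows, columns=["structure_id", "frame", "node",
                                "clustering_coefficient"]).to_csv(path, index=False)


def write_summary_pdb(summary: SummaryNetwork, path: str | Path) -> None:
    """Centroids as pseudo-water HETATM records, conservation in the B column."""
    lines = []
    for i, (c, cons) in enumerate(zip(summary.centroids, summary.cluster_conservation),
                                  start=1):
        lines.append(
            f"HETATM{i:>5d}  O   HOH W{i:>4d}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{cons:6.2f}           O")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_csv(summary: SummaryNetwork, path: str | Path,
                      pairs_path: str | Path | None = None) -> None:
    rows = [{
        "cluster": i,
        "x": round(summary.centroids[i][0], 4),
        "y": round(summary.centroids[i][1], 4),
        "z": round(summary.centroids[i][2], 4),
        "size": int(summary.cluster_sizes[i]),
        "conservation": round(float(summary.cluster_conservation[i]), 6),
    } for i in range(summary.n_summary)]
    pd.DataFrame(rows, columns=["cluster", "x", "y", "z", "size",
                                "conservation"]).to_csv(path, index=False)
    if pairs_path is not None:
        prow = [{"cluster_i": i, "cluster_j": j, "pair_conservation": round(v, 6)}
                for (i, j), v in sorted(summary.pair_conservation.items())]
        pd.DataFrame(prow, columns=["cluster_i", "cluster_j",
                                    "pair_conservation"]).to_csv(pairs_path, index=False)


def write_scores_csv(records: Sequence[InteractionScoreRecord], path: str | Path) -> None:
    rows = [{
        "common_column": r.common_column,
        "residue_name": r.residue_name,
        "raw_count": r.raw_count,
        "score": round(r.score, 6),
        "mean_simultaneous": round(r.mean_simultaneous, 6)
        if r.mean_simultaneous is not None else "",
        "backbone_score": round(r.backbone_score, 6),
        "sidechain_score": round(r.sidechain_score, 6),
    } for r in records]
    pd.DataFrame(rows, columns=["common_column", "residue_name", "raw_count",
                                "score", "mean_simultaneous", "backbone_score",
                                "sidechain_score"]).to_csv(path, index=False)


def write_dx(grid: DensityGrid, path: str | Path, normalize: bool = True) -> None:
    """Write a density grid in OpenDX format (readable by PyMOL/VMD/Chimera).

    With ``normalize`` the counts are divided by the number of pooled
    networks, giving per-frame occupancy.
    """
    nx_, ny, nz = grid.counts.shape
    data = grid.counts.astype(float)
    if normalize and grid.n_frames > 0:
        data = data / grid.n_frames
    o = grid.origin
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx_} {ny} {nz}",
        f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}",
        f"delta {s:.4f} 0 0",
        f"delta 0 {s:.4f} 0",
        f"delta 0 0 {s:.4f}",
        f"object 2 class gridconnections counts {nx_} {ny} {nz}",
        f"object 3 class array type double rank 0 items {data.size} data follows",
    ]
    flat = data.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "density" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")
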