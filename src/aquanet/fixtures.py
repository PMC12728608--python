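"""Synthetic structures and trajectories with planted hydration geometry.

The generator emulates the inputs the analysis expects — small proteins with
crystallographic waters, replicated across "structures" of a family or across
trajectory frames — with full control over the planted geometry:

* a minimal serine-like protein template (backbone N/CA/C/O plus one polar
  side-chain oxygen per residue), enough for Cα superposition and for the
  backbone/side-chain interaction split, without any force field;
* planted water sites with per-unit presence probability (or an explicit
  per-frame schedule) and isotropic Gaussian positional jitter;
* optional water hydrogens placed at 0.96 Å from the oxygen, oriented so a
  chosen acceptor sees a prescribed donor–hydrogen–acceptor angle;
* optional small rigid-body displacement per structure to exercise the
  superposition stage.

All randomness flows from one seed through per-unit ``numpy`` generators
seeded as ``default_rng([seed, unit_index])``, so sub-generators are
independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Atom, Structure, write_multi_model_pdb, write_pdb

__all__ = [
    "WaterSite",
    "FixtureSpec",
    "protein_template",
    "template_ca_position",
    "template_atom_position",
    "make_structures",
    "make_static_set",
    "make_trajectory",
    "place_hydrogens",
    "CONSERVED_DEMO_SITES",
    "conserved_sites_spec",
    "interaction_demo_frames",
    "water_pair_structure",
]

_OH_BOND = 0.96      # Å, O–H bond length in the rigid water model
_HOH_ANGLE = 104.5   # degrees


@dataclass
class WaterSite:
    """One planted hydration site.

    ``presence`` is either a probability in [0, 1] applied independently per
    unit, or an explicit boolean schedule of length ``n_units``.  ``jitter``
    is the per-axis Gaussian σ in Å.  When hydrogens are requested,
    ``acceptor`` (a 3-vector) orients one O–H so that the planted
    D–H···A angle toward it equals ``dha_angle`` degrees.
    """

    position: Sequence[float]
    presence: float | Sequence[bool] = 1.0
    jitter: float = 0.0
    acceptor: Sequence[float] | None = None
    dha_angle: float = 180.0
    positions: Sequence[Sequence[float]] | None = None  # per-unit override

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if isinstance(self.presence, (int, float)) and not 0 <= self.presence <= 1:
            raise ValueError("presence probability must be in [0, 1]")

    def realized(self, unit: int, rng: np.random.Generator) -> bool:
        if isinstance(self.presence, (int, float)):
            return bool(rng.random() < self.presence)
        return bool(self.presence[unit])


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure set or trajectory."""

    n_units: int = 5
    n_residues: int = 4
    sites: list[WaterSite] = field(default_factory=list)
    include_hydrogens: bool = False
    rigid_sigma_deg: float = 0.0     # per-unit random rotation magnitude
    rigid_sigma_trans: float = 0.0   # per-unit random translation σ, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_residues < 1:
            raise ValueError("n_units and n_residues must be >= 1")


def template_ca_position(i: int) -> np.ndarray:
    """Cα of residue *i* on an idealized helix (rise 1.5 Å, radius 2.3 Å,
    100° per residue) — non-collinear, so rigid superposition on the Cα set
    is fully determined."""
    theta = math.radians(100.0 * i)
    return np.array([1.5 * i, 2.3 * math.cos(theta), 2.3 * math.sin(theta)])


def protein_template(n_residues: int = 4, chain: str = "A") -> list[Atom]:
    """A serine-like pseudo-helix.

    Each residue carries backbone N, CA, C, O and a side-chain OG, giving
    both backbone and side-chain H-bond partners plus a Cα for superposition.
    """
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_residues):
        ca = template_ca_position(i)
        theta = math.radians(100.0 * i)
        radial = np.array([0.0, math.cos(theta), math.sin(theta)])
        tangent = np.array([0.0, -math.sin(theta), math.cos(theta)])
        axis = np.array([1.0, 0.0, 0.0])
        # substituents in the local helix frame, pointing outward/along the
        # chain so neighboring residues stay at bonded-plus distances
        offsets = {
            "N":  -1.2 * axis + 0.5 * tangent,
            "CA": np.zeros(3),
            "C":  1.2 * axis + 0.5 * tangent,
            "O":  1.2 * axis + 0.6 * tangent + 1.2 * radial,
            "OG": -0.3 * axis + 1.5 * radial,
        }
        for name, off in offsets.items():
            atoms.append(Atom(serial=serial, name=name,
                              element=name[0],
                              residue_name="SER", residue_number=i + 1,
                              chain=chain, coords=ca + off))
            serial += 1
    return atoms


def template_atom_position(residue_number: int, name: str) -> np.ndarray:
    """Coordinates of one template atom (residue numbers start at 1)."""
    for a in protein_template(residue_number):
        if a.residue_number == residue_number and a.name == name:
            return a.coords
    raise KeyError(f"no atom {name!r} in template residue {residue_number}")


def place_hydrogens(oxygen: np.ndarray, acceptor: np.ndarray | None,
                    dha_angle_deg: float = 180.0) -> tuple[np.ndarray, np.ndarray]:
    """Positions of two water hydrogens for a donor oxygen.

    H1 is placed so the angle O–H1···acceptor equals *dha_angle_deg* (180°
    puts H1 on the O→acceptor axis); H2 completes the 104.5° H–O–H geometry
    in the same plane.  Without an acceptor, H1 points along +x.
    """
    oxygen = np.asarray(oxygen, dtype=float)
    if acceptor is None:
        d = np.array([1.0, 0.0, 0.0])
        perp = np.array([0.0, 1.0, 0.0])
        alpha = 0.0
    else:
        acc = np.asarray(acceptor, dtype=float)
        vec = acc - oxygen
        dist = np.linalg.norm(vec)
        if dist < 1e-9:
            raise ValueError("acceptor coincides with the oxygen")
        d = vec / dist
        # perpendicular in-plane direction
        trial = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(trial, d)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = np.cross(d, trial)
        perp /= np.linalg.norm(perp)
        alpha = _solve_tilt(dist, math.radians(dha_angle_deg))
    h1 = oxygen + _OH_BOND * (math.cos(alpha) * d + math.sin(alpha) * perp)
    beta = alpha + math.radians(_HOH_ANGLE)
    h2 = oxygen + _OH_BOND * (math.cos(beta) * d + math.sin(beta) * perp)
    return h1, h2


def _solve_tilt(oa_distance: float, target_dha_rad: float) -> float:
    """Tilt of the O–H vector off the O→A axis giving the requested D–H···A angle."""
    from scipy.optimize import brentq

    r = _OH_BOND
    R = oa_distance

    def angle_at_h(alpha: float) -> float:
        h = r * np.array([math.cos(alpha), math.sin(alpha)])
        to_o = -h
        to_a = np.array([R, 0.0]) - h
        c = np.dot(to_o, to_a) / (np.linalg.norm(to_o) * np.linalg.norm(to_a))
        return math.acos(float(np.clip(c, -1.0, 1.0)))

    if target_dha_rad >= angle_at_h(1e-9):
        return 0.0  # on-axis placement gives the maximal (straight) angle
    # angle decreases monotonically from ~pi (alpha→0) toward smaller values
    return brentq(lambda a: angle_at_h(a) - target_dha_rad, 1e-9, math.pi - 1e-6)


def _rigid_transform(rng: np.random.Generator, sigma_deg: float,
                     sigma_trans: float) -> tuple[np.ndarray, np.ndarray]:
    angle = math.radians(rng.normal(0.0, sigma_deg)) if sigma_deg > 0 else 0.0
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    t = rng.normal(0.0, sigma_trans, size=3) if sigma_trans > 0 else np.zeros(3)
    return R, t


def make_structures(spec: FixtureSpec, source: str = "static") -> list[Structure]:
    """Generate the in-memory structures of a fixture spec.

    ``source="frame"`` labels units as frames of one trajectory (shared id,
    increasing frame_index); ``"static"`` gives each unit its own id.
    """
    structures: list[Structure] = []
    for u in range(spec.n_units):
        rng = np.random.default_rng([spec.seed, u])
        atoms = [Atom(a.serial, a.name, a.element, a.residue_name,
                      a.residue_number, a.chain, a.coords.copy())
                 for a in protein_template(spec.n_residues)]
        serial = max(a.serial for a in atoms) + 1
        resnum = 1
        for site in spec.sites:
            present = site.realized(u, rng)
            jitter = rng.normal(0.0, site.jitter, size=3) if site.jitter > 0 else np.zeros(3)
            if not present:
                continue
            base = site.position if site.positions is None else site.positions[u]
            pos = base + jitter
            atoms.append(Atom(serial=serial, name="O", element="O",
                              residue_name="HOH", residue_number=resnum,
                              chain="W", coords=pos, is_water=True))
            serial += 1
            if spec.include_hydrogens:
                acc = None if site.acceptor is None else np.asarray(site.acceptor, float)
                h1, h2 = place_hydrogens(pos, acc, site.dha_angle)
                for hname, hpos in (("H1", h1), ("H2", h2)):
                    atoms.append(Atom(serial=serial, name=hname, element="H",
                                      residue_name="HOH", residue_number=resnum,
                                      chain="W", coords=hpos, is_water=True,
                                      is_hydrogen=True))
                    serial += 1
            resnum += 1
        if spec.rigid_sigma_deg > 0 or spec.rigid_sigma_trans > 0:
            R, t = _rigid_transform(rng, spec.rigid_sigma_deg, spec.rigid_sigma_trans)
            for a in atoms:
                a.coords = R @ a.coords + t
        if source == "frame":
            structures.append(Structure("trajectory", atoms, source="frame",
                                        frame_index=u))
        else:
            structures.append(Structure(f"struct_{u:03d}", atoms, source="static"))
    return structures


def make_static_set(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write one PDB per unit into *out_dir*; returns the sorted paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in make_structures(spec, source="static"):
        p = out_dir / f"{s.id}.pdb"
        write_pdb(s, p)
        paths.append(p)
    return paths


def make_trajectory(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a topology PDB plus a multi-model PDB trajectory.

    The topology is frame 0; every frame must therefore contain the same
    atoms, so trajectory specs should use presence schedules that keep the
    atom count constant (parking absent waters far away rather than deleting
    them) or presence 1.0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = make_structures(spec, source="frame")
    n_atoms = {len(f.atoms) for f in frames}
    if len(n_atoms) != 1:
        raise ValueError(
            "trajectory frames must share one atom count; use presence=1.0 or "
            "an explicit schedule that keeps every water present")
    top = out_dir / "topology.pdb"
    traj = out_dir / "trajectory.pdb"
    write_pdb(frames[0], top)
    write_multi_model_pdb(frames, traj)
    return top, traj


# ---------------------------------------------------------------------------
# canned study fixtures
# ---------------------------------------------------------------------------

#: Five planted hydration sites, mutually >= 9 Å apart so that no site falls
#: inside another site's 6 Å crowding sphere.
CONSERVED_DEMO_SITES: tuple[tuple[float, float, float], ...] = (
    (0.0, 8.0, 0.0),
    (9.0, 8.0, 0.0),
    (18.0, 8.0, 0.0),
    (0.0, 8.0, 9.0),
    (18.0, 8.0, 9.0),
)


def conserved_sites_spec(n_units: int = 20, jitter: float = 0.2,
                         presence: float = 1.0, seed: int = 7) -> FixtureSpec:
    """Structure family with five fully separated planted hydration sites.

    With the defaults (20 structures, presence 1, σ = 0.2 Å) density
    clustering recovers exactly the planted sites with conservation 1, and a
    probe structure carrying one water per centroid scores a perfect
    conservation score of 1.
    """
    sites = [WaterSite(p, presence=presence, jitter=jitter)
             for p in CONSERVED_DEMO_SITES]
    return FixtureSpec(n_units=n_units, n_residues=6, sites=sites, seed=seed)


def interaction_demo_frames(n_frames: int = 10) -> list[Structure]:
    """Trajectory frames for the two-residue interaction-score worked example.

    Residue 1 (via its side-chain OG) binds exactly one water in every frame;
    residue 4 (via its backbone O) binds exactly two waters in the first half
    of the frames and none in the second half (those waters are parked 40 Å
    away).  Each water sits 2.9 Å from its target atom and beyond 4 Å from
    every other protein donor/acceptor, so the interaction counts are exactly
    as planted: residue 1 scores 1.0 with one simultaneous water, residue 4
    scores 1.0 with two.
    """
    if n_frames % 2:
        raise ValueError("n_frames must be even (half-occupied site schedule)")
    og1 = template_atom_position(1, "OG")
    ca1 = template_ca_position(0)
    out1 = og1 - ca1
    w_a = og1 + 2.9 * out1 / np.linalg.norm(out1)
    # positions found by grid search: within 2.9 Å of residue-4 backbone O and
    # beyond 4 Å of every other donor/acceptor of the 5-residue template
    w_b1 = np.array([7.22696828, 4.08938517, -1.06771725])
    w_b2 = np.array([7.91307530, 0.41262458, -2.98384057])
    park1 = np.array([40.0, 40.0, 40.0])
    park2 = np.array([46.0, 46.0, 46.0])
    half = n_frames // 2
    sites = [
        WaterSite(w_a),
        WaterSite(w_b1, positions=[w_b1] * half + [park1] * half),
        WaterSite(w_b2, positions=[w_b2] * half + [park2] * half),
    ]
    spec = FixtureSpec(n_units=n_frames, n_residues=5, sites=sites, seed=0)
    return make_structures(spec, source="frame")


def water_pair_structure(separation: float = 3.0, with_hydrogens: bool = False,
                         dha_angle: float = 180.0,
                         structure_id: str = "pair") -> Structure:
    """Two waters along x at a planted O–O separation.

    With hydrogens, the first water donates toward the second at the planted
    D–H···A angle; the second water's hydrogens point away from the first, so
    exactly one candidate donor geometry controls edge acceptance.
    """
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([separation, 0.0, 0.0])
    atoms = [
        Atom(1, "O", "O", "HOH", 1, "W", o1, is_water=True),
        Atom(2, "O", "O", "HOH", 2, "W", o2, is_water=True),
    ]
    if with_hydrogens:
        h1a, h1b = place_hydrogens(o1, o2, dha_angle)
        h2a, h2b = place_hydrogens(o2, None)
        serial = 3
        for resnum, (ha, hb) in ((1, (h1a, h1b)), (2, (h2a, h2b))):
            for name, pos in (("H1", ha), ("H2", hb)):
                atoms.append(Atom(serial, name, "H", "HOH", resnum, "W", pos,
                                  is_water=True, is_hydrogen=True))
                serial += 1
    return Structure(structure_id, atoms, source="static")
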