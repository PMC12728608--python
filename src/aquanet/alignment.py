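"""Common residue indexing and rigid superposition across related structures.

Cross-structure comparison of water positions only makes sense once (a) every
residue carries an index that is comparable between family members, and
(b) all coordinates live in one reference frame.  This module provides both:

* a center-star progressive multiple sequence alignment (pairwise global
  Needleman–Wunsch with BLOSUM62 and affine gaps; the center sequence is the
  one with the highest summed pairwise identity and every other sequence is
  merged against it), or the import of an externally computed MSA in PIR or
  aligned-FASTA format;
* Kabsch least-squares superposition on the Cα atoms of residues sharing an
  alignment column.

The alignment column index is the "common residue index" used by all
conservation analyses downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Structure

__all__ = [
    "AlignmentError",
    "ReconciliationError",
    "UnderdeterminedError",
    "AlignmentMap",
    "SuperpositionResult",
    "align_sequences",
    "align_structures",
    "import_alignment",
    "superpose",
    "kabsch",
    "write_alignment_fasta",
]


class AlignmentError(Exception):
    pass


class ReconciliationError(AlignmentError):
    """An imported alignment does not agree with the structure-derived sequence."""


class UnderdeterminedError(AlignmentError):
    """Too few matched residue pairs for a rigid superposition."""


@dataclass
class AlignmentMap:
    """A multiple sequence alignment plus residue-to-column mappings.

    ``aligned`` maps each label to its gapped sequence (all the same length,
    ``columns``).  ``pim`` is the pairwise percent-identity matrix (identities
    over columns where both sequences have a residue).  ``residue_maps`` maps
    a structure id to {(chain, resnum, icode): column}.
    """

    aligned: dict[str, str]
    columns: int
    pim: pd.DataFrame
    residue_maps: dict[str, dict[tuple[str, int, str], int]] = field(default_factory=dict)

    def position_columns(self, label: str) -> list[int]:
        """Alignment column of each ungapped residue position of *label*."""
        cols = []
        for col, ch in enumerate(self.aligned[label]):
            if ch != "-":
                cols.append(col)
        return cols

    def attach_structure(self, structure: Structure, label: str | None = None) -> None:
        """Build the residue-key → column mapping for *structure*.

        The structure's protein residues, in atom order, are walked against
        the ungapped alignment sequence of the matching label.
        """
        label = label or structure.id
        if label not in self.aligned:
            raise ReconciliationError(f"no alignment sequence labelled {label!r}")
        keys, seq = structure.residue_sequence()
        ungapped = self.aligned[label].replace("-", "")
        if len(ungapped) != len(seq):
            raise ReconciliationError(
                f"{label}: alignment sequence has {len(ungapped)} residues, "
                f"structure has {len(seq)}")
        for i, (a, b) in enumerate(zip(ungapped, seq)):
            if a != b and a != "X" and b != "X":
                raise ReconciliationError(
                    f"{label}: residue {i + 1} differs (alignment {a!r}, "
                    f"structure {b!r} at {keys[i]})")
        cols = self.position_columns(label)
        self.residue_maps[label] = dict(zip(keys, cols))

    def column_of(self, structure_id: str, residue_key: tuple[str, int, str]) -> int | None:
        return self.residue_maps.get(structure_id, {}).get(residue_key)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_pairs: int


@dataclass
class _Pairwise:
    aligned_a: str
    aligned_b: str
    identity: float  # percent


def _pairwise_align(seq_a: str, seq_b: str) -> _Pairwise:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    mat = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # BLOSUM62 lacks some ambiguity codes in old Biopython; X is present.
    aln = aligner.align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    ident = 0
    both = 0
    for x, y in zip(gapped_a, gapped_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    pct = 100.0 * ident / both if both else 0.0
    return _Pairwise(gapped_a, gapped_b, pct)


def _check_gap_runs(aligned: Mapping[str, str], max_gap: int) -> None:
    for label, seq in aligned.items():
        run = 0
        longest = 0
        for ch in seq:
            run = run + 1 if ch == "-" else 0
            longest = max(longest, run)
        if longest > max_gap:
            warnings.warn(
                f"alignment of {label!r} contains a gap run of {longest} "
                f"(> max_gap={max_gap}); consider supplying an external MSA",
                stacklevel=3)


def align_sequences(sequences: Mapping[str, str], max_gap: int = 20) -> AlignmentMap:
    """Progressive (center-star) global multiple alignment.

    All pairs are aligned with Needleman–Wunsch (BLOSUM62, gap open 10,
    extend 0.5); the center sequence maximises summed pairwise identity and
    the remaining sequences are merged against it column-wise.  Gap runs
    longer than *max_gap* trigger a warning.
    """
    labels = list(sequences)
    if len(labels) < 2:
        raise AlignmentError("need at least 2 sequences to align")
    for lab in labels:
        if not sequences[lab]:
            raise AlignmentError(f"sequence {lab!r} is empty")

    pair: dict[tuple[str, str], _Pairwise] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            pair[(la, lb)] = _pairwise_align(sequences[la], sequences[lb])

    def _identity(la: str, lb: str) -> float:
        if la == lb:
            return 100.0
        return pair[(la, lb)].identity if (la, lb) in pair else pair[(lb, la)].identity

    center = max(labels, key=lambda l: (sum(_identity(l, o) for o in labels if o != l), l))
    others = [l for l in labels if l != center]
    center_seq = sequences[center]
    L = len(center_seq)

    # per-slot insertion width: slot i = gap block before center residue i (slot L = after last)
    ins = [0] * (L + 1)
    per_seq: dict[str, tuple[str, str]] = {}
    for lab in others:
        pw = pair[(center, lab)] if (center, lab) in pair else None
        if pw is None:
            rev = pair[(lab, center)]
            pw = _Pairwise(rev.aligned_b, rev.aligned_a, rev.identity)
        per_seq[lab] = (pw.aligned_a, pw.aligned_b)
        slot = 0
        run = 0
        for ch in pw.aligned_a:
            if ch == "-":
                run += 1
            else:
                ins[slot] = max(ins[slot], run)
                run = 0
                slot += 1
        ins[L] = max(ins[L], run)

    def _expand(gapped_center: str, gapped_other: str) -> str:
        """Re-pad *gapped_other* so every sequence shares the master columns."""
        out: list[str] = []
        slot = 0
        run_chars: list[str] = []
        for cc, oc in zip(gapped_center, gapped_other):
            if cc == "-":
                run_chars.append(oc)
            else:
                out.append("".join(run_chars) + "-" * (ins[slot] - len(run_chars)))
                out.append(oc)
                run_chars = []
                slot += 1
        out.append("".join(run_chars) + "-" * (ins[L] - len(run_chars)))
        return "".join(out)

    aligned: dict[str, str] = {center: _expand(center_seq, center_seq)}
    for lab in others:
        gc, go = per_seq[lab]
        aligned[lab] = _expand(gc, go)

    columns = len(next(iter(aligned.values())))
    assert all(len(s) == columns for s in aligned.values())
    _check_gap_runs(aligned, max_gap)
    pim = _identity_matrix(aligned)
    return AlignmentMap(aligned=aligned, columns=columns, pim=pim)


def _identity_matrix(aligned: Mapping[str, str]) -> pd.DataFrame:
    labels = list(aligned)
    m = np.full((len(labels), len(labels)), 100.0)
    for i, la in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lb = labels[j]
            ident = both = 0
            for x, y in zip(aligned[la], aligned[lb]):
                if x != "-" and y != "-":
                    both += 1
                    if x == y:
                        ident += 1
            pct = 100.0 * ident / both if both else 0.0
            m[i, j] = m[j, i] = pct
    return pd.DataFrame(m, index=labels, columns=labels)


def align_structures(structures: Sequence[Structure], max_gap: int = 20) -> AlignmentMap:
    """Align structure-derived sequences and attach all residue mappings."""
    seqs = {s.id: s.residue_sequence()[1] for s in structures}
    amap = align_sequences(seqs, max_gap=max_gap)
    for s in structures:
        amap.attach_structure(s)
    return amap


def import_alignment(path: str | Path, structures: Sequence[Structure]) -> AlignmentMap:
    """Import an existing MSA (PIR or aligned FASTA) and reconcile it.

    Labels must match structure ids, and each ungapped alignment sequence must
    match the structure-derived sequence; the first discrepant residue is
    named on failure.
    """
    from Bio import SeqIO

    path = Path(path)
    text = path.read_text()
    fmt = "pir" if text.lstrip().startswith(">P1;") else "fasta"
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    aligned = {r.id.split(";")[-1]: str(r.seq).replace("*", "").upper() for r in records}
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: sequences have unequal aligned lengths {sorted(lengths)}")
    columns = lengths.pop()
    amap = AlignmentMap(aligned=aligned, columns=columns, pim=_identity_matrix(aligned))
    for s in structures:
        amap.attach_structure(s)
    return amap


def write_alignment_fasta(amap: AlignmentMap, path: str | Path) -> None:
    lines = []
    for label, seq in amap.aligned.items():
        lines.append(f">{label}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping *mobile* onto *reference*.

    Returns (R, t, rmsd) with x' = R·x + t and det(R) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - cm, reference - cr
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def superpose(mobile: Structure, reference: Structure,
              amap: AlignmentMap) -> tuple[Structure, SuperpositionResult]:
    """Superpose *mobile* onto *reference* using shared-column Cα atoms.

    Every atom of the mobile structure — waters included — is carried through
    the fitted rigid transform.
    """
    def _ca_by_column(s: Structure) -> dict[int, np.ndarray]:
        rmap = amap.residue_maps.get(s.id)
        if rmap is None:
            amap.attach_structure(s)
            rmap = amap.residue_maps[s.id]
        out: dict[int, np.ndarray] = {}
        for a in s.atoms:
            if not a.is_water and a.name.strip() == "CA":
                col = rmap.get(a.residue_key)
                if col is not None:
                    out[col] = a.coords
        return out

    mob_ca = _ca_by_column(mobile)
    ref_ca = _ca_by_column(reference)
    shared = sorted(set(mob_ca) & set(ref_ca))
    if len(shared) < 3:
        raise UnderdeterminedError(
            f"only {len(shared)} shared Cα columns between {mobile.id} and "
            f"{reference.id}; need >= 3")
    P = np.array([mob_ca[c] for c in shared])
    Q = np.array([ref_ca[c] for c in shared])
    R, t, rmsd = kabsch(P, Q)
    return mobile.transformed(R, t), SuperpositionResult(R, t, rmsd, len(shared))
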