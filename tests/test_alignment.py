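"""Sequence alignment, common indexing, and Kabsch superposition."""

import itertools
import math

import numpy as np
import pytest

from aquanet.alignment import (AlignmentError, ReconciliationError,
                               UnderdeterminedError, align_sequences,
                               align_structures, import_alignment, kabsch,
                               superpose)
from aquanet.fixtures import FixtureSpec, WaterSite, make_structures


def _nw_score_oracle(seq_a: str, seq_b: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Best global alignment score by exhaustive enumeration (tiny inputs)."""
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")

    best = -math.inf
    # enumerate all gapped alignments as interleavings
    def rec(i, j, cols):
        nonlocal best
        if i == len(seq_a) and j == len(seq_b):
            score = 0.0
            run_a = run_b = 0
            for ca, cb in cols:
                if ca == "-":
                    score -= gap_open if run_a == 0 else gap_extend
                    run_a += 1
                else:
                    run_a = 0
                if cb == "-":
                    score -= gap_open if run_b == 0 else gap_extend
                    run_b += 1
                else:
                    run_b = 0
                if ca != "-" and cb != "-":
                    score += blosum[ca][cb]
            best = max(best, score)
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, cols + [(seq_a[i], seq_b[j])])
        if i < len(seq_a):
            rec(i + 1, j, cols + [(seq_a[i], "-")])
        if j < len(seq_b):
            rec(i, j + 1, cols + [("-", seq_b[j])])

    rec(0, 0, [])
    return best


class TestAlignSequences:
    def test_identical_sequences(self):
        amap = align_sequences({"a": "ACDEFG", "b": "ACDEFG"})
        assert amap.columns == 6
        assert amap.aligned["a"] == "ACDEFG"
        assert amap.aligned["b"] == "ACDEFG"
        assert amap.pim.loc["a", "b"] == pytest.approx(100.0)

    def test_single_gap_matches_exhaustive_oracle(self):
        # ACDE vs ACE: the optimal NW alignment under the stated scoring gaps
        # the D; verify both the column count and that our alignment scores
        # as well as the exhaustively enumerated optimum.
        amap = align_sequences({"long": "ACDE", "short": "ACE"})
        assert amap.columns == 4
        assert amap.aligned["long"] == "ACDE"
        assert amap.aligned["short"].count("-") == 1
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        score = 0.0
        for x, y in zip(amap.aligned["long"], amap.aligned["short"]):
            if x != "-" and y != "-":
                score += blosum[x][y]
            else:
                score -= 10.0  # single-column gap run: open penalty only
        assert score == pytest.approx(_nw_score_oracle("ACDE", "ACE"))

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_sequences({"only": "ACDE"})

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_sequences({"a": "ACDE", "b": ""})

    def test_pim_symmetric_full_diagonal(self):
        amap = align_sequences({"a": "ACDEFGHIK", "b": "ACDEFGHIK", "c": "ACDEGHIK"})
        m = amap.pim.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 100.0)

    def test_three_way_alignment_consistent_lengths(self):
        amap = align_sequences({"a": "SSSSS", "b": "SSSS", "c": "SSSSS"})
        lengths = {len(s) for s in amap.aligned.values()}
        assert lengths == {amap.columns}


class TestImportAlignment:
    def _structures(self, n=2):
        spec = FixtureSpec(n_units=n, n_residues=4, sites=[])
        return make_structures(spec)

    def test_pir_identity_mapping(self, tmp_path):
        structs = self._structures()
        pir = tmp_path / "msa.pir"
        entries = []
        for s in structs:
            entries.append(f">P1;{s.id}\nsequence:{s.id}::::::::\nSSSS*")
        pir.write_text("\n".join(entries) + "\n")
        amap = import_alignment(pir, structs)
        for s in structs:
            cols = sorted(amap.residue_maps[s.id].values())
            assert cols == [0, 1, 2, 3]

    def test_gap_column_has_no_mapping(self, tmp_path):
        spec3 = FixtureSpec(n_units=1, n_residues=3, sites=[])
        spec4 = FixtureSpec(n_units=1, n_residues=4, sites=[])
        s3 = make_structures(spec3)[0]
        s4 = make_structures(spec4)[0]
        s3.id, s4.id = "three", "four"
        fasta = tmp_path / "msa.fasta"
        fasta.write_text(">three\nSS-S\n>four\nSSSS\n")
        amap = import_alignment(fasta, [s3, s4])
        assert sorted(amap.residue_maps["three"].values()) == [0, 1, 3]
        assert sorted(amap.residue_maps["four"].values()) == [0, 1, 2, 3]

    def test_length_mismatch_names_discrepancy(self, tmp_path):
        (s,) = self._structures(1)
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(f">{s.id}\nSSS\n>other\nSSS\n")
        with pytest.raises(ReconciliationError):
            import_alignment(fasta, [s])


class TestSuperpose:
    def _aligned_pair(self):
        spec = FixtureSpec(n_units=2, n_residues=5,
                           sites=[WaterSite([0, 8, 0])], seed=3)
        structs = make_structures(spec)
        amap = align_structures(structs)
        return structs, amap

    def test_self_superposition_is_identity(self):
        structs, amap = self._aligned_pair()
        moved, res = superpose(structs[0], structs[0], amap)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_known_transform_recovered(self):
        structs, amap = self._aligned_pair()
        ref = structs[0]
        theta = math.pi / 2
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1]])
        t = np.array([5.0, 0.0, 0.0])
        mobile = ref.transformed(R, t)
        mobile.id = ref.id  # same label: identical alignment row
        moved, res = superpose(mobile, ref, amap)
        assert res.rmsd < 1e-6
        np.testing.assert_allclose(moved.coords_array(), ref.coords_array(),
                                   atol=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_underdetermined_with_two_residues(self):
        spec = FixtureSpec(n_units=2, n_residues=2, sites=[])
        structs = make_structures(spec)
        amap = align_structures(structs)
        with pytest.raises(UnderdeterminedError):
            superpose(structs[0], structs[1], amap)

    def test_superposition_never_increases_rmsd(self, rng):
        structs, amap = self._aligned_pair()
        ref = structs[0]
        for _ in range(5):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, math.pi)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
            mobile = ref.transformed(R, rng.normal(0, 3, 3))
            mobile.id = ref.id
            before = np.sqrt(np.mean(np.sum(
                (mobile.coords_array() - ref.coords_array()) ** 2, axis=1)))
            _, res = superpose(mobile, ref, amap)
            assert res.rmsd <= before + 1e-12


def test_kabsch_proper_rotation(rng):
    pts = rng.normal(size=(10, 3))
    R, t, rmsd = kabsch(pts, pts[::-1] * 0 + pts)  # identity case
    assert np.linalg.det(R) == pytest.approx(1.0)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
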