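"""Clustering, conservation scoring, angle classification, density grids."""

import math

import numpy as np
import pandas as pd
import pytest

from aquanet.conservation import (ClusterParams, ConservationParams,
                                  GeometryError, angle_records, cluster_waters,
                                  conservation_score, density_hotspots,
                                  interaction_scores, pool_positions,
                                  two_angle_classify)
from aquanet.fixtures import (FixtureSpec, WaterSite, conserved_sites_spec,
                              interaction_demo_frames, make_structures)
from aquanet.network import Interaction, build_network
from aquanet.structure_io import ActiveRegion, Atom

from conftest import waters_structure


def _points(coords, unit="s0"):
    rows = [(unit, None, i + 1, *c) for i, c in enumerate(coords)]
    df = pd.DataFrame(rows, columns=["structure_id", "frame", "serial", "x", "y", "z"])
    df["unit"] = unit
    return df


class TestPooling:
    def test_three_structures_two_waters_each(self):
        spec = FixtureSpec(n_units=3, n_residues=2,
                           sites=[WaterSite([0, 8, 0]), WaterSite([8, 8, 0])])
        nets = [build_network(s) for s in make_structures(spec)]
        points = pool_positions(nets)
        assert len(points) == 6
        assert points["unit"].nunique() == 3

    def test_empty_network_contributes_nothing(self):
        spec = FixtureSpec(n_units=1, n_residues=2, sites=[])
        nets = [build_network(s) for s in make_structures(spec)]
        assert len(pool_positions(nets)) == 0

    def test_duplicates_not_removed(self):
        spec = FixtureSpec(n_units=1, n_residues=2, sites=[WaterSite([0, 8, 0])])
        net = build_network(make_structures(spec)[0])
        assert len(pool_positions([net, net])) == 2


class TestClusterWaters:
    def test_two_blobs_centroids_are_means(self, rng):
        blob1 = rng.normal([0, 0, 0], 0.3, size=(10, 3))
        blob2 = rng.normal([8, 0, 0], 0.3, size=(10, 3))
        pts = pd.concat([_points(blob1, "a"), _points(blob2, "b")],
                        ignore_index=True)
        summary = cluster_waters(pts, ClusterParams(eps=1.5, min_samples=3))
        assert summary.n_summary == 2
        means = sorted([blob1.mean(axis=0), blob2.mean(axis=0)],
                       key=lambda m: m[0])
        got = summary.centroids[np.argsort(summary.centroids[:, 0])]
        np.testing.assert_allclose(got, means, atol=1e-9)

    def test_identical_points_single_cluster(self):
        pts = _points([[1.0, 2.0, 3.0]] * 6)
        summary = cluster_waters(pts, ClusterParams(min_samples=3))
        assert summary.n_summary == 1
        np.testing.assert_allclose(summary.centroids[0], [1, 2, 3])

    def test_full_occupancy_gives_conservation_one(self):
        spec = conserved_sites_spec(n_units=5, jitter=0.0)
        nets = [build_network(s) for s in make_structures(spec)]
        summary = cluster_waters(pool_positions(nets))
        assert summary.n_summary == 5
        np.testing.assert_allclose(summary.cluster_conservation, 1.0)

    def test_cluster_conservation_counts_structures_by_exhaustive_check(self):
        spec = conserved_sites_spec(n_units=8, jitter=0.1, presence=0.7, seed=21)
        structs = make_structures(spec)
        nets = [build_network(s) for s in structs]
        points = pool_positions(nets)
        summary = cluster_waters(points, all_units=[s.id for s in structs])
        assert summary.n_summary >= 1
        for ci, centroid in enumerate(summary.centroids):
            count = 0
            for s in structs:
                waters = np.array([a.coords for a in s.water_oxygens]).reshape(-1, 3)
                if len(waters) and np.min(
                        np.linalg.norm(waters - centroid, axis=1)) <= 1.0:
                    count += 1
            assert summary.cluster_conservation[ci] == pytest.approx(count / 8)

    def test_pairwise_conservation_on_close_sites(self):
        # two sites 1.8 Å apart (inside the 2 Å pair cutoff), both always there
        sites = [WaterSite([0, 8, 0]), WaterSite([1.8, 8, 0])]
        spec = FixtureSpec(n_units=6, n_residues=2, sites=sites)
        nets = [build_network(s) for s in make_structures(spec)]
        summary = cluster_waters(pool_positions(nets),
                                 ClusterParams(eps=0.5, min_samples=3))
        assert summary.n_summary == 2
        assert summary.pair_conservation[(0, 1)] == pytest.approx(1.0)
        assert (0, 1) in summary.edges  # 1.8 Å < H-bond cutoff

    def test_all_noise_warns_and_returns_empty(self):
        pts = _points([[0, 0, 0], [50, 0, 0], [0, 60, 0]])
        with pytest.warns(UserWarning):
            summary = cluster_waters(pts, ClusterParams(eps=0.5, min_samples=3))
        assert summary.n_summary == 0


class TestConservationScore:
    def _summary(self, centroids):
        pts = _points(np.repeat(np.asarray(centroids, float), 6, axis=0))
        return cluster_waters(pts, ClusterParams(eps=0.5, min_samples=3))

    def test_perfect_match_scores_one(self):
        centroids = [[0, 0, 0], [10, 0, 0], [0, 10, 0]]
        summary = self._summary(centroids)
        assert conservation_score(summary, np.asarray(centroids, float)) == 1.0

    def test_no_waters_scores_zero(self):
        summary = self._summary([[0, 0, 0], [10, 0, 0]])
        assert conservation_score(summary, np.empty((0, 3))) == 0.0

    def test_hand_evaluated_half_matched_case(self):
        # summary waters at 0 and 20 on x; the structure matches the first
        # (plus one extra water 3 Å away, inside the 6 Å sphere) and misses
        # the second entirely: S = (1/2)(1/(1+1)) = 0.25
        summary = self._summary([[0, 0, 0], [20, 0, 0]])
        waters = np.array([[0.2, 0, 0], [3.0, 0, 0]])
        assert conservation_score(summary, waters) == pytest.approx(0.25)

    def test_far_waters_never_change_the_score(self, rng):
        summary = self._summary([[0, 0, 0], [10, 0, 0]])
        waters = np.array([[0.1, 0, 0], [10.3, 0, 0]])
        base = conservation_score(summary, waters)
        far = rng.uniform(40, 80, size=(12, 3))
        assert conservation_score(summary, np.vstack([waters, far])) == \
            pytest.approx(base, abs=1e-12)

    def test_empty_summary_is_signaled(self):
        pts = _points([[0, 0, 0]])
        with pytest.warns(UserWarning):
            empty = cluster_waters(pts, ClusterParams(min_samples=5))
        with pytest.raises(ValueError):
            conservation_score(empty, np.zeros((1, 3)))


class TestTwoAngleClassification:
    def _interaction(self, water_pos, prot_pos):
        w = Atom(1, "O", "O", "HOH", 1, "W", water_pos, is_water=True)
        p = Atom(2, "OG", "O", "SER", 5, "A", prot_pos)
        return Interaction(w, p, "water-protein", float(np.linalg.norm(
            np.asarray(water_pos) - np.asarray(prot_pos))), protein_site="side-chain")

    @pytest.mark.parametrize("prot,ref,expected", [
        ([1, 0, 0], [-1, 0, 0], 180.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 1, 0], [1, 0, 0], 45.0),
    ])
    def test_reference_angles(self, prot, ref, expected):
        rec = two_angle_classify(self._interaction([0, 0, 0], prot), ref1=ref)
        assert rec.angle1 == pytest.approx(expected)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            two_angle_classify(self._interaction([0, 10, 0], [1, 0, 0]))
        # water sits exactly on the default reference 1 → undefined direction

    def test_water_water_rejected(self):
        w1 = Atom(1, "O", "O", "HOH", 1, "W", [0, 0, 0], is_water=True)
        w2 = Atom(2, "O", "O", "HOH", 2, "W", [3, 0, 0], is_water=True)
        with pytest.raises(ValueError):
            two_angle_classify(Interaction(w1, w2, "water-water", 3.0))

    def test_batch_records_cover_all_wp_interactions(self):
        nets = [build_network(f) for f in interaction_demo_frames(4)]
        df = angle_records(nets)
        assert len(df) == sum(n.n_wp_interactions for n in nets)
        assert ((df["angle1"] >= 0) & (df["angle1"] <= 180)).all()


class TestInteractionScores:
    def test_worked_example_one_vs_two_waters(self):
        nets = [build_network(f) for f in interaction_demo_frames(10)]
        records = interaction_scores(nets)
        assert len(records) == 2
        by_site = {(r.backbone_score > 0): r for r in records}
        always_one = by_site[False]    # side-chain contact of residue 1
        half_two = by_site[True]       # backbone contact of residue 4
        assert always_one.score == pytest.approx(1.0)
        assert always_one.mean_simultaneous == pytest.approx(1.0)
        assert half_two.score == pytest.approx(1.0)
        assert half_two.mean_simultaneous == pytest.approx(2.0)

    def test_score_is_total_over_frames(self):
        nets = [build_network(f) for f in interaction_demo_frames(8)]
        for r in interaction_scores(nets):
            assert r.score == pytest.approx(r.raw_count / len(nets))
            assert r.score == pytest.approx(r.backbone_score + r.sidechain_score)

    def test_unbound_residues_absent(self):
        nets = [build_network(f) for f in interaction_demo_frames(4)]
        records = interaction_scores(nets)
        # residues 2, 3, 5 never bind: only two records exist
        assert len(records) == 2


class TestDensityHotspots:
    def test_immobile_water_fills_one_voxel(self):
        sites = [WaterSite([0, 8, 0])]
        spec = FixtureSpec(n_units=20, n_residues=2, sites=sites)
        nets = [build_network(s) for s in make_structures(spec, source="frame")]
        grid = density_hotspots(nets, grid_spacing=0.5,
                                center=np.array([0.0, 8.0, 0.0]), radius=6.0)
        assert grid.counts.max() == 20
        assert grid.counts.sum() == 20

    def test_counts_conserved(self):
        spec = conserved_sites_spec(n_units=10, jitter=0.1)
        nets = [build_network(s) for s in make_structures(spec)]
        grid = density_hotspots(nets, grid_spacing=1.0,
                                center=np.array([9.0, 8.0, 4.5]), radius=15.0)
        in_region = 0
        for net in nets:
            pts = net.water_positions()
            d = np.linalg.norm(pts - np.array([9.0, 8.0, 4.5]), axis=1)
            in_region += int((d <= 15.0).sum())
        assert grid.counts.sum() == in_region
        assert grid.counts.sum() <= grid.n_samples

    def test_two_alternating_sites_equal_maxima(self):
        a, b = [0.0, 8.0, 0.0], [5.0, 8.0, 0.0]
        sched = [WaterSite(a, positions=[a, b] * 5)]
        spec = FixtureSpec(n_units=10, n_residues=2, sites=sched)
        nets = [build_network(s) for s in make_structures(spec, source="frame")]
        grid = density_hotspots(nets, grid_spacing=0.5,
                                center=np.array([2.5, 8.0, 0.0]), radius=6.0)
        counts = np.sort(grid.counts.ravel())[::-1]
        assert counts[0] == 5 and counts[1] == 5 and counts[2] == 0

    def test_zero_networks_rejected(self):
        with pytest.raises(ValueError):
            density_hotspots([], grid_spacing=0.5,
                             center=np.zeros(3), radius=5.0)
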