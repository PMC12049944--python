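"""Exhaustive pose scanning against a brute-force enumerator."""
import itertools
import math

import numpy as np
import pytest
from scipy import ndimage

import beltlink as bl
from beltlink.docking_scan import (
    Pose,
    Restraint,
    ScanConfig,
    ScanResult,
    accessible_interaction_space,
    flag_false_positives,
    score_fixed_pose,
    voxelize,
)
from beltlink.errors import RestraintError
from beltlink.rotations import quaternion_to_matrix, rotation_set, super_fibonacci
from beltlink.structures import ToyStructure


def structure_from_points(points, name="S"):
    pts = np.asarray(points, dtype=float)
    return ToyStructure(name, "A" * len(pts), pts)


class TestRotationSet:
    def test_unit_quaternions_and_determinism(self):
        q1, q2 = super_fibonacci(64), super_fibonacci(64)
        assert np.array_equal(q1, q2)
        assert np.allclose(np.linalg.norm(q1, axis=1), 1.0)

    def test_matrices_are_rotations(self):
        m = quaternion_to_matrix(super_fibonacci(20))
        for r in m:
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_angular_gap_shrinks_with_set_size(self):
        gaps = [rotation_set(n).max_gap for n in (24, 96, 384)]
        assert gaps[0] > gaps[1] > gaps[2] > 0


class TestVoxelize:
    def test_single_atom_single_voxel(self):
        g = voxelize(structure_from_points([[1.0, 2.0, 3.0]]), spacing=2.0)
        assert int(g.occupied.sum()) == 1

    def test_two_atoms_ten_angstroms_apart(self):
        g = voxelize(structure_from_points([[0, 0, 0], [10.0, 0, 0]]), spacing=2.0)
        idx = np.argwhere(g.occupied)
        assert len(idx) == 2
        assert abs(idx[0][0] - idx[1][0]) == 5

    def test_whole_voxel_translation_invariance(self):
        pts = np.array([[0.3, 0.7, 1.1], [4.9, 2.2, 3.3], [1.0, 5.0, 2.0]])
        g0 = voxelize(structure_from_points(pts), spacing=2.0)
        g1 = voxelize(structure_from_points(pts + np.array([4.0, -6.0, 2.0])), spacing=2.0)
        assert g0.occupied.sum() == g1.occupied.sum()
        assert np.array_equal(g0.occupied, g1.occupied)

    def test_round_trip_within_half_spacing(self, rng):
        pts = rng.uniform(-20, 20, size=(30, 3))
        g = voxelize(structure_from_points(pts), spacing=2.0)
        centers = g.index_to_world(g.world_to_index(pts))
        assert np.all(np.abs(centers - pts) <= 1.0 + 1e-12)


def brute_force_scan(fixed_pts, scan_pts, restraints, anchors_f, anchors_s,
                     config, matrices, translations):
    """Independent enumerator: plain Python loops over every pose, applying
    the documented grid-based accessibility rule and exact restraint
    distances."""
    fixed_pts = np.asarray(fixed_pts, float)
    scan_pts = np.asarray(scan_pts, float)
    c_s = scan_pts.mean(axis=0)
    scan_radius = max(np.linalg.norm(p - c_s) for p in scan_pts)
    pad = scan_radius + config.interaction_shell + config.translation_step + config.voxel_spacing
    lo = np.minimum(fixed_pts.min(axis=0), np.asarray(translations).min(axis=0)) - pad
    hi = np.maximum(fixed_pts.max(axis=0), np.asarray(translations).max(axis=0)) + pad
    grid = voxelize(fixed_pts, config.voxel_spacing, bounds=(lo, hi))
    dt = ndimage.distance_transform_edt(~grid.occupied, sampling=config.voxel_spacing)

    accessible = 0
    sat_counts = [0] * len(restraints)
    hist = [0] * (len(restraints) + 1)
    for R in matrices:
        for g in translations:
            overlap, sep = 0, math.inf
            for p in scan_pts:
                y = g + R @ (p - c_s)
                i, j, k = grid.world_to_index(y)
                if 0 <= i < grid.shape[0] and 0 <= j < grid.shape[1] and 0 <= k < grid.shape[2]:
                    overlap += bool(grid.occupied[i, j, k])
                    sep = min(sep, dt[i, j, k])
            if not (
                overlap <= config.clash_overlap_max
                and config.collision_radius <= sep <= config.interaction_shell
            ):
                continue
            accessible += 1
            nsat = 0
            for r_i, r in enumerate(restraints):
                y = g + R @ (anchors_s[r_i] - c_s)
                d = min(np.linalg.norm(y - f) for f in anchors_f[r_i])
                if d <= r.max_span:
                    sat_counts[r_i] += 1
                    nsat += 1
            hist[nsat] += 1
    cum = {n: sum(hist[n:]) for n in range(len(restraints) + 1)}
    cum[0] = accessible
    return accessible, sat_counts, cum


class TestAccessibleInteractionSpace:
    @pytest.fixture()
    def tiny_system(self):
        fixed = structure_from_points(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0], [2, 2, 3]], name="F"
        )
        scanning = structure_from_points([[0, 0, 0], [3, 0, 0], [0, 0, 3]], name="S")
        return fixed, scanning

    def test_zero_restraints_consistency_map(self, tiny_system):
        fixed, scanning = tiny_system
        cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=4, translation_step=3.0)
        res = accessible_interaction_space(fixed, scanning, [], cfg)
        assert res.complexes_consistent_with_n == {0: res.accessible_pose_count}
        assert res.accessible_pose_count > 0

    @pytest.mark.parametrize("n_rot,span", [(1, 10.0), (8, 6.0)])
    def test_matches_brute_force_enumeration(self, tiny_system, n_rot, span):
        fixed, scanning = tiny_system
        cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=n_rot, translation_step=4.0)
        restraints = [
            Restraint("F", 1, "S", 1, span),
            Restraint("F", 5, "S", 3, span * 0.75),
        ]
        rots = rotation_set(n_rot)
        axis = np.arange(-8.0, 8.1, 4.0)
        translations = np.array(list(itertools.product(axis, axis, axis)))
        res = accessible_interaction_space(
            fixed, scanning, restraints, cfg, rotations=rots, translations=translations
        )
        F = fixed.coords
        S = scanning.coords
        anchors_f = [np.array([F[0]]), np.array([F[4]])]
        anchors_s = [S[0], S[2]]
        acc, sat, cum = brute_force_scan(
            F, S, restraints, anchors_f, anchors_s, cfg, rots.matrices, translations
        )
        assert res.accessible_pose_count == acc
        assert list(res.satisfied_counts) == sat
        assert res.complexes_consistent_with_n == cum

    def test_consistency_map_non_increasing(self, tiny_system):
        fixed, scanning = tiny_system
        cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=8, translation_step=4.0)
        restraints = [Restraint("F", i + 1, "S", 1, 8.0) for i in range(4)]
        res = accessible_interaction_space(fixed, scanning, restraints, cfg)
        values = [res.complexes_consistent_with_n[n] for n in range(5)]
        assert values == sorted(values, reverse=True)
        assert all(v <= res.accessible_pose_count for v in values)

    def test_impossible_restraint_zeroes_top_count(self):
        """Five satisfiable restraints plus one that no accessible pose can
        satisfy: N=6 empty, N=5 populated."""
        ring = structure_from_points(
            [[10 * np.cos(t), 10 * np.sin(t), 0] for t in np.linspace(0, 2 * np.pi, 12, endpoint=False)],
            name="F",
        )
        probe = structure_from_points([[0, 0, 0], [0, 0, 4]], name="S")
        restraints = [Restraint("F", i + 1, "S", 1, 40.0, label=f"ok{i}") for i in range(5)]
        restraints.append(Restraint("F", 1, "S", 1, 0.1, label="impossible"))
        cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=6, translation_step=4.0)
        res = accessible_interaction_space(ring, probe, restraints, cfg)
        assert res.complexes_consistent_with_n[6] == 0
        assert res.complexes_consistent_with_n[5] >= 1

    def test_joint_whole_voxel_shift_invariance(self, tiny_system):
        fixed, scanning = tiny_system
        cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=4, translation_step=4.0)
        restraints = [Restraint("F", 1, "S", 1, 8.0)]
        axis = np.arange(-8.0, 8.1, 4.0)
        base = np.array(list(itertools.product(axis, axis, axis)))
        shift = np.array([4.0, -8.0, 4.0])  # whole voxels and whole steps
        shifted_fixed = structure_from_points(fixed.coords + shift, name="F")
        r1 = accessible_interaction_space(
            fixed, scanning, restraints, cfg, translations=base
        )
        r2 = accessible_interaction_space(
            shifted_fixed, scanning, restraints, cfg, translations=base + shift
        )
        assert r1.accessible_pose_count == r2.accessible_pose_count
        assert list(r1.satisfied_counts) == list(r2.satisfied_counts)

    def test_finer_rotation_set_finds_no_fewer_consistent_poses(self):
        fixed = structure_from_points([[0, 0, 0], [5, 0, 0], [0, 5, 0]], name="F")
        scanning = structure_from_points([[0, 0, 0], [4, 0, 0]], name="S")
        restraints = [Restraint("F", 1, "S", 2, 7.0), Restraint("F", 2, "S", 1, 7.0)]

        def max_n(n_rot):
            cfg = ScanConfig(voxel_spacing=2.0, rotation_set_size=n_rot, translation_step=3.0)
            res = accessible_interaction_space(fixed, scanning, restraints, cfg)
            return max(
                (n for n, c in res.complexes_consistent_with_n.items() if c > 0), default=0
            )

        assert max_n(16) >= max_n(8)

    def test_missing_restraint_residue_rejected_before_scan(self, tiny_system):
        fixed, scanning = tiny_system
        with pytest.raises(RestraintError):
            accessible_interaction_space(
                fixed, scanning, [Restraint("F", 99, "S", 1, 10.0)],
                ScanConfig(rotation_set_size=1),
            )


class TestFlagFalsePositives:
    def _result_with_fractions(self, fractions):
        n = len(fractions)
        restraints = [Restraint("F", i + 1, "S", 1, 10.0, label=f"r{i}") for i in range(n)]
        return ScanResult(
            accessible_pose_count=1000,
            total_pose_count=2000,
            complexes_consistent_with_n={0: 1000},
            restraints=restraints,
            satisfied_counts=np.round(np.asarray(fractions) * 1000).astype(int),
            rotation_max_gap=1.0,
            config=ScanConfig(),
        )

    def test_low_outlier_flagged(self):
        res = self._result_with_fractions([0.6] * 5 + [0.55, 0.65, 0.6, 0.62] + [0.01])
        report = flag_false_positives(res)
        assert [r.label for r in report.flagged] == ["r9"]

    def test_uniform_fractions_nothing_flagged(self):
        res = self._result_with_fractions([0.5] * 6)
        report = flag_false_positives(res)
        assert report.flagged == [] and report.degenerate_sd

    def test_needs_two_restraints(self):
        res = self._result_with_fractions([0.5])
        with pytest.raises(ValueError):
            flag_false_positives(res)

    def test_scene_false_positives_recovered(self):
        """One planted-truth scene: both buried-bead restraints flagged, no
        belt-facing restraint flagged."""
        scene = bl.make_belt_lcat_scene(seed=3)
        cfg = ScanConfig(
            voxel_spacing=3.0, rotation_set_size=16, translation_step=5.0,
            interaction_shell=8.0, collision_radius=5.0,
        )
        res = accessible_interaction_space(scene.fixed, scene.decoy, scene.restraints, cfg)
        report = flag_false_positives(res)
        flagged = {r.label for r in report.flagged}
        assert {r.label for r in scene.fp_restraints} <= flagged
        assert sum(1 for lbl in flagged if lbl.startswith("true")) <= 1


class TestScoreFixedPose:
    def test_planted_scene_pose_satisfies_all_true_restraints(self):
        scene = bl.make_belt_lcat_scene(seed=1)
        score = score_fixed_pose(
            scene.fixed, scene.decoy, scene.planted_pose, scene.true_restraints
        )
        assert score.n_satisfied == len(scene.true_restraints)
        assert score.total_violation == 0.0

    def test_translation_grows_distances_by_at_most_shift(self):
        scene = bl.make_belt_lcat_scene(seed=1)
        base = score_fixed_pose(
            scene.fixed, scene.decoy, scene.planted_pose, scene.restraints
        )
        moved = Pose(
            rotation=scene.planted_pose.rotation,
            translation=scene.planted_pose.translation + np.array([10.0, 0, 0]),
        )
        shifted = score_fixed_pose(scene.fixed, scene.decoy, moved, scene.restraints)
        assert np.all(shifted.distances - base.distances <= 10.0 + 1e-9)
        assert np.all(base.distances - shifted.distances <= 10.0 + 1e-9)

    def test_candidate_built_to_satisfy_restraints_wins(self):
        scene = bl.make_belt_lcat_scene(seed=2)
        good = score_fixed_pose(
            scene.fixed, scene.decoy, scene.planted_pose, scene.true_restraints
        )
        # a decoy rotated 180° about z at the same centroid: wrong face
        flipped = Pose(
            rotation=np.diag([-1.0, -1.0, 1.0]),
            translation=scene.planted_pose.translation,
        )
        bad = score_fixed_pose(scene.fixed, scene.decoy, flipped, scene.true_restraints)
        assert good.n_satisfied > bad.n_satisfied
        assert good.total_violation < bad.total_violation
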