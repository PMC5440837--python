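"""Kabsch superposition, helix-axis fitting, clash counting, the rotation
scan, and the full template-guided dock."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from groovedock import synthetic_data as sd
from groovedock.docking import (
    ClashParams,
    GrooveOccludedError,
    RigidTransform,
    count_clashes,
    fit_helix_axis,
    kabsch,
    rotation_about_axis,
    rotation_scan,
    strip_side_chains,
    template_guided_dock,
)
from groovedock.structio import Atom, Structure


def cloud(rng, n=20):
    return rng.normal(size=(n, 3)) * 5.0


def as_structure(coords, chain="A", name="CA"):
    atoms = [
        Atom(name, "C", c, i + 1, "ALA", chain) for i, c in enumerate(np.atleast_2d(coords))
    ]
    return Structure(atoms)


class TestRigidTransform:
    def test_identity_and_compose_inverse(self, rng):
        t = rotation_about_axis(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 1.0]), 73.0)
        pts = cloud(rng)
        round_trip = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(round_trip, pts, atol=1e-10)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        pts = cloud(rng)
        t, rmsd = kabsch(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_transform(self, rng):
        pts = cloud(rng)
        true_rot = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        target = pts @ true_rot.T + np.array([1.0, 2.0, 3.0])
        t, rmsd = kabsch(pts, target)
        assert rmsd < 1e-8
        np.testing.assert_allclose(t.rotation, true_rot, atol=1e-8)
        np.testing.assert_allclose(t.apply(pts), target, atol=1e-8)

    def test_mirror_target_never_reflected(self, rng):
        pts = cloud(rng)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        t, rmsd = kabsch(pts, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-8)
        assert rmsd > 0.1

    def test_matches_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's weighted Wahba solution on centred sets."""
        for _ in range(10):
            pts = cloud(rng, 15)
            target = cloud(rng, 15)
            t, rmsd = kabsch(pts, target)
            rot, rssd = Rotation.align_vectors(
                target - target.mean(axis=0), pts - pts.mean(axis=0)
            )
            np.testing.assert_allclose(t.rotation, rot.as_matrix(), atol=1e-8)
            assert rmsd == pytest.approx(rssd / np.sqrt(len(pts)), abs=1e-8)

    def test_optimality_beats_random_rotations(self, rng):
        for _ in range(20):
            pts = cloud(rng, 12)
            target = cloud(rng, 12)
            _, best = kabsch(pts, target)
            c_p = pts - pts.mean(axis=0)
            c_q = target - target.mean(axis=0)
            for rot in Rotation.random(100, rng=rng):
                trial = np.sqrt(np.mean(np.sum((c_p @ rot.as_matrix().T - c_q) ** 2, axis=1)))
                assert best <= trial + 1e-9

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            kabsch(cloud(rng, 5), cloud(rng, 6))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)


class TestHelixAxis:
    def test_ideal_helix_axis_is_z(self):
        helix = sd.build_ideal_helix(sd.HelixSpec(n_residues=20))
        point, direction = fit_helix_axis(helix.ca_coords())
        np.testing.assert_allclose(direction, [0, 0, 1], atol=1e-3)
        assert np.linalg.norm(direction) == pytest.approx(1.0, abs=1e-12)

    def test_equivariance_under_rotation(self, rng):
        helix = sd.build_ideal_helix(sd.HelixSpec(n_residues=20))
        rot = Rotation.random(rng=rng).as_matrix()
        _, d0 = fit_helix_axis(helix.ca_coords())
        _, d1 = fit_helix_axis(helix.ca_coords() @ rot.T)
        np.testing.assert_allclose(d1, rot @ d0, atol=1e-3)

    def test_orientation_follows_chain_direction(self):
        spec = sd.HelixSpec(n_residues=20, axis_direction=(0.0, 0.0, -1.0),
                            axis_point=(0.0, 0.0, 10.0))
        helix = sd.build_ideal_helix(spec)
        _, direction = fit_helix_axis(helix.ca_coords())
        assert direction[2] < 0  # N-to-C points down

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            fit_helix_axis(np.zeros((3, 3)))


class TestClashes:
    def test_pair_inside_cutoff_counts(self):
        a = as_structure([[0.0, 0, 0]])
        b = as_structure([[2.0, 0, 0]], chain="B")
        assert count_clashes(a, b, ClashParams(cutoff=2.5)) == 1

    def test_boundary_distance_is_not_a_clash(self):
        a = as_structure([[0.0, 0, 0]])
        b = as_structure([[2.5, 0, 0]], chain="B")
        assert count_clashes(a, b, ClashParams(cutoff=2.5)) == 0

    def test_hydrogens_ignored(self):
        a = Structure([Atom("H1", "H", np.zeros(3), 1, "ALA", "A")])
        b = as_structure([[1.0, 0, 0]], chain="B")
        assert count_clashes(a, b) == 0

    def test_grid_vs_brute_force_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(-10, 10, size=(100, 3))
            b = rng.uniform(-10, 10, size=(100, 3))
            sa, sb = as_structure(a), as_structure(b, chain="B")
            expected = int(
                np.sum(np.linalg.norm(a[:, None] - b[None, :], axis=2) < 2.5)
            )
            assert count_clashes(sa, sb, ClashParams(cutoff=2.5)) == expected

    def test_symmetry(self, rng):
        a = as_structure(rng.uniform(-5, 5, size=(50, 3)))
        b = as_structure(rng.uniform(-5, 5, size=(50, 3)), chain="B")
        assert count_clashes(a, b) == count_clashes(b, a)


class TestRotationScan:
    def test_profile_length(self, planted, receptor):
        axis = (np.array([0.0, 0, 0]), np.array([0.0, 0, 1.0]))
        probe = as_structure([[50.0, 0, 0]])
        _, profile = rotation_scan(probe, axis, planted.receptor, step=5.0)
        assert len(profile) == 72

    def test_step_must_divide_360(self, planted):
        axis = (np.zeros(3), np.array([0.0, 0, 1.0]))
        with pytest.raises(ValueError):
            rotation_scan(as_structure([[50.0, 0, 0]]), axis, planted.receptor, step=7.0)

    def test_clash_free_construction_wins(self):
        # receptor atoms everywhere except near angle 0
        axis = (np.zeros(3), np.array([0.0, 0, 1.0]))
        angles = np.deg2rad(np.arange(30, 331, 5))
        blockers = np.column_stack(
            [10 * np.cos(angles), 10 * np.sin(angles), np.zeros(len(angles))]
        )
        receptor = as_structure(blockers, chain="R")
        probe = as_structure([[10.0, 0, 0]])
        best, profile = rotation_scan(probe, axis, receptor, step=1.0,
                                      p=ClashParams(cutoff=2.0))
        assert profile[0][1] == 0
        assert best == 0.0


class TestTemplateGuidedDock:
    def dock(self, pair, scene, receptor, query=None, **kw):
        return template_guided_dock(
            template=pair.long.structure,
            filler=pair.filler,
            query=query if query is not None else pair.short.structure,
            receptor=scene.receptor,
            target_m4=receptor.m4_segments[0],
            **kw,
        )

    def test_recovers_planted_angle_and_pose(self, pair, receptor, planted):
        result = self.dock(pair, planted, receptor)
        assert result.best_angle == pytest.approx(40.0, abs=1.0)
        docked = result.transform.apply_structure(pair.short.structure)
        rmsd = np.sqrt(np.mean(np.sum((docked.coords - planted.bundle.coords) ** 2, axis=1)))
        assert rmsd < 1.0

    def test_result_invariants(self, pair, receptor, planted):
        result = self.dock(pair, planted, receptor)
        counts = [c for _, c in result.scan]
        assert min(counts) == counts[int(result.best_angle)]
        assert any(a == result.best_angle for a, _ in result.scan)
        assert len(result.scan) == 360

    def test_docked_template_filler_lands_on_m4_axis(self, pair, receptor, planted):
        """The mapped filler helix occupies the target M4 position: its axis
        coincides with the M4 axis (the residual spin about that axis is the
        scanned degree of freedom)."""
        from groovedock.structio import select

        result = self.dock(pair, planted, receptor)
        filler = select(pair.long.structure, pair.filler.chain_id, pair.filler)
        moved = result.transform.apply(filler.ca_coords())
        m4 = select(planted.receptor, receptor.m4_segments[0].chain_id,
                    receptor.m4_segments[0]).ca_coords()
        p_f, d_f = fit_helix_axis(moved)
        p_m, d_m = fit_helix_axis(m4)
        assert abs(np.dot(d_f, d_m)) > 1 - 1e-6
        offset = (p_f - p_m) - np.dot(p_f - p_m, d_m) * d_m
        assert np.linalg.norm(offset) < 0.1

    def test_long_query_raises_groove_occluded(self, pair, receptor, planted):
        with pytest.raises(GrooveOccludedError):
            self.dock(pair, planted, receptor, query=pair.long.structure)

    def test_rigid_invariance(self, pair, receptor, planted, rng):
        result = self.dock(pair, planted, receptor)
        motion = rotation_about_axis(
            rng.normal(size=3), rng.normal(size=3), float(rng.uniform(0, 360))
        )
        moved_template = motion.apply_structure(pair.long.structure)
        moved_query = motion.apply_structure(pair.short.structure)
        moved_receptor = motion.apply_structure(planted.receptor)
        moved_result = template_guided_dock(
            template=moved_template,
            filler=pair.filler,
            query=moved_query,
            receptor=moved_receptor,
            target_m4=receptor.m4_segments[0],
        )
        assert moved_result.best_angle == result.best_angle
        assert [c for _, c in moved_result.scan] == [c for _, c in result.scan]
        # final relative pose agrees: map both docked queries back into the
        # receptor frame of the unmoved scene
        docked = result.transform.apply(pair.short.structure.coords)
        docked_moved = motion.inverse().apply(
            moved_result.transform.apply(moved_query.coords)
        )
        np.testing.assert_allclose(docked_moved, docked, atol=1e-6)

    def test_determinism_under_atom_order(self, pair, receptor, planted, rng):
        perm = rng.permutation(len(pair.short.structure.atoms))
        shuffled = Structure([pair.short.structure.atoms[i] for i in perm])
        a = self.dock(pair, planted, receptor)
        b = self.dock(pair, planted, receptor, query=shuffled)
        assert a.best_angle == b.best_angle
        assert [c for _, c in a.scan] == [c for _, c in b.scan]


class TestStripSideChains:
    def test_side_chains_removed(self):
        names = ["N", "CA", "C", "O", "CB", "CG", "CD1", "OE1"]
        atoms = [Atom(n, n[0], np.array([float(i), 0, 0]), 1, "GLU", "A")
                 for i, n in enumerate(names)]
        stripped = strip_side_chains(Structure(atoms))
        assert [a.name for a in stripped.atoms] == ["N", "CA", "C", "O", "CB"]

    def test_identity_on_reduced_models(self, pair):
        stripped = strip_side_chains(pair.short.structure)
        assert len(stripped) == len(pair.short.structure)

    def test_never_grows(self, receptor):
        assert len(strip_side_chains(receptor.structure)) <= len(receptor.structure)
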