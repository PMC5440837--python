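"""Generators: ideal helices, bundles, the receptor fixture, planted scenes,
image and intensity-table simulators."""

import numpy as np
import pytest

from groovedock import synthetic_data as sd
from groovedock.bifc import classify, BiFCRecord
from groovedock.docking import ClashParams, count_clashes, rotation_about_axis
from groovedock.structio import select


class TestIdealHelix:
    def test_z_spacing_follows_rise(self):
        helix = sd.build_ideal_helix(sd.HelixSpec(n_residues=10))
        z = helix.ca_coords()[:, 2]
        np.testing.assert_allclose(z, np.arange(10) * 1.5, atol=1e-12)

    def test_azimuth_period_18_residues(self):
        helix = sd.build_ideal_helix(sd.HelixSpec(n_residues=24))
        ca = helix.ca_coords()
        # 18 * 100 deg = 5 full turns: same azimuth
        np.testing.assert_allclose(ca[0][:2], ca[18][:2], atol=1e-9)

    def test_all_pairwise_distances_match_closed_form(self):
        spec = sd.HelixSpec(n_residues=12)
        ca = sd.build_ideal_helix(spec).ca_coords()
        for i in range(12):
            for j in range(i + 1, 12):
                k = j - i
                expected = np.sqrt(
                    (k * spec.rise) ** 2
                    + 2 * spec.helix_radius**2
                    * (1 - np.cos(np.deg2rad(k * spec.twist)))
                )
                assert np.linalg.norm(ca[j] - ca[i]) == pytest.approx(expected, abs=1e-9)

    def test_pseudo_cb_radially_outward(self):
        spec = sd.HelixSpec(n_residues=5)
        helix = sd.build_ideal_helix(spec)
        ca = [a for a in helix.atoms if a.name == "CA"]
        cb = [a for a in helix.atoms if a.name == "CB"]
        for a, b in zip(ca, cb):
            assert np.linalg.norm(b.position - a.position) == pytest.approx(1.5)
            # CB farther from the axis (z axis here) than CA
            assert np.hypot(*b.position[:2]) > np.hypot(*a.position[:2])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sd.HelixSpec(n_residues=3)
        with pytest.raises(ValueError):
            sd.HelixSpec(n_residues=10, rise=-1.0)
        with pytest.raises(ValueError):
            sd.HelixSpec(n_residues=10, axis_direction=(0, 0, 2))


class TestBundles:
    def test_gap_bundle_has_11_helices(self):
        bundle = sd.build_bundle(sd.ring_bundle_spec())
        assert len(bundle.helices) == 11

    def test_full_ring_has_12(self):
        bundle = sd.build_bundle(sd.ring_bundle_spec(gap_index=None))
        assert len(bundle.helices) == 12

    def test_min_inter_axis_distance_is_ring_chord(self):
        spec = sd.ring_bundle_spec(gap_index=None)
        centres = np.array([p.spec.axis_point[:2] for p in spec.placements])
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
        d[d == 0] = np.inf
        expected = 2 * spec.ring_radius * np.sin(np.pi / 12)
        assert d.min() == pytest.approx(expected, rel=1e-9)

    def test_overlapping_helices_rejected(self):
        spec = sd.ring_bundle_spec(ring_radius=2.0, gap_index=None)
        with pytest.raises(ValueError, match="overlap"):
            sd.build_bundle(spec)


class TestLongShortPair:
    def test_shared_atoms_superpose_exactly(self, pair):
        short_keys = {a.key: a.position for a in pair.short.structure.atoms}
        for atom in pair.long.structure.atoms:
            if atom.key in short_keys:
                np.testing.assert_array_equal(atom.position, short_keys[atom.key])

    def test_atom_difference_is_three_extra_helices(self, pair):
        diff = len(pair.long.structure) - len(pair.short.structure)
        extras = [seg for seg in pair.long.helices
                  if seg.label in ("TMF", "TMX1", "TMX2")]
        assert len(extras) == 3
        n_extra = sum(
            2 * (seg.end - seg.start + 1) for seg in extras  # CA + CB per residue
        )
        assert diff == n_extra

    def test_filler_sits_at_groove_mouth(self, pair):
        filler = select(pair.long.structure, pair.filler.chain_id, pair.filler)
        centroid = filler.ca_coords().mean(axis=0)
        ring_radius = pair.short.spec.ring_radius
        assert np.hypot(centroid[0], centroid[1]) <= ring_radius + 1e-6


class TestReceptorFixture:
    def test_m4_axes_are_most_distant_and_m2_closest(self, receptor):
        from groovedock.structio import HelixSegment as HS

        radii = {}
        for chain in "ABCD":
            for name, (start, n) in {
                "M1": (700, 24), "M2": (740, 18), "M3": (770, 24), "M4": (813, 24),
            }.items():
                helix = select(receptor.structure, chain, HS(chain, start, start + n - 1))
                centroid = helix.ca_coords().mean(axis=0)
                radii.setdefault(name, []).append(np.hypot(centroid[0], centroid[1]))
        assert min(radii["M4"]) > max(v for n in ("M1", "M2", "M3") for v in radii[n])
        assert max(radii["M2"]) < min(v for n in ("M1", "M3", "M4") for v in radii[n])

    def test_fourfold_symmetry(self, receptor):
        rot = rotation_about_axis(np.zeros(3), np.array([0.0, 0.0, 1.0]), 90.0)
        chains = "ABCD"
        for k in range(4):
            src = select(receptor.structure, chains[k])
            dst = select(receptor.structure, chains[(k + 1) % 4])
            moved = rot.apply(src.coords)
            rmsd = np.sqrt(np.mean(np.sum((moved - dst.coords) ** 2, axis=1)))
            assert rmsd < 1e-6

    def test_m4_segment_is_registered_landmark(self, receptor):
        seg = receptor.m4_segments[0]
        assert (seg.start, seg.end) == (813, 836)


class TestPlantedScene:
    def test_ground_truth_reproduces_scene(self, pair, receptor, planted):
        rebuilt = planted.ground_truth.apply_structure(pair.short.structure)
        np.testing.assert_allclose(rebuilt.coords, planted.bundle.coords, atol=1e-9)

    def test_no_hard_clashes(self, planted):
        assert count_clashes(planted.bundle, planted.receptor, ClashParams(cutoff=2.0)) == 0

    def test_deterministic(self, pair, receptor):
        a = sd.plant_complex(pair, receptor, true_angle=123.0)
        b = sd.plant_complex(pair, receptor, true_angle=123.0)
        np.testing.assert_array_equal(a.bundle.coords, b.bundle.coords)
        np.testing.assert_array_equal(a.receptor.coords, b.receptor.coords)


class TestColocSimulator:
    def test_full_coloc_no_noise_channels_identical(self):
        cells = sd.simulate_coloc_images(
            sd.ColocSimParams(n_cells=2, coloc_fraction=1.0, noise_model="none", seed=3)
        )
        for cell in cells:
            np.testing.assert_allclose(cell.image.ch1, cell.image.ch2)

    def test_same_seed_bit_identical(self):
        p = sd.ColocSimParams(n_cells=3, coloc_fraction=0.4, seed=9)
        a = sd.simulate_coloc_images(p)
        b = sd.simulate_coloc_images(p)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.image.ch1, cb.image.ch1)
            np.testing.assert_array_equal(ca.image.ch2, cb.image.ch2)

    def test_truth_carried_per_cell(self):
        cells = sd.simulate_coloc_images(sd.ColocSimParams(n_cells=2, coloc_fraction=0.25, seed=1))
        assert all(c.true_coloc_fraction == 0.25 for c in cells)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sd.ColocSimParams(coloc_fraction=1.5)


class TestBiFCSimulator:
    @pytest.mark.parametrize(
        "fold,expected_positive",
        [(5.0, True), (1.0, False), (3.5, False)],  # strict '>' at the boundary
    )
    def test_noise_free_classification(self, fold, expected_positive):
        table = sd.simulate_bifc(
            sd.BiFCSimParams(n_cells=5, reporter_fold=fold, noise_cv=0.0, seed=0)
        )
        for _, row in table.iterrows():
            rec = BiFCRecord(row.cell_id, row.group, row.background, row.cy3, row.venus)
            _, venus_positive = classify(rec)
            assert venus_positive == expected_positive

    def test_deterministic(self):
        p = sd.BiFCSimParams(n_cells=10, reporter_fold=2.0, seed=5)
        a = sd.simulate_bifc(p)
        b = sd.simulate_bifc(p)
        assert a.equals(b)
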