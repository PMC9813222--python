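"""Simulator: model-tip rasterization, vdW surfaces, rotations, datasets."""

import math

import numpy as np
import pytest

import blindtip as bt
from blindtip.simulate import _tip_profile

from conftest import brute_sphere_heights


class TestModelTip:
    def test_apex_and_branch_continuity(self):
        r, th = 2.5, 10.0
        assert _tip_profile(np.array([0.0]), r, th)[0] == 0.0
        join = r * math.cos(math.radians(th))
        lo, hi = _tip_profile(np.array([join - 1e-9, join + 1e-9]), r, th)
        assert abs(lo - hi) < 1e-6
        assert abs(lo - (r - r * math.sin(math.radians(th)))) < 1e-6

    def test_grid_matches_scalar_oracle(self, truth_tip):
        # independent scalar evaluation of the two-branch profile per pixel
        r, th_deg, px = 2.5, 10.0, 1.5
        th = math.radians(th_deg)
        for (rr, cc), val in np.ndenumerate(truth_tip.p):
            d = math.hypot((rr - 5) * px, (cc - 5) * px)
            if d <= r * math.cos(th):
                t = r - math.sqrt(r**2 - d**2)
            else:
                t = r - r * math.sin(th) + (d - r * math.cos(th)) / math.tan(th)
            assert val == pytest.approx(-t, abs=1e-12)

    def test_apex_value_zero_and_nonpositive(self, truth_tip):
        assert truth_tip.p[truth_tip.origin_index] == 0.0
        assert truth_tip.p.max() == 0.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            bt.TipSpec(apex_radius=-1.0)
        with pytest.raises(ValueError):
            bt.TipSpec(half_angle=95.0)


class TestDoubleTip:
    def test_zero_offset_equals_single(self):
        spec = bt.TipSpec()
        np.testing.assert_array_equal(
            bt.make_double_tip(spec, offset_px=0, grid_shape=(10, 10)).p,
            bt.make_tip(spec).p,
        )

    def test_two_apex_maxima_along_x(self):
        tip = bt.make_double_tip(bt.TipSpec(), offset_px=4)
        assert tip.shape == (10, 14)
        row = tip.p[tip.origin_index[0]]
        peaks = [
            c
            for c in range(1, len(row) - 1)
            if row[c] == 0.0 and row[c] >= row[c - 1] and row[c] >= row[c + 1]
        ]
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == 4

    def test_pixelwise_max_of_components(self):
        spec = bt.TipSpec()
        tip = bt.make_double_tip(spec, offset_px=4, grid_shape=(10, 14))
        spec14 = bt.TipSpec(grid_shape=(10, 14))
        left = bt.make_tip(spec14, origin_index=(5, 5)).p
        right = bt.make_tip(spec14, origin_index=(5, 9)).p
        np.testing.assert_allclose(tip.p, np.maximum(left, right), atol=1e-12)

    def test_apex_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            bt.make_double_tip(bt.TipSpec(), offset_px=30, grid_shape=(10, 14))


class TestRandomRotation:
    def test_deterministic_and_orthonormal(self):
        R1 = bt.random_rotation(np.random.default_rng(5))
        R2 = bt.random_rotation(np.random.default_rng(5))
        np.testing.assert_array_equal(R1, R2)
        np.testing.assert_allclose(R1 @ R1.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(R1) == pytest.approx(1.0, abs=1e-10)

    def test_uniformity_mean_of_rotated_vector(self):
        rng = np.random.default_rng(99)
        n = 20_000
        v = np.array([1.0, 0.0, 0.0])
        mean = np.mean([bt.random_rotation(rng) @ v for _ in range(n)], axis=0)
        assert np.linalg.norm(mean) < 4.0 / np.sqrt(n)


class TestSurfaceFromAtoms:
    def test_single_atom_top_of_sphere(self):
        atoms = bt.AtomSet([[0.0, 0.0, 1.0]], [1.0])
        surf = bt.surface_from_atoms(atoms, np.eye(3), grid_shape=(5, 5), pixel_size=1.0)
        # resting on the stage: sphere bottom at z=0, top at z=2
        assert surf.heights[2, 2] == pytest.approx(2.0)
        assert surf.heights[0, 0] == 0.0  # farther than the radius: stage level

    def test_matches_per_atom_oracle(self, rng):
        xyz = rng.uniform(-2, 2, size=(12, 3))
        atoms = bt.AtomSet(xyz, rng.uniform(0.5, 1.2, size=12))
        R = bt.random_rotation(rng)
        surf = bt.surface_from_atoms(atoms, R, grid_shape=(8, 8), pixel_size=1.0)
        com = atoms.coordinates.mean(axis=0)
        rot = (atoms.coordinates - com) @ R.T
        rot[:, 2] -= (rot[:, 2] - atoms.radii).min()
        placed = bt.AtomSet(rot, atoms.radii)
        np.testing.assert_allclose(
            surf.heights, brute_sphere_heights(placed, (8, 8), 1.0), atol=1e-12
        )

    def test_non_orthonormal_rotation_rejected(self):
        atoms = bt.AtomSet([[0.0, 0.0, 0.0]], [1.0])
        with pytest.raises(ValueError):
            bt.surface_from_atoms(atoms, np.diag([2.0, 1.0, 1.0]))


class TestBlobAtoms:
    def test_reproducible_and_above_stage(self):
        a = bt.make_blob_atoms(n_atoms=500, rng=3)
        b = bt.make_blob_atoms(n_atoms=500, rng=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        surf = bt.surface_from_atoms(a, np.eye(3), (20, 20), 1.0)
        assert surf.heights.max() > 1.0  # the globule rises above the stage

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bt.make_blob_atoms(n_atoms=0)


class TestGenerateDataset:
    def test_noise_free_frames_equal_dilated_truth(self, tiny_dataset):
        for frame, clean in zip(tiny_dataset.frames, tiny_dataset.truth.clean_images):
            np.testing.assert_array_equal(frame.heights, clean.heights)
        for frame, surf in zip(tiny_dataset.frames, tiny_dataset.truth.surfaces):
            np.testing.assert_array_equal(
                frame.heights, bt.dilate(surf, tiny_dataset.truth.tip).heights
            )

    def test_opening_identity_round_trip(self, tiny_dataset):
        tip = tiny_dataset.truth.tip
        for frame in tiny_dataset.frames:
            opened, _ = bt.opening(frame, tip)
            np.testing.assert_allclose(opened.heights, frame.heights, atol=1e-12)

    def test_erosion_bounds_truth_surface(self, tiny_dataset):
        tip = tiny_dataset.truth.tip
        for frame, surf in zip(tiny_dataset.frames, tiny_dataset.truth.surfaces):
            rec = bt.erode(frame, tip)
            assert np.all(rec.heights >= surf.heights - 1e-12)

    def test_noise_standard_deviation(self, blob_atoms):
        tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
        ds = bt.generate_dataset(
            blob_atoms, tip, n_frames=20, grid_shape=(30, 30), sigma=0.3, seed=8
        )
        resid = np.concatenate(
            [
                (fr.heights - cl.heights).ravel()
                for fr, cl in zip(ds.frames, ds.truth.clean_images)
            ]
        )
        assert resid.std() == pytest.approx(0.3, rel=0.05)

    def test_bit_identical_regeneration(self, blob_atoms):
        tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
        kw = dict(n_frames=3, grid_shape=(16, 16), sigma=0.5, seed=13)
        d1 = bt.generate_dataset(blob_atoms, tip, **kw)
        d2 = bt.generate_dataset(blob_atoms, tip, **kw)
        for f1, f2 in zip(d1.frames, d2.frames):
            np.testing.assert_array_equal(f1.heights, f2.heights)

    def test_frame_k_independent_of_n_frames(self, blob_atoms):
        tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
        d3 = bt.generate_dataset(blob_atoms, tip, n_frames=3, grid_shape=(16, 16), sigma=0.2, seed=9)
        d5 = bt.generate_dataset(blob_atoms, tip, n_frames=5, grid_shape=(16, 16), sigma=0.2, seed=9)
        np.testing.assert_array_equal(d3.frames[2].heights, d5.frames[2].heights)

    def test_invalid_sigma(self, blob_atoms):
        tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
        with pytest.raises(ValueError):
            bt.generate_dataset(blob_atoms, tip, n_frames=1, sigma=-0.1)
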