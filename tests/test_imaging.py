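"""Pair-axis transform, windowed intensity sampling, synthetic stacks."""

import numpy as np
import pytest

from ecmcomm import comms
from ecmcomm.imaging import (
    ImageStack,
    WindowSpecExp,
    track_cells,
    compute_pair_transform,
    sample_window_intensity,
    window_intensity_series,
    quantify_pair_series,
    apply_normalization_border,
    background_zscore_experiment,
    single_cell_orientations,
    synthesize_stack,
    _sample_box,
)

VOX = (2.0, 0.41, 0.41)


class TestPairTransform:
    def test_round_trip_recovers_points_to_nanometer_precision(self):
        rng = np.random.default_rng(0)
        a = np.array([10.0, 20.0, 8.0])
        b = np.array([55.0, 47.0, 20.0])
        tr = compute_pair_transform(a, b, VOX)
        pts = rng.uniform(0, 60, (50, 3))
        back = tr.to_physical(tr.to_pair(pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_axes_are_orthonormal(self):
        tr = compute_pair_transform([0, 0, 0], [30, 14, 9], VOX)
        assert np.allclose(tr.basis @ tr.basis.T, np.eye(3), atol=1e-12)

    def test_lateral_pair_resolutions(self):
        # theta = 0: connecting axis keeps the lateral resolution
        tr = compute_pair_transform([0, 0, 5], [40, 0, 5], VOX)
        assert tr.theta_deg == pytest.approx(0.0)
        assert tr.res_conn == pytest.approx(0.41)
        assert tr.res_z == pytest.approx(2.0)

    def test_vertical_pair_resolutions(self):
        # theta = 90: connecting axis takes the axial resolution
        tr = compute_pair_transform([5, 5, 0], [5, 5, 30], VOX)
        assert tr.theta_deg == pytest.approx(90.0)
        assert tr.res_conn == pytest.approx(2.0)
        assert tr.res_z == pytest.approx(0.41)

    def test_oblique_pair_mixes_resolutions(self):
        # theta = 45 with 0.41 lateral and 2.0 axial: res_conn = 1.205 um
        l = 30.0
        tr = compute_pair_transform([0, 0, 0], [l / np.sqrt(2), 0, l / np.sqrt(2)], VOX)
        assert tr.theta_deg == pytest.approx(45.0)
        assert tr.res_conn == pytest.approx(1.205)
        assert tr.res_z == pytest.approx(1.205)

    def test_z_axis_is_perpendicular_to_connecting_axis(self):
        tr = compute_pair_transform([0, 0, 0], [20, 10, 14], VOX)
        assert abs(tr.basis[0] @ tr.basis[2]) < 1e-12

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            compute_pair_transform([1, 1, 1], [1, 1, 1], VOX)


class TestTracking:
    def test_static_centers_give_constant_tracks(self):
        frames = [np.array([[0, 0, 0.0], [30, 0, 0.0]])] * 5
        tracks = track_cells(frames)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(tr) == 5
            assert np.allclose(tr.positions, tr.positions[0])

    def test_small_drift_does_not_swap_identities(self):
        rng = np.random.default_rng(1)
        base = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        frames = [base + i * np.array([[0.5, 0, 0], [-0.5, 0, 0]]) for i in range(10)]
        tracks = track_cells(frames)
        assert tracks[0].positions[-1][0] < tracks[1].positions[-1][0]

    def test_cell_leaving_field_truncates_its_track(self):
        frames = [np.array([[0.0, 0, 0], [30.0, 0, 0]])] * 3
        frames += [np.array([[0.0, 0, 0]])] * 2  # second cell exits
        tracks = track_cells(frames)
        assert len(tracks[0]) == 5
        assert len(tracks[1]) == 3


def _constant_stack(value=7.0, shape=(10, 40, 40), vox=(2.0, 1.0, 1.0), n_frames=3):
    voxels = np.full((n_frames,) + shape, value, dtype=np.float32)
    return ImageStack(voxels=voxels, voxel_size=vox)


class TestWindowSampling:
    def test_constant_stack_samples_to_constant_mean(self):
        stack = _constant_stack(7.0)
        tr = compute_pair_transform([5, 20, 8], [33, 22, 10], stack.voxel_size)
        mean, valid = sample_window_intensity(stack, 0, tr, [15.0, 0.0, 0.0], edge=10.0)
        assert valid
        assert mean == pytest.approx(7.0, rel=1e-6)

    def test_out_of_bounds_boundary_convention(self):
        # sampling grid of 20 points per axis (edge 15, resolution 0.75):
        # exactly one layer outside = 5% stays valid, two layers = 10% invalid
        stack = _constant_stack(1.0, shape=(40, 40, 40), vox=(0.75, 0.75, 0.75))
        tr = compute_pair_transform([0, 15, 15], [30, 15, 15], stack.voxel_size)
        extent_x = stack.extent[0]
        center_valid = np.array([extent_x - 6.75 - 0.0, 0.0, 0.0])
        c = tr.to_pair(np.array([extent_x - 6.75, 15.0, 15.0]))[0]
        mean, valid = sample_window_intensity(stack, 0, tr, c, edge=15.0)
        assert valid  # exactly 5% out: strict "over 5%" keeps the frame
        c2 = tr.to_pair(np.array([extent_x - 6.0, 15.0, 15.0]))[0]
        mean2, valid2 = sample_window_intensity(stack, 0, tr, c2, edge=15.0)
        assert not valid2  # 10% out

    def test_fully_out_of_bounds_window_is_invalid_not_an_error(self):
        stack = _constant_stack()
        tr = compute_pair_transform([5, 20, 8], [33, 22, 10], stack.voxel_size)
        mean, valid = sample_window_intensity(stack, 0, tr, [500.0, 0.0, 0.0], edge=10.0)
        assert not valid

    def test_artifact_frame_is_invalid(self):
        stack = _constant_stack()
        stack = ImageStack(
            voxels=stack.voxels, voxel_size=stack.voxel_size, artifact_frames={1}
        )
        tr = compute_pair_transform([5, 20, 8], [33, 22, 10], stack.voxel_size)
        _, v0 = sample_window_intensity(stack, 0, tr, [10.0, 0.0, 0.0], edge=8.0)
        _, v1 = sample_window_intensity(stack, 1, tr, [10.0, 0.0, 0.0], edge=8.0)
        assert v0 and not v1


class TestNormalizationBorder:
    def test_constant_stack_corrects_to_zero(self):
        stack = _constant_stack(9.0, shape=(40, 60, 60), vox=(1.0, 1.0, 1.0))
        track_a = np.tile([10.0, 30.0, 20.0], (3, 1))
        track_b = np.tile([50.0, 30.0, 20.0], (3, 1))
        s = window_intensity_series(
            stack, track_a, track_b, spec=WindowSpecExp(), borders=True
        )
        assert np.all(s.valid)
        assert np.allclose(s.z, 0.0, atol=1e-5)

    def test_shared_additive_drift_is_removed(self):
        shape = (40, 60, 60)
        drift = np.array([0.0, 5.0, -3.0])
        voxels = np.stack([np.full(shape, 10.0 + d, dtype=np.float32) for d in drift])
        stack = ImageStack(voxels=voxels, voxel_size=(1.0, 1.0, 1.0))
        track_a = np.tile([10.0, 30.0, 20.0], (3, 1))
        track_b = np.tile([50.0, 30.0, 20.0], (3, 1))
        s = window_intensity_series(stack, track_a, track_b, spec=WindowSpecExp(), borders=True)
        assert np.allclose(s.z, 0.0, atol=1e-5)

    def test_borders_out_of_reach_invalidate_the_frame(self):
        # stack too shallow for the border geometry in Z
        stack = _constant_stack(5.0, shape=(10, 60, 60), vox=(1.0, 1.0, 1.0))
        track_a = np.tile([10.0, 30.0, 5.0], (3, 1))
        track_b = np.tile([50.0, 30.0, 5.0], (3, 1))
        s = window_intensity_series(stack, track_a, track_b, spec=WindowSpecExp(), borders=True)
        assert not np.any(s.valid)


class TestBackgroundExperiment:
    def test_uniform_stack_is_degenerate(self):
        stack = _constant_stack(5.0, shape=(20, 60, 60), vox=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            background_zscore_experiment(stack, np.array([[30.0, 30.0, 10.0]]))

    def test_generator_onset_density_near_cells_is_elevated(self):
        stack, truth = synthesize_stack(
            n_pairs=1, pair_distance_diameters=5.0, n_frames=4,
            shape=(26, 60, 110), voxel_size=(2.0, 1.2, 1.2), seed=3,
        )
        bg = background_zscore_experiment(stack, truth["cell_centers"])
        tracks = truth["tracks"]
        s = window_intensity_series(
            stack, tracks[:, 0], tracks[:, 1],
            spec=WindowSpecExp(), borders=False, background=bg,
        )
        # generator calibration: onset about 3 background sd above the mean
        assert 1.5 < s.z[0] < 5.5

    def test_background_window_zscores_near_zero(self):
        stack, truth = synthesize_stack(
            n_pairs=1, pair_distance_diameters=5.0, n_frames=3,
            shape=(26, 60, 110), voxel_size=(2.0, 1.2, 1.2), seed=4,
        )
        bg = background_zscore_experiment(stack, truth["cell_centers"])
        # a corner region far from both cells
        tr = compute_pair_transform([20, 10, 10], [60, 10, 10], stack.voxel_size)
        mean, valid = sample_window_intensity(stack, 0, tr, [5.0, 0.0, 0.0], edge=15.0)
        assert valid
        assert abs(bg.zscore(mean)) < 2.5


class TestOrientations:
    def test_thirty_two_orientations_enumerated(self):
        stack = _constant_stack(3.0, shape=(30, 80, 80), vox=(1.5, 1.5, 1.5))
        track = np.tile([60.0, 60.0, 22.0], (2, 1))
        series = single_cell_orientations(stack, track, spec=WindowSpecExp(edge=10.0))
        assert len(series) == 32

    def test_symmetric_field_gives_identical_series_under_direction_flip(self):
        stack = _constant_stack(3.0, shape=(30, 80, 80), vox=(1.5, 1.5, 1.5))
        track = np.tile([60.0, 60.0, 22.0], (2, 1))
        series = single_cell_orientations(stack, track, spec=WindowSpecExp(edge=10.0))
        vals = np.array([s.z[0] for s in series])
        # pairs (i, i+1) are the two directions of the same orientation
        assert np.allclose(vals[0::2], vals[1::2], equal_nan=True)


class TestSynthesizeStack:
    def test_fixed_seed_is_byte_identical(self):
        kw = dict(n_pairs=1, n_frames=3, pair_distance_diameters=2.0,
                  shape=(16, 40, 60), voxel_size=(2.0, 1.2, 1.2), seed=11)
        s1, t1 = synthesize_stack(**kw)
        s2, t2 = synthesize_stack(**kw)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert np.array_equal(t1["tracks"], t2["tracks"])

    def test_ground_truth_partners_are_mutual(self):
        _, truth = synthesize_stack(n_pairs=3, n_frames=2, pair_distance_diameters=3.0,
                                    shape=(16, 80, 80), voxel_size=(2.0, 1.5, 1.5), seed=5)
        po = truth["partner_of"]
        assert all(po[po[i]] == i for i in po)

    def test_tiff_round_trip(self, tmp_path):
        stack, _ = synthesize_stack(n_pairs=1, n_frames=2, pair_distance_diameters=2.0,
                                    shape=(16, 40, 80), voxel_size=(2.0, 1.5, 1.5), seed=6)
        path = tmp_path / "stack.tiff"
        stack.save_tiff(path)
        back = ImageStack.load_tiff(path)
        assert np.allclose(back.voxels, stack.voxels)
        assert back.voxel_size == stack.voxel_size


class TestStackPipeline:
    SHAPE = (26, 96, 140)
    VOXEL = (2.0, 1.2, 1.2)

    def _pairs(self, stack, truth, bg):
        spec = WindowSpecExp(z_offset=0.5)
        tracks = truth["tracks"]
        out = []
        for p in range(len(truth["partner_of"]) // 2):
            i, j = 2 * p, 2 * p + 1
            out.append(
                quantify_pair_series(
                    stack, tracks[:, i], tracks[:, j], spec=spec, background=bg,
                    cell_id_a=f"c{i}", cell_id_b=f"c{j}", run_id="synthetic",
                )
            )
        return out

    def test_coupled_pairs_are_distinguishable_and_matchable(self):
        probs, fracs = [], []
        for seed in range(3):
            stack, truth = synthesize_stack(
                n_pairs=3, pair_distance_diameters=6.0, coupling=0.8,
                n_frames=30, shape=self.SHAPE, voxel_size=self.VOXEL, seed=seed,
            )
            bg = background_zscore_experiment(stack, truth["cell_centers"])
            pairs = self._pairs(stack, truth, bg)
            res = comms.same_vs_different(pairs, comms.DetrendPolicy.experiment())
            mm = comms.matchmaking(pairs, comms.DetrendPolicy.experiment(), rng_seed=seed)
            fracs.append(res.fraction_same_higher)
            probs.append(mm.probability_correct)
        assert np.mean(fracs) > 0.65
        assert np.mean(probs) > 0.3  # far above the 0.02 random baseline

    def test_uncoupled_pairs_sit_at_chance(self):
        fracs = []
        for seed in range(4):
            stack, truth = synthesize_stack(
                n_pairs=3, pair_distance_diameters=6.0, coupling=0.0,
                n_frames=30, shape=self.SHAPE, voxel_size=self.VOXEL, seed=100 + seed,
            )
            bg = background_zscore_experiment(stack, truth["cell_centers"])
            pairs = self._pairs(stack, truth, bg)
            res = comms.same_vs_different(pairs, comms.DetrendPolicy.experiment())
            fracs.append(res.fraction_same_higher)
        assert 0.3 < np.mean(fracs) < 0.7

    def test_border_correction_removes_spurious_cellfree_correlations(self):
        """With shared background fluctuations (local modes + illumination
        flicker), windows at cell-free locations correlate spuriously with
        real cells; the normalization borders should cancel most of that
        common-mode correlation while real pairs stay discriminable (paired
        comparison on the same generated stacks)."""
        fake_drop, frac_with = [], []
        for seed in range(3):
            stack, truth = synthesize_stack(
                n_pairs=2, pair_distance_diameters=6.0, coupling=0.9,
                local_background_strength=8.0, flicker_strength=8.0,
                n_frames=30, shape=self.SHAPE, voxel_size=self.VOXEL, seed=200 + seed,
            )
            bg = background_zscore_experiment(stack, truth["cell_centers"])
            tracks = truth["tracks"]
            extent = stack.extent
            cell_pos = {f"c{i}": truth["cell_centers"][i] for i in range(4)}

            results = {}
            for use_borders in (True, False):
                spec = WindowSpecExp(z_offset=0.5)
                pairs = []
                for p in range(2):
                    i, j = 2 * p, 2 * p + 1
                    a = window_intensity_series(
                        stack, tracks[:, i], tracks[:, j], spec=spec, anchor="a",
                        borders=use_borders, background=bg, cell_id=f"c{i}", run_id="s",
                    )
                    b = window_intensity_series(
                        stack, tracks[:, i], tracks[:, j], spec=spec, anchor="b",
                        borders=use_borders, background=bg, cell_id=f"c{j}", run_id="s",
                    )
                    pairs.append((a, b))

                def source(cell_id, fake_pos, _b=use_borders, _bg=bg, _stack=stack):
                    idx = int(cell_id[1:])
                    fake_track = np.tile(fake_pos, (_stack.n_frames, 1))
                    real_track = tracks[:, idx]
                    return window_intensity_series(
                        _stack, fake_track, real_track, spec=WindowSpecExp(z_offset=0.5),
                        anchor="a", borders=_b, background=_bg, cell_id="fake",
                    )

                res = comms.real_vs_fake(
                    pairs, cell_pos, source, comms.DetrendPolicy.experiment(),
                    bounds=(np.full(3, 10.0), extent - 10.0),
                )
                results[use_borders] = res
            fake_drop.append(
                results[False].diff_corrs.mean() - results[True].diff_corrs.mean()
            )
            frac_with.append(results[True].fraction_same_higher)
        # the cell-free (real-fake) correlation drops once borders are applied
        assert np.mean(fake_drop) > 0.1
        # and real pairs remain discriminable better than chance
        assert np.mean(frac_with) > 0.5
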