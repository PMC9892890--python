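"""Simulator: flow profile, hologram forward model, stack generation."""

import numpy as np
import pytest
from scipy import integrate

import holoenum as he


class TestPoiseuilleVelocity:
    def test_no_slip_at_walls(self, flow_default, optics_default):
        for y, z in [(0.0, 165.0), (800.0, 165.0), (400.0, 0.0), (400.0, 330.0)]:
            assert he.poiseuille_velocity(y, z, flow_default, optics_default) == 0.0

    def test_maximum_at_center(self, flow_default, optics_default):
        u_c = he.poiseuille_velocity(400.0, 165.0, flow_default, optics_default)
        rng = np.random.default_rng(0)
        for _ in range(50):
            y, z = rng.uniform(0, 800), rng.uniform(0, 330)
            assert he.poiseuille_velocity(y, z, flow_default, optics_default) <= u_c

    def test_quadrature_recovers_volumetric_flow(self, flow_default, optics_default):
        """Integral of u(y,z) over the cross-section = total flow rate;
        mean speed Q/(W*H) ~ 221 mm/s at 3.5 mL/min over 800x330 um."""
        W, H = 800.0, 330.0
        q, _ = integrate.dblquad(
            lambda z, y: he.poiseuille_velocity(y, z, flow_default, optics_default),
            0.0,
            W,
            0.0,
            H,
        )
        q_expected = flow_default.total_flow_rate_um3_s
        assert q == pytest.approx(q_expected, rel=0.01)
        mean_speed_mm_s = q_expected / (W * H) / 1e3
        assert mean_speed_mm_s == pytest.approx(221.0, rel=0.01)

    def test_outside_channel_raises(self, flow_default, optics_default):
        with pytest.raises(ValueError):
            he.poiseuille_velocity(-1.0, 100.0, flow_default, optics_default)


class TestProjectHologram:
    def test_empty_cell_list_gives_unit_reference(self, optics_small):
        holo = he.project_hologram([], optics_small)
        assert np.allclose(holo, 1.0)

    def test_fringes_centred_on_cell(self, optics_small):
        cell = he.SimCell(
            cell_id=0,
            class_label=he.TUMOR,
            diameter_um=18.0,
            amplitude_contrast=0.9,
            phase_contrast_rad=0.0,
            y_um=140.0,
            z_um=50.0,
            entry_time_s=0.0,
            texture_seed=1,
            x_um=120.0,
        )
        holo = he.project_hologram([cell], optics_small)
        w = np.abs(1.0 - holo)
        yy, xx = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
        cy = (w * yy).sum() / w.sum()
        cx = (w * xx).sum() / w.sum()
        assert np.hypot(cy - cell.y_um, cx - cell.x_um) <= 2.0

    def test_fringe_extent_grows_with_distance(self, optics_small):
        """Fresnel-zone scaling: the energy-weighted fringe radius of the
        same cell increases with propagation distance."""
        radii = []
        for z in (50.0, 250.0):
            cell = he.SimCell(
                cell_id=0,
                class_label=he.TUMOR,
                diameter_um=18.0,
                amplitude_contrast=0.9,
                phase_contrast_rad=0.0,
                y_um=128.0,
                z_um=z,
                entry_time_s=0.0,
                texture_seed=1,
                x_um=128.0,
            )
            w = np.abs(1.0 - he.project_hologram([cell], optics_small))
            yy, xx = np.mgrid[0:256, 0:256]
            r = np.hypot(yy - 128.0, xx - 128.0)
            radii.append((w * r).sum() / w.sum())
        assert radii[1] > radii[0]

    def test_cell_larger_than_fov_raises(self, optics_small):
        cell = he.SimCell(
            cell_id=0,
            class_label=he.TUMOR,
            diameter_um=300.0,
            amplitude_contrast=0.4,
            phase_contrast_rad=0.0,
            y_um=128.0,
            z_um=100.0,
            entry_time_s=0.0,
            x_um=128.0,
        )
        with pytest.raises(ValueError):
            he.project_hologram([cell], he.OpticalConfig(fov_px=(64, 64)))


class TestSimulateStack:
    def test_zero_mix_gives_pure_background(self, optics_small):
        flow = he.FlowConfig(n_frames=5)
        sim = he.SimParams(noise_sigma_frac=0.0)
        stack = he.simulate_stack(optics_small, flow, {}, seed=0, sim=sim)
        assert stack.n_frames == 5
        for frame in stack.frames:
            np.testing.assert_allclose(frame, stack.illumination, rtol=1e-6)

    def test_zero_contrast_cells_equal_background(self, optics_small):
        flow = he.FlowConfig(n_frames=20)
        sim = he.SimParams(
            noise_sigma_frac=0.0,
            tumor_amplitude_contrast=0.0,
            wbc_amplitude_contrast=0.0,
        )
        stack = he.simulate_stack(
            optics_small, flow, {he.TUMOR: 1e5}, seed=1, sim=sim
        )
        for frame in stack.frames:
            np.testing.assert_allclose(frame, stack.illumination, rtol=1e-6)

    def test_identical_seeds_bit_identical(self, optics_small):
        flow = he.FlowConfig(n_frames=8)
        mix = {he.TUMOR: 5e4, he.WBC: 5e4}
        a = he.simulate_stack(optics_small, flow, mix, seed=7)
        b = he.simulate_stack(optics_small, flow, mix, seed=7)
        assert np.array_equal(a.frames, b.frames)
        c = he.simulate_stack(optics_small, flow, mix, seed=8)
        assert not np.array_equal(a.frames, c.frames)

    def test_poisson_arrival_statistics(self, optics_default, flow_default):
        """At 100 cells/mL over 1 mL the unique-cell draw is Poisson(100):
        the across-seed mean must fall in the central [80, 120] band."""
        counts = [
            len(
                he.simulate_tracks(
                    optics_default, flow_default, {he.TUMOR: 100.0}, seed=s
                )[0]
            )
            for s in range(20)
        ]
        assert 80.0 <= np.mean(counts) <= 120.0

    def test_fastest_cell_crosses_fov_within_one_frame(
        self, optics_default, flow_default
    ):
        """Centre-line displacement per frame exceeds the 800 um field of
        view, so the fastest cells are seen at most once."""
        u_max = he.poiseuille_velocity(400.0, 165.0, flow_default, optics_default)
        per_frame_um = u_max / flow_default.frame_rate_fps
        assert per_frame_um > optics_default.fov_px[1] * optics_default.pixel_pitch_um

    def test_ground_truth_closure_and_multiframe_cells(
        self, optics_default, flow_default
    ):
        """Every cell inside the FOV during >=1 frame is logged with its
        track; slow near-interface cells span 2-3 consecutive frames and
        none exceeds 3."""
        cells, gt = he.simulate_tracks(
            optics_default, flow_default, {he.TUMOR: 3000.0}, seed=4, n_frames=2000
        )
        assert set(gt["cell_id"]).issubset({c.cell_id for c in cells})
        per_cell = gt.groupby("cell_id").size()
        assert per_cell.max() <= 3
        assert (per_cell >= 2).any()
        # appearances of one cell are consecutive frames
        for cid, sub in gt.groupby("cell_id"):
            frames = np.sort(sub["frame"].to_numpy())
            assert np.all(np.diff(frames) == 1)


class TestTrainingCrops:
    def test_shapes_labels_and_range(self, optics_default):
        crops, labels = he.make_training_crops(20, optics_default, seed=0)
        assert crops.shape == (40, 36, 36)
        assert set(labels.tolist()) == {0, 1}
        assert float(crops.min()) >= 0.0 and float(crops.max()) <= 1.0

    def test_deterministic_given_seed(self, optics_default):
        a, _ = he.make_training_crops(5, optics_default, seed=3)
        b, _ = he.make_training_crops(5, optics_default, seed=3)
        assert np.array_equal(a, b)
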