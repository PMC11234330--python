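"""Velocimetry recovery against rendered ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapflow import tracking
from trapflow.synthetic import OpticsSpec, render_video
from trapflow.tracking import detect, detect_stack, homogeneity, link_ptv, \
    piv, track_velocities
from trapflow.transport import ParticleSpec, TrajectorySet


def moving_trajectories(n, speed_um_s, duration, rng_seed=0, span=300.0,
                        diameter=2.0):
    """Straight +x motion at a common speed, random start positions."""
    rng = np.random.default_rng(rng_seed)
    t = np.array([0.0, duration])
    start = np.column_stack([rng.uniform(10, span / 3, n),
                             rng.uniform(10, span - 10, n),
                             np.full(n, 7.5)])
    end = start + np.array([speed_um_s * duration, 0.0, 0.0])
    pos = np.stack([start, end], axis=1)
    return TrajectorySet(t=t, positions=pos,
                         spec=ParticleSpec(diameter=diameter), rng_seed=0)


class TestDetect:
    def test_blank_frame_no_detections(self):
        assert detect(np.zeros((64, 64))).empty

    def test_counts_match_rendered_ground_truth(self):
        # 50 spots on a jittered grid, guaranteed non-overlapping
        rng = np.random.default_rng(3)
        xs, ys = np.meshgrid(np.arange(10, 320, 31.0),
                             np.arange(10, 150, 31.0))
        pts = np.column_stack([
            (xs.ravel() + rng.uniform(-3, 3, xs.size)) * 0.65,
            (ys.ravel() + rng.uniform(-3, 3, ys.size)) * 0.65,
            np.full(xs.size, 7.5)])[:50]
        traj = TrajectorySet(t=np.array([0.0, 1.0]),
                             positions=np.repeat(pts[:, None], 2, axis=1),
                             spec=ParticleSpec(), rng_seed=0)
        optics = OpticsSpec(frame_count=1, background=0.0)
        stack = render_video(traj, optics, frame_shape=(160, 330),
                             noise=False)
        df = detect(stack.frames[0], threshold=1.0, min_separation=3)
        assert len(df) == 50

    def test_centroid_subpixel_accuracy(self):
        x_um, y_um = 20.41, 15.83
        traj = TrajectorySet(
            t=np.array([0.0, 1.0]),
            positions=np.repeat(np.array([[[x_um, y_um, 7.5]]]), 2, axis=1),
            spec=ParticleSpec(), rng_seed=0)
        optics = OpticsSpec(frame_count=1, background=0.0)
        stack = render_video(traj, optics, frame_shape=(48, 48), noise=False)
        df = detect(stack.frames[0], threshold=1.0, min_separation=4)
        assert len(df) == 1
        assert df["x"].iloc[0] == pytest.approx(x_um / 0.65, abs=0.1)
        assert df["y"].iloc[0] == pytest.approx(y_um / 0.65, abs=0.1)


class TestLinkPTV:
    def test_single_particle_speed_arithmetic(self):
        # 3 px/frame at 25 Hz and 0.65 um/px -> 48.75 um/s
        optics = OpticsSpec()
        dets = pd.DataFrame({
            "frame": np.arange(5),
            "x": 10.0 + 3.0 * np.arange(5),
            "y": np.full(5, 20.0),
        })
        tracks = link_ptv(dets, expected_velocity=48.75, optics=optics)
        vel = track_velocities(tracks)
        assert len(vel) == 1
        assert vel["speed"].iloc[0] == pytest.approx(3 * 0.65 * 25)

    def test_uniform_flow_video_parameter_recovery(self):
        # end-to-end: render 40 frames of 111 um/s flow, recover the speed
        optics = OpticsSpec(frame_count=40)
        duration = optics.frame_count * optics.frame_interval
        traj = moving_trajectories(20, 111.0, duration, rng_seed=5,
                                   span=160.0)
        stack = render_video(traj, optics, frame_shape=(256, 512),
                             rng_seed=2)
        dets = detect_stack(stack.frames, threshold=25.0,
                            min_separation=3)
        tracks = link_ptv(dets, expected_velocity=111.0, optics=optics)
        vel = track_velocities(tracks)
        vel = vel[vel["n_steps"] >= 5]
        mean_speed = vel["speed"].mean()
        assert mean_speed == pytest.approx(111.0, rel=0.05)

    def test_link_rates_on_ground_truth(self):
        # at sparse seeding (< 0.01 spots/px^2), >= 95% of true links are
        # recovered with <= 1% false links
        rng = np.random.default_rng(8)
        xs, ys = np.meshgrid(np.arange(12.0, 500, 16), np.arange(12.0, 250,
                                                                 16))
        truth_a = np.column_stack([
            xs.ravel() + rng.uniform(-3, 3, xs.size),
            ys.ravel() + rng.uniform(-3, 3, xs.size)])
        shift = np.array([3.0, 0.0])
        truth_b = truth_a + shift
        frame_a = spot_frame((262, 512), truth_a)
        frame_b = spot_frame((262, 512), truth_b)
        optics = OpticsSpec()
        dets = pd.concat([
            detect(frame_a, threshold=1.0).assign(frame=0),
            detect(frame_b, threshold=1.0).assign(frame=1)],
            ignore_index=True)
        speed = shift[0] * optics.pixel_size * optics.frame_rate
        tracks = link_ptv(dets, expected_velocity=speed, optics=optics)
        linked = tracks.dropna(subset=["u"])
        # map each linked start to its nearest true particle
        correct = 0
        for _, row in linked.iterrows():
            d_a = np.hypot(*(truth_a - [row["x"], row["y"]]).T)
            ia = np.argmin(d_a)
            end = tracks[(tracks["track_id"] == row["track_id"])
                         & (tracks["frame"] == 1)][["x", "y"]].iloc[0]
            d_b = np.hypot(*(truth_b - end.to_numpy()).T)
            correct += np.argmin(d_b) == ia and d_b.min() < 1.0
        n_true = truth_a.shape[0]
        assert correct / n_true >= 0.95
        assert (len(linked) - correct) / max(len(linked), 1) <= 0.01

    def test_ambiguous_crossing_dropped(self):
        # two detections equidistant from one predicted position: no link
        optics = OpticsSpec()
        dets = pd.DataFrame({
            "frame": [0, 1, 1],
            "x": [10.0, 11.0, 11.0],
            "y": [20.0, 21.0, 19.0],
        })
        tracks = link_ptv(dets, expected_velocity=0.0, optics=optics)
        # three distinct track ids, no velocities assigned
        assert tracks["track_id"].nunique() == 3
        assert tracks["u"].dropna().empty

    def test_requires_two_frames(self):
        optics = OpticsSpec()
        dets = pd.DataFrame({"frame": [0], "x": [1.0], "y": [1.0]})
        with pytest.raises(ValueError):
            link_ptv(dets, 10.0, optics)

    def test_missing_optics_rejected(self):
        dets = pd.DataFrame({"frame": [0, 1], "x": [1.0, 2.0],
                             "y": [1.0, 1.0]})
        with pytest.raises(ValueError):
            link_ptv(dets, 10.0, None)


def spot_frame(shape, centers, sigma=1.5, amp=100.0):
    ny, nx = shape
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cx, cy in centers:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                            / (2 * sigma ** 2))
    return img


@pytest.fixture(scope="module")
def speckle():
    rng = np.random.default_rng(11)
    centers = rng.uniform(5, 123, size=(60, 2))
    return spot_frame((128, 128), centers)


class TestPIV:
    def test_identical_frames_zero_field(self, speckle):
        grid = piv(speckle, speckle, window=32, overlap=0.5)
        assert np.allclose(grid.u, 0.0, atol=1e-9)
        assert np.allclose(grid.v, 0.0, atol=1e-9)

    def test_integer_shift_recovered_exactly(self, speckle):
        shifted = np.roll(speckle, (0, 5), axis=(0, 1))
        grid = piv(speckle, shifted, window=32, overlap=0.5)
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(grid.u[inner], 5.0, atol=1e-9)
        assert np.allclose(grid.v[inner], 0.0, atol=1e-9)

    def test_subpixel_shift_within_tenth_pixel(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(8, 140, size=(200, 2))
        a = spot_frame((150, 150), centers)
        b = spot_frame((150, 150), centers + np.array([2.5, 0.0]))
        grid = piv(a, b, window=32, overlap=0.5)
        inner = grid.u[1:-1, 1:-1]
        assert np.abs(inner - 2.5).max() < 0.1

    @given(st.integers(0, 24), st.integers(0, 24))
    @settings(max_examples=10, deadline=None)
    def test_translation_equivariance(self, ox, oy):
        # moving the field of view over the same uniformly displaced scene
        # leaves the recovered vectors unchanged (all equal to the true
        # displacement)
        rng = np.random.default_rng(9)
        centers = rng.uniform(10, 170, size=(110, 2))
        scene_a = spot_frame((184, 184), centers)
        scene_b = spot_frame((184, 184), centers + np.array([3.0, 2.0]))
        a = scene_a[oy:oy + 128, ox:ox + 128]
        b = scene_b[oy:oy + 128, ox:ox + 128]
        g = piv(a, b, window=32, overlap=0.5)
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(g.u[inner], 3.0, atol=0.1)
        assert np.allclose(g.v[inner], 2.0, atol=0.1)

    def test_window_larger_than_frame_rejected(self, speckle):
        with pytest.raises(ValueError):
            piv(speckle, speckle, window=256)

    def test_velocity_units_roundtrip(self, speckle):
        optics = OpticsSpec()
        shifted = np.roll(speckle, (0, 3), axis=(0, 1))
        grid = piv(speckle, shifted, window=32, overlap=0.5, optics=optics)
        px_per_frame = grid.u / (optics.pixel_size * optics.frame_rate)
        assert np.allclose(px_per_frame[1:-1, 1:-1], 3.0, atol=1e-9)


class TestHomogeneity:
    def test_uniform_field_zero_dispersion(self):
        grid = tracking.VectorGrid(
            x=np.tile(np.arange(10.0), (10, 1)),
            y=np.tile(np.arange(10.0)[:, None], (1, 10)),
            u=np.full((10, 10), 100.0), v=np.zeros((10, 10)),
            quality=np.ones((10, 10)), window=32, overlap=0.5)
        rep = homogeneity(grid, roi=(0, 0, 9, 9))
        assert rep.speed_cv == 0.0
        assert rep.direction_dispersion_deg == pytest.approx(0.0, abs=1e-9)
        assert rep.mean_speed == 100.0

    def test_too_few_vectors_rejected(self):
        grid = tracking.VectorGrid(
            x=np.arange(5.0), y=np.zeros(5), u=np.ones(5), v=np.zeros(5),
            quality=np.ones(5), window=32, overlap=0.5)
        with pytest.raises(ValueError):
            homogeneity(grid, roi=(0, 0, 4, 1))

    def test_roi_outside_data_rejected(self):
        grid = tracking.VectorGrid(
            x=np.arange(20.0), y=np.zeros(20), u=np.ones(20),
            v=np.zeros(20), quality=np.ones(20), window=32, overlap=0.5)
        with pytest.raises(ValueError):
            homogeneity(grid, roi=(100, 100, 200, 200))
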