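"""Flow-solver oracles: conservation, Poiseuille closed forms, vortex
metric analytic cases, streamline behavior."""

import numpy as np
import pytest

from conftest import analytic_field, uniform_field
from trapflow import flowsim
from trapflow.geometry import (
    ChannelSpec,
    MicrotrapSpec,
    WATER,
    build_channel,
    build_microtrap,
    mean_velocity,
)


@pytest.fixture(scope="module")
def plain_flow():
    ch = ChannelSpec(analysis_area=(400.0, 200.0), grid_spacing=2.0)
    dm = build_channel(ch)
    return dm, flowsim.solve_depth_averaged(dm, 0.5, WATER,
                                            channel=ChannelSpec())


class TestDepthAveraged:
    def test_plain_channel_uniform_velocity(self, plain_flow):
        _, ff = plain_flow
        U = mean_velocity(0.5, ChannelSpec())
        assert np.allclose(ff.u, U, rtol=1e-9)
        assert np.allclose(ff.v, 0.0, atol=1e-9 * U)

    def test_plain_channel_pressure_drop_matches_slot_flow(self, plain_flow):
        # closed form dp = 12 mu Q L / (w h^3) for slot Poiseuille
        dm, ff = plain_flow
        L = dm.nx * dm.grid_spacing
        Q = 0.5e9 / 60.0
        expected = 12.0 * 1e-3 * (Q / 5000.0) * L / 15.0 ** 3
        # pressure at the first column extrapolates half a cell upstream
        drop = ff.pressure[:, 0].mean()
        assert drop == pytest.approx(
            expected * (1 - 0.5 / dm.nx), rel=0.01)

    def test_depth_flux_conservation(self, trap_flow_low):
        assert trap_flow_low.depth_flux_divergence() <= 1e-6

    def test_cross_section_flux_constant(self, trap_flow_low, trap_depth,
                                         small_channel):
        inlet = trap_flow_low.cross_section_flux(0)
        ny = trap_depth.ny
        expected = 0.5e9 / 60.0 / 5000.0 * ny * trap_depth.grid_spacing
        assert inlet == pytest.approx(expected, rel=1e-9)
        for ix in (trap_depth.nx // 3, trap_depth.nx // 2,
                   trap_depth.nx - 1):
            assert trap_flow_low.cross_section_flux(ix) == pytest.approx(
                inlet, rel=1e-3)

    def test_linearity_in_flow_rate(self, trap_depth, trap_flow_low):
        hi = flowsim.solve_depth_averaged(trap_depth, 3.0, WATER,
                                          channel=ChannelSpec())
        assert np.allclose(hi.u, 6.0 * trap_flow_low.u, rtol=1e-6,
                           atol=1e-9)
        om_lo = flowsim.vorticity(trap_flow_low).values
        om_hi = flowsim.vorticity(hi).values
        assert np.allclose(om_hi, 6.0 * om_lo, rtol=1e-6, atol=1e-8)
        q_lo = flowsim.q_criterion(trap_flow_low).values
        q_hi = flowsim.q_criterion(hi).values
        assert np.allclose(q_hi, 36.0 * q_lo, rtol=1e-6, atol=1e-6)

    def test_mirror_symmetry(self, trap_depth, trap_flow_low):
        # the trap is symmetric about the channel centerline: u even, v odd
        u, v = trap_flow_low.u, trap_flow_low.v
        scale = np.abs(u).max()
        assert np.allclose(u, u[::-1, :], atol=1e-6 * scale)
        assert np.allclose(v, -v[::-1, :], atol=1e-6 * scale)

    def test_zero_flow_rate_gives_zero_field(self, trap_depth):
        ff = flowsim.solve_depth_averaged(trap_depth, 0.0, WATER,
                                          channel=ChannelSpec())
        assert np.all(ff.u == 0) and np.all(ff.v == 0)

    def test_negative_flow_rate_rejected(self, trap_depth):
        with pytest.raises(ValueError):
            flowsim.solve_depth_averaged(trap_depth, -1.0)


class TestVerticalSlice:
    def test_flat_profile_recovers_plane_poiseuille(self):
        prof = np.full(80, 15.0)
        sl = flowsim.solve_vertical_slice(prof, 2.0, 0.5, WATER,
                                          ChannelSpec(), dz=0.5)
        mid = sl.u[:, 40]
        ratio = mid.max() / mid.mean()
        assert ratio == pytest.approx(1.5, rel=0.02)
        # vertical velocity vanishes to discretization level
        assert np.abs(sl.v).max() < 1e-3 * mid.max()

    def test_cavity_recirculation_detected(self):
        # two 10 um-high walls flanking a narrow slot: the over-flow drives
        # a closed eddy (streamfunction changes sign inside the slot)
        prof = np.full(120, 15.0)
        prof[40:52] = 5.0   # upstream wall (24 um)
        prof[58:70] = 5.0   # downstream wall; 12 um slot between
        sl = flowsim.solve_vertical_slice(prof, 2.0, 3.0, WATER,
                                          ChannelSpec(), dz=0.5)
        psi = sl.streamfunction()
        zc = (np.arange(sl.u.shape[0]) + 0.5) * 0.5
        slot = np.zeros_like(psi, dtype=bool)
        slot[zc < 10.0, 52:58] = True
        span = psi.max() - psi.min()
        assert psi[slot].min() < -1e-6 * span

    def test_zero_flow_gives_zero_field(self):
        sl = flowsim.solve_vertical_slice(np.full(20, 15.0), 2.0, 0.0)
        assert np.all(sl.u == 0) and np.all(sl.v == 0)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            flowsim.solve_vertical_slice(np.array([15.0, -1.0, 15.0, 15.0]),
                                         2.0, 1.0)


class TestVortexMetrics:
    def test_rigid_rotation_vorticity_and_q(self):
        om = 3.0
        f = analytic_field(lambda x, y: -om * (y - 32.0),
                           lambda x, y: om * (x - 32.0))
        vort = flowsim.vorticity(f).values
        q = flowsim.q_criterion(f).values
        interior = (slice(2, -2), slice(2, -2))
        assert np.allclose(vort[interior], 2 * om, rtol=1e-9)
        assert np.allclose(q[interior], om ** 2, rtol=1e-9)

    def test_uniform_flow_has_zero_vorticity(self):
        f = uniform_field(u=50.0, v=20.0)
        assert np.allclose(flowsim.vorticity(f).values, 0.0)

    def test_simple_shear_q_zero(self):
        g = 2.0
        f = analytic_field(lambda x, y: g * y, lambda x, y: 0.0 * x)
        q = flowsim.q_criterion(f).values
        assert np.allclose(q[2:-2, 2:-2], 0.0, atol=1e-12)

    def test_pure_strain_q_negative_gamma_squared(self):
        g = 1.5
        f = analytic_field(lambda x, y: g * x, lambda x, y: -g * y)
        q = flowsim.q_criterion(f).values
        assert np.allclose(q[2:-2, 2:-2], -g ** 2, rtol=1e-9)


class TestExports:
    def test_field_tiff_roundtrip(self, tmp_path, trap_flow_low):
        import json

        import tifffile

        prefix = str(tmp_path / "field")
        trap_flow_low.save(prefix)
        data = tifffile.imread(prefix + ".tif")
        assert data.shape[0] == 3  # u, v, p planes
        assert np.allclose(data[0], trap_flow_low.u.astype(np.float32))
        meta = json.load(open(prefix + ".json"))
        assert meta["plane"] == "XY_depth_averaged"

    def test_streamlines_csv(self, tmp_path):
        import pandas as pd

        f = uniform_field(u=100.0)
        lines = flowsim.streamlines(f, seeds=[(5.0, 30.0), (5.0, 50.0)],
                                    step=2.0)
        path = tmp_path / "lines.csv"
        flowsim.streamlines_to_csv(lines, str(path))
        df = pd.read_csv(path)
        assert set(df["polyline_id"]) == {0, 1}
        assert len(df) == sum(len(li) for li in lines)


class TestStreamlines:
    def test_uniform_flow_gives_straight_lines(self):
        f = uniform_field(u=100.0, v=0.0)
        lines = flowsim.streamlines(f, seeds=[(5.0, 30.0), (5.0, 60.0)],
                                    step=2.0)
        for line in lines:
            assert np.allclose(line[:, 1], line[0, 1], atol=1e-9)
            assert line[-1, 0] > 150.0  # integrated to the outlet

    def test_seed_outside_domain_rejected(self):
        f = uniform_field()
        with pytest.raises(ValueError):
            flowsim.streamlines(f, seeds=[(-5.0, 10.0)])

    def test_streamline_stagnates_at_dead_fluid(self):
        # velocity vanishes in the right half; the streamline must stop
        # near the interface instead of wandering into the dead region
        u = np.zeros((40, 80))
        u[:, :40] = 100.0
        f = flowsim.FlowField2D(u=u, v=np.zeros_like(u),
                                plane="XY_depth_averaged", grid_spacing=2.0,
                                flow_rate=1.0)
        (line,) = flowsim.streamlines(f, seeds=[(10.0, 40.0)], step=1.0,
                                      max_steps=2000)
        assert line[-1, 0] < 90.0

    def test_closed_recirculation_returns_near_start(self):
        om = 1.0
        f = analytic_field(lambda x, y: -om * (y - 32.0),
                           lambda x, y: om * (x - 32.0))
        (line,) = flowsim.streamlines(f, seeds=[(32.0, 22.0)], step=0.5,
                                      max_steps=400)
        # the orbit keeps its radius about the rotation center and
        # re-approaches the seed after a revolution
        dists = np.hypot(line[:, 0] - 32.0, line[:, 1] - 32.0)
        assert np.allclose(dists, 10.0, rtol=0.05)
        assert np.any(np.hypot(line[20:, 0] - line[0, 0],
                               line[20:, 1] - line[0, 1]) < 1.0)
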