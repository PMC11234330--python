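import numpy as np
import pytest

from trapflow.geometry import (
    ChannelSpec,
    MicrotrapSpec,
    WATER,
    build_microtrap,
)
from trapflow import flowsim


@pytest.fixture(scope="session")
def small_channel() -> ChannelSpec:
    """Compact analysis domain used throughout the unit tests."""
    return ChannelSpec(analysis_area=(650.0, 350.0), grid_spacing=2.0)


@pytest.fixture(scope="session")
def trap_depth(small_channel):
    return build_microtrap(MicrotrapSpec(), small_channel)


@pytest.fixture(scope="session")
def trap_flow_low(trap_depth):
    """Depth-averaged field at the low study flow rate (0.5 uL/min)."""
    return flowsim.solve_depth_averaged(trap_depth, 0.5, WATER,
                                        channel=ChannelSpec())


def uniform_field(u=100.0, v=0.0, shape=(50, 80), spacing=2.0,
                  flow_rate=0.5):
    """Analytic uniform plan-view field for transport/metric tests."""
    return flowsim.FlowField2D(
        u=np.full(shape, float(u)), v=np.full(shape, float(v)),
        plane="XY_depth_averaged", grid_spacing=spacing,
        flow_rate=flow_rate)


def analytic_field(fu, fv, shape=(64, 64), spacing=1.0):
    """Field sampled from closed-form velocity functions of (x, y) in um."""
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    X, Y = np.meshgrid(x, y)
    return flowsim.FlowField2D(u=fu(X, Y), v=fv(X, Y),
                               plane="XY_depth_averaged",
                               grid_spacing=spacing, flow_rate=1.0)
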