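"""Channel and feature geometry as rasterized clearance maps, plus
dimensionless flow numbers.

Coordinate convention
---------------------
``x`` increases downstream, ``y`` across the channel, ``z`` up; all lengths
are in micrometres (um) and times in seconds.  Raster grids are row-major
arrays indexed ``[iy, ix]``; the physical ``y`` coordinate increases with the
row index, so displaying an array with matplotlib's default ``origin='upper'``
flips the channel vertically (a pure display convention — the solvers and
statistics are insensitive to it).

A :class:`DepthMap` stores the *local vertical clearance* ``h(x, y)`` of the
channel: the full channel height over open floor and ``channel height -
feature height`` over feature walls.  Features never span the full height
(they are built to two thirds of it), so ``h > 0`` everywhere and fluid can
pass over the walls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# Boltzmann constant, J/K
_KB = 1.380649e-23
# standard gravity, m/s^2
_G = 9.81

__all__ = [
    "FluidProperties",
    "ChannelSpec",
    "MicrotrapSpec",
    "ArrowSpec",
    "DepthMap",
    "WATER",
    "build_channel",
    "build_microtrap",
    "build_arrow_array",
    "load_config",
    "reynolds_number",
    "peclet_number",
    "mean_velocity",
    "settling_velocity",
    "stokes_einstein_diffusivity",
]


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid properties.

    Parameters
    ----------
    density : float
        Fluid density in kg/m^3.
    dynamic_viscosity : float
        Dynamic viscosity in Pa s.
    temperature : float
        Temperature in degrees Celsius (used for Stokes-Einstein
        diffusivities).
    """

    density: float = 1000.0
    dynamic_viscosity: float = 1.0e-3
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.dynamic_viscosity <= 0:
            raise ValueError("fluid viscosity must be positive")


#: Round-number water properties used throughout (1000 kg/m^3, 1.0 mPa s).
WATER = FluidProperties()


@dataclass(frozen=True)
class ChannelSpec:
    """Straight shallow channel with a central analysis area.

    The physical channel is 5 mm wide and 15 um high; the solvers operate on
    the central ``analysis_area`` (default 1500 x 1000 um) where the flow is
    homogeneous.  ``grid_spacing`` sets the raster resolution.
    """

    width: float = 5000.0
    height: float = 15.0
    analysis_area: tuple[float, float] = (1500.0, 1000.0)
    grid_spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("channel dimensions must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        ax, ay = self.analysis_area
        if ax <= 0 or ay <= 0:
            raise ValueError("analysis_area dimensions must be positive")
        if ay > self.width:
            raise ValueError("analysis_area must fit within the channel width")

    @property
    def cross_section_um2(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class MicrotrapSpec:
    """Nested-funnel microtrap: 3 funnels opening with the flow and 3
    against it, forming 5 inner cavities.

    Dimensions follow the fabricated feature: 410 um long, 150 um wide,
    10 um high walls of 20 um thickness.  The funnel gap width and the
    funnel half-angle are not printed for the fabricated device and are
    exposed as parameters.  The default gap of 2 um follows the original
    single-cell funnel-trap concept the feature is based on (constrictions
    of about one bacterium width): a gap that small is hydraulically
    negligible, which is what makes the cavities low-velocity refuges -
    with tens-of-microns gaps the funnels would jet instead of trap and
    in-trap velocities would exceed the observed scale by orders of
    magnitude.
    """

    length: float = 410.0
    width: float = 150.0
    feature_height: float = 10.0
    wall_thickness: float = 20.0
    funnels_with_flow: int = 3
    funnels_against_flow: int = 3
    funnel_gap_width: float = 2.0
    funnel_half_angle: float = 45.0
    traps_per_channel: int = 7

    def __post_init__(self) -> None:
        for name in ("length", "width", "feature_height", "wall_thickness",
                     "funnel_gap_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.funnels_with_flow < 1 or self.funnels_against_flow < 1:
            raise ValueError("need at least one funnel in each direction")
        if not 0 < self.funnel_half_angle < 90:
            raise ValueError("funnel_half_angle must be in (0, 90) degrees")

    @property
    def cavities(self) -> int:
        """Number of inner cavities (one fewer than the funnel count)."""
        return self.funnels_with_flow + self.funnels_against_flow - 1


@dataclass(frozen=True)
class ArrowSpec:
    """Array of chevron ("arrow") features pointing against the flow.

    Each arrow is a V-shaped wall of ``width`` (= wall thickness) 20 um
    spanning ``length`` 140 um across the flow; 7 arrows are placed in a
    streamwise line separated by one arrow length (center-to-center pitch
    ``length + spacing`` = 280 um).
    """

    width: float = 20.0
    length: float = 140.0
    count: int = 7
    spacing: float = 140.0
    feature_height: float = 10.0
    half_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.width <= 0 or self.length <= 0 or self.feature_height <= 0:
            raise ValueError("arrow dimensions must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class DepthMap:
    """Raster of local vertical clearance encoding channel + feature
    topography.

    Attributes
    ----------
    clearance : (ny, nx) float array
        Local clearance h in um; equals ``channel_height`` over open floor
        and ``channel_height - feature_height`` over feature walls.
    grid_spacing : float
        Cell size in um (cells are square; centers at
        ``origin + (i + 0.5) * grid_spacing``).
    origin : (float, float)
        Physical (x, y) of the lower-left domain corner, um.
    solid_mask : (ny, nx) bool array
        True over the feature footprint.
    cavity_labels : (ny, nx) int array or None
        0 outside cavities; 1..n label the topologically enclosed cavity
        regions in downstream order.
    landmarks : dict
        Feature landmarks in physical um coordinates: ``trap_bbox``
        (x0, y0, x1, y1), ``corners`` (concave wall junction points),
        ``cavity_centroids`` (downstream order), ``gap_centers``.
    """

    clearance: np.ndarray
    grid_spacing: float
    channel_height: float
    feature_height: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)
    solid_mask: np.ndarray = None  # type: ignore[assignment]
    cavity_labels: np.ndarray | None = None
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clearance = np.asarray(self.clearance, dtype=float)
        if self.solid_mask is None:
            self.solid_mask = np.zeros(self.clearance.shape, dtype=bool)
        if self.clearance.min() <= 0:
            raise ValueError("clearance must be positive everywhere "
                             "(features do not span the full height)")
        if self.solid_mask.shape != self.clearance.shape:
            raise ValueError("solid_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.clearance.shape

    @property
    def nx(self) -> int:
        return self.clearance.shape[1]

    @property
    def ny(self) -> int:
        return self.clearance.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates, um."""
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.grid_spacing

    @property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates, um."""
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.grid_spacing

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) physical bounds, um."""
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.grid_spacing,
                y0, y0 + self.ny * self.grid_spacing)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(iy, ix) of the cell containing physical point (x, y)."""
        ix = int((x - self.origin[0]) / self.grid_spacing)
        iy = int((y - self.origin[1]) / self.grid_spacing)
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise ValueError(f"point ({x}, {y}) outside the depth map")
        return iy, ix

    def count_cavities(self) -> int:
        """Number of enclosed cavity regions (0 if no feature)."""
        if self.cavity_labels is None:
            return 0
        return int(self.cavity_labels.max())

    def translated(self, dx: float, dy: float) -> "DepthMap":
        """Same geometry with a shifted physical origin."""
        lm = dict(self.landmarks)
        if "trap_bbox" in lm:
            x0, y0, x1, y1 = lm["trap_bbox"]
            lm["trap_bbox"] = (x0 + dx, y0 + dy, x1 + dx, y1 + dy)
        for key in ("corners", "cavity_centroids", "gap_centers"):
            if key in lm:
                lm[key] = [(px + dx, py + dy) for px, py in lm[key]]
        return replace(self, origin=(self.origin[0] + dx,
                                     self.origin[1] + dy), landmarks=lm)

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.tif`` (clearance, 32-bit float um) and
        ``<prefix>.json`` (grid metadata)."""
        import tifffile

        tifffile.imwrite(f"{prefix}.tif", self.clearance.astype(np.float32))
        meta = {
            "grid_spacing_um": self.grid_spacing,
            "origin_um": list(self.origin),
            "channel_height_um": self.channel_height,
            "feature_height_um": self.feature_height,
            "landmarks": {
                k: (float(v) if np.isscalar(v)
                    else [list(map(float, p)) if np.iterable(p)
                          else float(p) for p in v])
                for k, v in self.landmarks.items()},
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# rasterization helpers


def _capsule_mask(xg: np.ndarray, yg: np.ndarray,
                  p0: tuple[float, float], p1: tuple[float, float],
                  thickness: float) -> np.ndarray:
    """Cells whose centers lie within ``thickness/2`` of segment p0-p1."""
    px, py = np.meshgrid(xg, yg)
    ax, ay = p0
    bx, by = p1
    abx, aby = bx - ax, by - ay
    ab2 = abx * abx + aby * aby
    if ab2 == 0:
        d2 = (px - ax) ** 2 + (py - ay) ** 2
    else:
        t = np.clip(((px - ax) * abx + (py - ay) * aby) / ab2, 0.0, 1.0)
        d2 = (px - (ax + t * abx)) ** 2 + (py - (ay + t * aby)) ** 2
    return d2 <= (thickness / 2.0) ** 2


def _grid_for(channel: ChannelSpec) -> tuple[np.ndarray, np.ndarray]:
    ax, ay = channel.analysis_area
    d = channel.grid_spacing
    nx = int(round(ax / d))
    ny = int(round(ay / d))
    if nx < 1 or ny < 1:
        raise ValueError("grid_spacing too coarse for the analysis area")
    xg = (np.arange(nx) + 0.5) * d
    yg = (np.arange(ny) + 0.5) * d
    return xg, yg


def build_channel(spec: ChannelSpec) -> DepthMap:
    """Plain channel: uniform clearance equal to the channel height."""
    xg, yg = _grid_for(spec)
    h = np.full((yg.size, xg.size), spec.height, dtype=float)
    return DepthMap(clearance=h, grid_spacing=spec.grid_spacing,
                    channel_height=spec.height)


def _microtrap_segments(spec: MicrotrapSpec) -> dict:
    """Wall segments and landmarks of the trap in trap-local coordinates
    (origin at the upstream-left corner of the 410 x 150 footprint)."""
    L, W, t = spec.length, spec.width, spec.wall_thickness
    g = spec.funnel_gap_width
    tan_a = np.tan(np.deg2rad(spec.funnel_half_angle))
    yc = W / 2.0
    # arm centerline: from the gap-edge tip (apex) down to the rail centerline
    tip_y = yc - g / 2.0 - t / 2.0     # tip center keeps the gap edge at g/2
    sweep = (tip_y - t / 2.0) / tan_a  # x-extent of an arm centerline
    # apex stations: funnels "with flow" open upstream and narrow downstream
    # (apex gap at larger x, arms sweeping back); "against flow" mirrored.
    n_with = spec.funnels_with_flow
    n_against = spec.funnels_against_flow
    n = n_with + n_against
    margin = sweep + t / 2.0 + t / 4.0
    stations = np.linspace(margin, L - margin, n)
    if stations[0] < 0 or (n > 1 and stations[1] - stations[0] < t):
        raise ValueError("microtrap funnels do not fit in the footprint")
    segments = []  # (p0, p1, thickness)
    gap_rects = []  # (x0, x1, y0, y1) sealing rectangles for cavity labeling
    corners = []
    gap_centers = []
    # side rails along both long edges (endpoints inset by the cap radius
    # so the rounded capsule ends stay inside the footprint)
    segments.append(((t / 2.0, t / 2.0), (L - t / 2.0, t / 2.0), t))
    segments.append(((t / 2.0, W - t / 2.0), (L - t / 2.0, W - t / 2.0), t))
    for i, xa in enumerate(stations):
        sgn = +1.0 if i < n_with else -1.0  # +1: apex downstream ('>')
        for side in (+1.0, -1.0):  # upper / lower arm
            tip = (xa, yc - side * (yc - tip_y))
            root = (xa - sgn * sweep, yc - side * (yc - t / 2.0))
            segments.append((tip, root, t))
            corners.append((root[0], yc - side * (yc - t)))
        gap_rects.append((xa - t / 2.0, xa + t / 2.0,
                          yc - g / 2.0, yc + g / 2.0))
        gap_centers.append((xa, yc))
    return {
        "segments": segments,
        "gap_rects": gap_rects,
        "corners": corners,
        "gap_centers": gap_centers,
        "stations": list(stations),
    }


def _label_cavities(open_mask: np.ndarray) -> np.ndarray:
    """Label connected open regions that do not touch the array border,
    numbered in order of increasing centroid x (column)."""
    lab, n = ndimage.label(open_mask)
    if n == 0:
        return np.zeros_like(lab)
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0],
                                       lab[:, -1]]))
    keep = [i for i in range(1, n + 1) if i not in border]
    out = np.zeros_like(lab)
    if not keep:
        return out
    cx = ndimage.center_of_mass(open_mask, lab, keep)
    order = np.argsort([c[1] for c in cx])
    for new, idx in enumerate(order, start=1):
        out[lab == keep[idx]] = new
    return out


def build_microtrap(spec: MicrotrapSpec,
                    channel: ChannelSpec) -> DepthMap:
    """Rasterize a microtrap centered in the channel analysis area.

    The clearance is the channel height over open floor and
    ``channel.height - spec.feature_height`` over walls.  Cavity regions
    (connected open regions enclosed by walls except at the funnel gaps)
    are labeled 1..5 in downstream order in ``cavity_labels``.
    """
    if spec.feature_height >= channel.height:
        raise ValueError("feature height must be below the channel height")
    ax, ay = channel.analysis_area
    if spec.length > ax or spec.width > ay:
        raise ValueError("microtrap larger than the analysis area")
    xg, yg = _grid_for(channel)
    geo = _microtrap_segments(spec)
    # trap-local -> analysis-area coordinates (trap centered)
    ox = (ax - spec.length) / 2.0
    oy = (ay - spec.width) / 2.0
    solid = np.zeros((yg.size, xg.size), dtype=bool)
    for p0, p1, t in geo["segments"]:
        solid |= _capsule_mask(xg, yg, (p0[0] + ox, p0[1] + oy),
                               (p1[0] + ox, p1[1] + oy), t)
    h = np.where(solid, channel.height - spec.feature_height, channel.height)
    # seal funnel gaps, then label enclosed open regions inside the bbox
    sealed = solid.copy()
    for x0, x1, y0, y1 in geo["gap_rects"]:
        ixs = (xg >= x0 + ox) & (xg <= x1 + ox)
        iys = (yg >= y0 + oy) & (yg <= y1 + oy)
        sealed[np.ix_(iys, ixs)] = True
    bx0, bx1 = ox, ox + spec.length
    by0, by1 = oy, oy + spec.width
    in_bbox_x = (xg >= bx0) & (xg <= bx1)
    in_bbox_y = (yg >= by0) & (yg <= by1)
    sub = ~sealed[np.ix_(in_bbox_y, in_bbox_x)]
    sub_labels = _label_cavities(sub)
    labels = np.zeros_like(solid, dtype=np.int32)
    labels[np.ix_(in_bbox_y, in_bbox_x)] = sub_labels
    d = channel.grid_spacing
    # representative interior point per cavity: the cavities are chevron
    # shaped (non-convex), so the raw centroid can fall on a wall; take the
    # open cell farthest from any wall (where the cavity vortex core and
    # the observed colony sites sit)
    centroids = []
    dist = ndimage.distance_transform_edt(~solid) * d
    for i in range(1, sub_labels.max() + 1):
        mask = labels == i
        cy_i, cx_i = np.unravel_index(
            np.argmax(np.where(mask, dist, -1.0)), mask.shape)
        centroids.append(((cx_i + 0.5) * d, (cy_i + 0.5) * d))
    landmarks = {
        "trap_bbox": (bx0, by0, bx1, by1),
        "corners": [(x + ox, y + oy) for x, y in geo["corners"]],
        "gap_centers": [(x + ox, y + oy) for x, y in geo["gap_centers"]],
        "cavity_centroids": centroids,
        "wall_thickness": spec.wall_thickness,
    }
    dm = DepthMap(clearance=h, grid_spacing=d, channel_height=channel.height,
                  feature_height=spec.feature_height, solid_mask=solid,
                  cavity_labels=labels, landmarks=landmarks)
    return dm


def build_arrow_array(spec: ArrowSpec, channel: ChannelSpec) -> DepthMap:
    """Rasterize a streamwise line of arrow (chevron) features centered in
    the analysis area; arrows point against the flow (apex upstream), so the
    cavity of each chevron opens downstream."""
    if spec.count == 0:
        return build_channel(channel)
    if spec.feature_height >= channel.height:
        raise ValueError("feature height must be below the channel height")
    ax, ay = channel.analysis_area
    pitch = spec.length + spec.spacing
    t = spec.width  # the 20 um dimension is the wall thickness
    tan_a = np.tan(np.deg2rad(spec.half_angle))
    span = spec.length            # across-flow extent of the chevron
    sweep = (span / 2.0 - t / 2.0) / tan_a
    total = (spec.count - 1) * pitch + sweep + t
    if total > ax or span > ay:
        raise ValueError("arrow array larger than the analysis area")
    xg, yg = _grid_for(channel)
    yc = ay / 2.0
    x_first = (ax - (spec.count - 1) * pitch) / 2.0
    solid = np.zeros((yg.size, xg.size), dtype=bool)
    apexes = []
    for k in range(spec.count):
        xa = x_first + k * pitch  # apex (upstream-most point)
        for side in (+1.0, -1.0):
            tip = (xa, yc)
            root = (xa + sweep, yc + side * (span / 2.0 - t / 2.0))
            solid |= _capsule_mask(xg, yg, tip, root, t)
        apexes.append((xa, yc))
    h = np.where(solid, channel.height - spec.feature_height, channel.height)
    landmarks = {"apexes": apexes, "pitch": pitch}
    return DepthMap(clearance=h, grid_spacing=channel.grid_spacing,
                    channel_height=channel.height,
                    feature_height=spec.feature_height, solid_mask=solid,
                    landmarks=landmarks)


_SPEC_CLASSES = {"channel": ChannelSpec, "microtrap": MicrotrapSpec,
                 "arrow": ArrowSpec, "fluid": FluidProperties}


def load_config(path: str) -> dict:
    """Read a geometry/fluid configuration file (YAML or JSON).

    The file maps section names (``channel``, ``microtrap``, ``arrow``,
    ``fluid``) to keyword dictionaries for the corresponding spec
    dataclasses; unknown sections raise.  Returns a dict of constructed
    spec objects.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    out = {}
    for section, kwargs in raw.items():
        try:
            cls = _SPEC_CLASSES[section]
        except KeyError:
            raise ValueError(f"unknown config section {section!r}") from None
        kwargs = dict(kwargs or {})
        if "analysis_area" in kwargs:
            kwargs["analysis_area"] = tuple(kwargs["analysis_area"])
        out[section] = cls(**kwargs)
    return out


# ---------------------------------------------------------------------------
# dimensionless numbers and particle physics


def _flow_rate_um3_s(flow_rate_ul_min: float) -> float:
    return flow_rate_ul_min * 1.0e9 / 60.0


def mean_velocity(flow_rate: float, channel: ChannelSpec) -> float:
    """Mean streamwise velocity U = Q / (w h) in um/s for a flow rate in
    uL/min."""
    if flow_rate < 0:
        raise ValueError("flow rate must be >= 0")
    area = channel.cross_section_um2
    if area <= 0:
        raise ValueError("channel cross-section must be positive")
    return _flow_rate_um3_s(flow_rate) / area


def reynolds_number(flow_rate: float, channel: ChannelSpec,
                    fluid: FluidProperties = WATER,
                    length_scale: str = "hydraulic_diameter",
                    feature_height: float = 10.0) -> float:
    """Channel Reynolds number Re = rho U L / mu.

    ``length_scale`` selects the characteristic length: the hydraulic
    diameter 2wh/(w+h) of the wide slot, the channel height, or the feature
    height (the convention under which the low/high flow rates map to
    Re ~ 0.001 / 0.01).  U is the mean velocity Q/(w h).
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be >= 0")
    scales = {
        "hydraulic_diameter":
            2.0 * channel.width * channel.height
            / (channel.width + channel.height),
        "channel_height": channel.height,
        "feature_height": feature_height,
    }
    try:
        L_um = scales[length_scale]
    except KeyError:
        raise ValueError(f"unknown length_scale {length_scale!r}") from None
    U = mean_velocity(flow_rate, channel) * 1e-6  # m/s
    return fluid.density * U * (L_um * 1e-6) / fluid.dynamic_viscosity


def peclet_number(velocity: float, length: float, diffusivity: float) -> float:
    """Peclet number Pe = v L / D (velocity um/s, length um, D um^2/s)."""
    if velocity < 0 or length < 0:
        raise ValueError("velocity and length must be >= 0")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    return velocity * length / diffusivity


def stokes_einstein_diffusivity(radius: float,
                                fluid: FluidProperties = WATER) -> float:
    """Brownian diffusivity D = kT / (6 pi mu r) in um^2/s for a particle
    radius in um."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    T = fluid.temperature + 273.15
    D_m2s = _KB * T / (6.0 * np.pi * fluid.dynamic_viscosity * radius * 1e-6)
    return D_m2s * 1e12


def settling_velocity(diameter: float, particle_density: float,
                      fluid: FluidProperties = WATER) -> float:
    """Stokes settling velocity v = (rho_p - rho_f) g d^2 / (18 mu), um/s.

    ``particle_density`` is in g/mL; a positive value means the particle
    sinks (density 1.3 g/mL for the polymer tracers vs 1.1 for live cells).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    drho = particle_density * 1000.0 - fluid.density  # kg/m^3
    d_m = diameter * 1e-6
    v_ms = drho * _G * d_m * d_m / (18.0 * fluid.dynamic_viscosity)
    return v_ms * 1e6
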