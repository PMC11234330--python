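"""Creeping-flow solvers and vortex metrics.

Two complementary models are provided, both valid in the Stokes regime
(Re << 1) of the shallow channel:

* :func:`solve_depth_averaged` — plan-view (XY) lubrication / Hele-Shaw
  model.  In a thin gap of local clearance ``h(x, y)`` the depth-integrated
  flux is ``q = -(h^3 / 12 mu) grad p`` and mass conservation gives
  ``div(h^3 grad p) = 0``.  Features that occupy part of the channel height
  enter through ``h``: flow passes over them but with a conductance reduced
  by ``(h_wall / h_open)^3``.  Where ``h`` is uniform the depth-averaged
  velocity is a potential flow; in-plane vorticity is generated only where
  the clearance varies (feature edges).

* :func:`solve_vertical_slice` — full 2-D incompressible Stokes flow in a
  streamwise vertical (XZ) plane over a clearance profile taken from a
  depth map.  This resolves the closed recirculation (cavity eddies) that a
  depth-averaged model cannot represent: flow passing over the feature tops
  drives lid-driven-cavity-like vortices between the walls.

Vortex metrics follow the standard definitions: vorticity
``omega = dv/dx - du/dy`` and Q-criterion
``Q = (||Omega||^2 - ||S||^2) / 2`` with ``Omega`` and ``S`` the
antisymmetric and symmetric parts of the velocity gradient; ``Q > 0`` marks
regions where rotation dominates strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from trapflow.geometry import (
    ChannelSpec,
    DepthMap,
    FluidProperties,
    WATER,
    _flow_rate_um3_s,
)

__all__ = [
    "FlowField2D",
    "ScalarField",
    "SolverError",
    "solve_depth_averaged",
    "solve_vertical_slice",
    "vorticity",
    "q_criterion",
    "speed",
    "streamlines",
    "streamlines_to_csv",
]


class SolverError(RuntimeError):
    """Raised when a flow solve fails to produce a valid field."""


@dataclass
class FlowField2D:
    """Gridded velocity field on cell centers.

    ``plane`` is ``"XY_depth_averaged"`` (u, v are depth-averaged in-plane
    velocities, um/s) or ``"XZ_slice"`` (v holds the vertical velocity w).
    For the XY model ``pressure`` (Pa) and the conservative face fluxes are
    kept so that flux invariants can be audited exactly.
    """

    u: np.ndarray
    v: np.ndarray
    plane: str
    grid_spacing: float
    flow_rate: float
    pressure: np.ndarray | None = None
    depth: DepthMap | None = None
    # depth-integrated face fluxes (um^3/s per face), XY model only
    face_flux_x: np.ndarray | None = None  # (ny, nx+1)
    face_flux_y: np.ndarray | None = None  # (ny+1, nx)
    # XZ slice extras
    clearance_profile: np.ndarray | None = None
    channel_height: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    # ---- conservation audits (XY model) ----------------------------------
    def depth_flux_divergence(self) -> float:
        """Maximum cell-wise divergence of the depth flux, relative to the
        mean face-flux magnitude."""
        if self.face_flux_x is None or self.face_flux_y is None:
            raise ValueError("face fluxes only available for the XY model")
        div = (np.diff(self.face_flux_x, axis=1)
               + np.diff(self.face_flux_y, axis=0))
        scale = np.mean(np.abs(self.face_flux_x)) + 1e-300
        return float(np.max(np.abs(div)) / scale)

    def cross_section_flux(self, ix: int) -> float:
        """Total volumetric flux (um^3/s) through the transverse section at
        x-face ``ix`` (0..nx)."""
        if self.face_flux_x is None:
            raise ValueError("face fluxes only available for the XY model")
        return float(self.face_flux_x[:, ix].sum())

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.tif`` (channels u, v and, when present, p as
        32-bit float planes) and ``<prefix>.json`` metadata."""
        import json

        import tifffile

        planes = [self.u, self.v]
        names = ["u_um_s", "v_um_s"]
        if self.pressure is not None:
            planes.append(self.pressure)
            names.append("p_Pa")
        tifffile.imwrite(f"{prefix}.tif",
                         np.stack(planes).astype(np.float32),
                         photometric="minisblack")
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"channels": names, "plane": self.plane,
                       "grid_spacing_um": self.grid_spacing,
                       "flow_rate_ul_min": self.flow_rate}, fh, indent=1)

    # ---- XZ slice extras -------------------------------------------------
    def streamfunction(self) -> np.ndarray:
        """Streamfunction psi(z, x) (um^2/s) for an XZ slice, psi = 0 at the
        floor; closed recirculation shows as a sign change of psi."""
        if self.plane != "XZ_slice":
            raise ValueError("streamfunction is defined for XZ slices")
        return np.cumsum(self.u, axis=0) * self.grid_spacing


@dataclass
class ScalarField:
    """Scalar derived from a flow field (same grid)."""

    values: np.ndarray
    kind: str  # "vorticity" (1/s), "q_criterion" (1/s^2), "speed" (um/s)
    grid_spacing: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# depth-averaged (Hele-Shaw) plan-view solver


def solve_depth_averaged(depth: DepthMap, flow_rate: float,
                         fluid: FluidProperties = WATER,
                         channel: ChannelSpec | None = None) -> FlowField2D:
    """Solve ``div(h^3/(12 mu) grad p) = 0`` on the depth map.

    Boundary conditions: uniform inflow flux on the upstream (x = 0) edge
    corresponding to ``flow_rate`` distributed over the full channel width,
    zero pressure on the downstream edge, no flux through the side walls.
    The depth-averaged velocity is ``(u, v) = -(h^2 / 12 mu) grad p``.

    The discrete system is a finite-volume Laplacian with harmonic-mean face
    transmissibilities, solved by a sparse direct factorization, so the
    returned field conserves the depth flux to machine precision.
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be >= 0")
    h = depth.clearance
    ny, nx = h.shape
    d = depth.grid_spacing
    mu = fluid.dynamic_viscosity
    width = channel.width if channel is not None else 5000.0
    if channel is not None and depth.channel_height != channel.height:
        raise ValueError("depth map and channel height disagree")

    T = h ** 3 / (12.0 * mu)  # transmissibility per unit width, um^2/s * um
    # harmonic-mean face transmissibilities
    Tx = np.zeros((ny, nx + 1))
    Ty = np.zeros((ny + 1, nx))
    Tx[:, 1:-1] = 2.0 * T[:, :-1] * T[:, 1:] / (T[:, :-1] + T[:, 1:])
    Ty[1:-1, :] = 2.0 * T[:-1, :] * T[1:, :] / (T[:-1, :] + T[1:, :])
    # outlet (east) Dirichlet p = 0 through a half-cell
    Tx[:, -1] = 2.0 * T[:, -1]

    q_in = _flow_rate_um3_s(flow_rate) / width  # um^2/s per unit width

    idx = np.arange(ny * nx).reshape(ny, nx)
    cw = Tx[:, :-1] / d * d   # conductance = T * face_len / dist = T
    ce = Tx[:, 1:] / d * d
    cs = Ty[:-1, :] / d * d
    cn = Ty[1:, :] / d * d
    diag = cw + ce + cs + cn
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    add(idx, idx, diag)
    add(idx[:, 1:], idx[:, :-1], -cw[:, 1:])
    add(idx[:, :-1], idx[:, 1:], -ce[:, :-1])
    add(idx[1:, :], idx[:-1, :], -cs[1:, :])
    add(idx[:-1, :], idx[1:, :], -cn[:-1, :])
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx))
    b = np.zeros(ny * nx)
    b[idx[:, 0]] = q_in * d  # inflow volumetric flux per inlet cell face

    if flow_rate == 0:
        p = np.zeros((ny, nx))
    else:
        p = spsolve(A, b).reshape(ny, nx)
        if not np.all(np.isfinite(p)):
            raise SolverError("pressure solve produced non-finite values")

    # conservative face fluxes (um^3/s): Q_f = T_f * (p_up - p_down)
    qx = np.zeros((ny, nx + 1))
    qx[:, 1:-1] = Tx[:, 1:-1] * (p[:, :-1] - p[:, 1:])
    qx[:, 0] = q_in * d
    qx[:, -1] = Tx[:, -1] * (p[:, -1] - 0.0)
    qy = np.zeros((ny + 1, nx))
    qy[1:-1, :] = Ty[1:-1, :] * (p[:-1, :] - p[1:, :])

    # cell-center velocities: average adjacent face fluxes / (h * face_len)
    u = 0.5 * (qx[:, :-1] + qx[:, 1:]) / (h * d)
    v = 0.5 * (qy[:-1, :] + qy[1:, :]) / (h * d)
    return FlowField2D(u=u, v=v, plane="XY_depth_averaged", grid_spacing=d,
                       flow_rate=flow_rate, pressure=p, depth=depth,
                       face_flux_x=qx, face_flux_y=qy)


# ---------------------------------------------------------------------------
# vertical-slice Stokes solver (MAC grid, direct solve)


def solve_vertical_slice(clearance_profile: np.ndarray, grid_spacing: float,
                         flow_rate: float,
                         fluid: FluidProperties = WATER,
                         channel: ChannelSpec = ChannelSpec(),
                         dz: float = 0.5,
                         mean_velocity_override: float | None = None,
                         ) -> FlowField2D:
    """2-D incompressible Stokes flow in a streamwise vertical (XZ) plane.

    ``clearance_profile`` is the 1-D clearance h(x) along a streamwise line
    of a depth map (um, sampled at ``grid_spacing``); features rise from the
    floor, so the open fluid region at station x is ``z in [H - h(x), H]``
    with H the channel height.  No-slip applies on the floor, the ceiling
    and the (staircase) feature boundary.  A parabolic profile with the mean
    velocity ``Q / (w H)`` is imposed at the inlet and outlet (both ends of
    the profile should therefore be feature-free).

    The discretization is a staggered (MAC) grid; momentum and continuity
    are assembled into one sparse saddle-point system and solved directly.

    Returns a :class:`FlowField2D` with ``plane="XZ_slice"``; ``u`` is the
    streamwise and ``v`` the vertical velocity at cell centers, arrays
    indexed ``[iz, ix]`` with z increasing away from the floor.
    """
    hprof = np.asarray(clearance_profile, dtype=float)
    if hprof.ndim != 1 or hprof.size < 4:
        raise ValueError("clearance_profile must be a 1-D array (>= 4 cells)")
    H = channel.height
    if np.any(hprof <= 0) or np.any(hprof > H + 1e-9):
        raise ValueError("clearance must lie in (0, channel height]")
    dx = grid_spacing
    nx = hprof.size
    nz = int(round(H / dz))
    if abs(nz * dz - H) > 1e-9:
        raise ValueError("dz must divide the channel height")
    mu = fluid.dynamic_viscosity
    if mean_velocity_override is not None:
        U = mean_velocity_override
    else:
        U = _flow_rate_um3_s(flow_rate) / channel.cross_section_um2
    zc = (np.arange(nz) + 0.5) * dz          # cell-center z
    floor_z = H - hprof                       # local feature-top height
    solid_cell = zc[:, None] < floor_z[None, :] - 1e-9  # (nz, nx)

    if U == 0.0:
        zero = np.zeros((nz, nx))
        return FlowField2D(u=zero, v=zero.copy(), plane="XZ_slice",
                           grid_spacing=dx, flow_rate=flow_rate,
                           clearance_profile=hprof, channel_height=H)

    # unknown layout: u (nz, nx+1) at x-faces, w (nz+1, nx) at z-faces,
    # p (nz, nx) at centers
    nu = nz * (nx + 1)
    nw = (nz + 1) * nx
    npp = nz * nx
    iu = np.arange(nu).reshape(nz, nx + 1)
    iw = np.arange(nw).reshape(nz + 1, nx) + nu
    ip = np.arange(npp).reshape(nz, nx) + nu + nw
    N = nu + nw + npp

    u_solid = np.zeros((nz, nx + 1), dtype=bool)
    u_solid[:, 1:-1] = solid_cell[:, :-1] | solid_cell[:, 1:]
    u_solid[:, 0] = solid_cell[:, 0]
    u_solid[:, -1] = solid_cell[:, -1]
    w_solid = np.zeros((nz + 1, nx), dtype=bool)
    w_solid[1:-1, :] = solid_cell[:-1, :] | solid_cell[1:, :]
    w_solid[0, :] = True    # floor
    w_solid[-1, :] = True   # ceiling

    rows, cols, vals, rhs = [], [], [], np.zeros(N)

    def add(r, c, v):
        rows.append(int(r))
        cols.append(int(c))
        vals.append(float(v))

    u_in = 6.0 * U * zc * (H - zc) / (H * H)  # parabolic inlet/outlet profile

    # --- u-momentum -------------------------------------------------------
    for k in range(nz):
        for i in range(nx + 1):
            r = iu[k, i]
            if i == 0 or i == nx:               # Dirichlet inlet/outlet
                add(r, r, 1.0)
                rhs[r] = u_in[k]
                continue
            if u_solid[k, i]:                   # no-slip on feature
                add(r, r, 1.0)
                continue
            # viscous Laplacian; ghost across floor/ceiling: u_ghost = -u
            cx = mu / dx ** 2
            cz = mu / dz ** 2
            diag = -2.0 * cx - 2.0 * cz
            add(r, iu[k, i - 1], cx)
            add(r, iu[k, i + 1], cx)
            if k > 0:
                add(r, iu[k - 1, i], cz)
            else:
                diag -= cz                      # wall at z=0
            if k < nz - 1:
                add(r, iu[k + 1, i], cz)
            else:
                diag -= cz                      # wall at z=H
            add(r, r, diag)
            add(r, ip[k, i], -1.0 / dx)
            add(r, ip[k, i - 1], 1.0 / dx)
    # --- w-momentum -------------------------------------------------------
    for k in range(nz + 1):
        for i in range(nx):
            r = iw[k, i]
            if w_solid[k, i]:
                add(r, r, 1.0)
                continue
            cx = mu / dx ** 2
            cz = mu / dz ** 2
            diag = -2.0 * cx - 2.0 * cz
            add(r, iw[k - 1, i], cz)
            add(r, iw[k + 1, i], cz)
            if i > 0:
                add(r, iw[k, i - 1], cx)
            else:
                diag += cx                      # d w / d x = 0 at inlet
            if i < nx - 1:
                add(r, iw[k, i + 1], cx)
            else:
                diag += cx                      # d w / d x = 0 at outlet
            add(r, r, diag)
            add(r, ip[k, i], -1.0 / dz)
            add(r, ip[k - 1, i], 1.0 / dz)
    # --- continuity (tiny pressure regularization fixes the gauge) --------
    eps = 1e-9 / mu
    for k in range(nz):
        for i in range(nx):
            r = ip[k, i]
            if solid_cell[k, i]:
                add(r, r, 1.0)
                continue
            add(r, iu[k, i + 1], 1.0 / dx)
            add(r, iu[k, i], -1.0 / dx)
            add(r, iw[k + 1, i], 1.0 / dz)
            add(r, iw[k, i], -1.0 / dz)
            add(r, r, eps)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N))
    sol = spsolve(A, rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("vertical-slice Stokes solve failed")
    u_f = sol[:nu].reshape(nz, nx + 1)
    w_f = sol[nu:nu + nw].reshape(nz + 1, nx)
    u_c = 0.5 * (u_f[:, :-1] + u_f[:, 1:])
    w_c = 0.5 * (w_f[:-1, :] + w_f[1:, :])
    u_c[solid_cell] = 0.0
    w_c[solid_cell] = 0.0
    return FlowField2D(u=u_c, v=w_c, plane="XZ_slice", grid_spacing=dx,
                       flow_rate=flow_rate, clearance_profile=hprof,
                       channel_height=H)


# ---------------------------------------------------------------------------
# derived scalar fields


def _gradients(field: FlowField2D):
    d = field.grid_spacing
    # axis 0 is y (XY) or z (XZ); axis 1 is x
    dudy, dudx = np.gradient(field.u, d, d)
    dvdy, dvdx = np.gradient(field.v, d, d)
    return dudx, dudy, dvdx, dvdy


def vorticity(field: FlowField2D) -> ScalarField:
    """Out-of-plane vorticity ``omega = dv/dx - du/dy`` (1/s) by centered
    differences (``du/dz`` for an XZ slice)."""
    dudx, dudy, dvdx, dvdy = _gradients(field)
    return ScalarField(values=dvdx - dudy, kind="vorticity",
                       grid_spacing=field.grid_spacing)


def q_criterion(field: FlowField2D) -> ScalarField:
    """Q-criterion ``Q = (||Omega||^2 - ||S||^2) / 2`` (1/s^2).

    For a 2-D field this reduces to
    ``Q = -(du/dx)^2/2 - (dv/dy)^2/2 - (du/dy)(dv/dx)``; rigid rotation at
    rate omega gives ``Q = omega^2``, simple shear gives 0, pure strain at
    rate gamma gives ``-gamma^2``.
    """
    dudx, dudy, dvdx, dvdy = _gradients(field)
    Q = -0.5 * (dudx ** 2 + dvdy ** 2) - dudy * dvdx
    return ScalarField(values=Q, kind="q_criterion",
                       grid_spacing=field.grid_spacing)


def speed(field: FlowField2D) -> ScalarField:
    """Velocity magnitude (um/s)."""
    return ScalarField(values=field.speed(), kind="speed",
                       grid_spacing=field.grid_spacing)


# ---------------------------------------------------------------------------
# streamlines


def _bilinear(grid: np.ndarray, d: float, x: float, y: float) -> float:
    """Bilinear interpolation on a cell-centered grid (domain-local
    coordinates); clamps to the boundary cells."""
    ny, nx = grid.shape
    fx = np.clip(x / d - 0.5, 0.0, nx - 1.0)
    fy = np.clip(y / d - 0.5, 0.0, ny - 1.0)
    i0 = int(min(fx, nx - 2)) if nx > 1 else 0
    j0 = int(min(fy, ny - 2)) if ny > 1 else 0
    tx = fx - i0
    ty = fy - j0
    return float(grid[j0, i0] * (1 - tx) * (1 - ty)
                 + grid[j0, i0 + 1] * tx * (1 - ty)
                 + grid[j0 + 1, i0] * (1 - tx) * ty
                 + grid[j0 + 1, i0 + 1] * tx * ty)


def streamlines(field: FlowField2D, seeds=None,
                step: float = 1.0, max_steps: int = 20000,
                stagnation_speed: float = 1e-9) -> list[np.ndarray]:
    """Integrate streamlines with classical RK4.

    ``seeds`` are (x, y) points in domain-local coordinates (um).  Each
    polyline ends when it leaves the domain, stalls below
    ``stagnation_speed`` (um/s), or exhausts ``max_steps``.
    """
    if seeds is None:
        raise ValueError("seeds are required")
    ny, nx = field.shape
    d = field.grid_spacing
    Lx, Ly = nx * d, ny * d

    def vel(p):
        return np.array([_bilinear(field.u, d, p[0], p[1]),
                         _bilinear(field.v, d, p[0], p[1])])

    out = []
    for seed in seeds:
        p = np.asarray(seed, dtype=float)
        if not (0 <= p[0] <= Lx and 0 <= p[1] <= Ly):
            raise ValueError(f"seed {tuple(p)} outside the domain")
        pts = [p.copy()]
        for _ in range(max_steps):
            v1 = vel(p)
            sp = np.hypot(*v1)
            if sp < stagnation_speed:
                break
            hstep = step / sp  # arc-length parametrized step
            v2 = vel(p + 0.5 * hstep * v1)
            v3 = vel(p + 0.5 * hstep * v2)
            v4 = vel(p + hstep * v3)
            p = p + (hstep / 6.0) * (v1 + 2 * v2 + 2 * v3 + v4)
            if not (0 <= p[0] <= Lx and 0 <= p[1] <= Ly):
                break
            pts.append(p.copy())
        out.append(np.array(pts))
    return out


def streamlines_to_csv(lines, path: str) -> None:
    """Write streamline polylines as CSV (polyline_id, x, y)."""
    import pandas as pd

    frames = [
        {"polyline_id": np.full(len(line), i), "x": line[:, 0],
         "y": line[:, 1]} for i, line in enumerate(lines)]
    pd.concat([pd.DataFrame(f) for f in frames],
              ignore_index=True).to_csv(path, index=False)
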