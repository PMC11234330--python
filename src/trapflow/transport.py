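"""Tracer-particle transport: Brownian dynamics in a flow field, and
trap-occupancy statistics.

The tracers model the fluorescent polymer microspheres used as passive
flow markers (1-5 um diameter, 1.3 g/mL): advection by the local fluid
velocity, isotropic Brownian motion with the Stokes-Einstein diffusivity,
and gravitational settling in z (the spheres are slightly denser than
water and than live cells).  Active motility is deliberately absent - the
tracers are the hydrodynamic null model.

The composition is 2.5-D: in-plane motion follows the depth-averaged
(XY) velocity field, while z evolves independently through settling and
Brownian motion, clipped to the local clearance.  This is an approximation
(vertical advection by the 3-D flow is not fed back into the XY motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trapflow.flowsim import FlowField2D
from trapflow.geometry import (
    DepthMap,
    FluidProperties,
    WATER,
    settling_velocity,
    stokes_einstein_diffusivity,
)

__all__ = ["ParticleSpec", "TrajectorySet", "OccupancyStats", "advect",
           "trap_occupancy"]


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical tracer particle.

    diameter in um (0.5-10), density in g/mL; ``diffusivity_override``
    (um^2/s) replaces the Stokes-Einstein value when given (set it to 0 for
    purely deterministic advection).
    """

    diameter: float = 2.0
    density: float = 1.3
    diffusivity_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.diameter <= 10.0:
            raise ValueError("diameter must be in [0.5, 10] um")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def diffusivity(self, fluid: FluidProperties = WATER) -> float:
        """Brownian diffusivity in um^2/s."""
        if self.diffusivity_override is not None:
            return self.diffusivity_override
        return stokes_einstein_diffusivity(self.diameter / 2.0, fluid)


@dataclass
class TrajectorySet:
    """Time-stamped particle positions.

    ``positions`` has shape (n_particles, n_times, 3) in um; ``exited``
    flags particles absorbed at the downstream outlet (their position is
    frozen at the exit point from that time on).
    """

    t: np.ndarray
    positions: np.ndarray
    spec: ParticleSpec
    rng_seed: int
    exited: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.exited is None:
            self.exited = np.zeros(self.positions.shape[0], dtype=bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def velocities(self) -> np.ndarray:
        """Per-step planar velocities, shape (n, nt-1, 2), um/s."""
        dt = np.diff(self.t)[None, :, None]
        return np.diff(self.positions[:, :, :2], axis=1) / dt

    def to_dataframe(self) -> pd.DataFrame:
        n, nt, _ = self.positions.shape
        return pd.DataFrame({
            "particle_id": np.repeat(np.arange(n), nt),
            "t": np.tile(self.t, n),
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "z": self.positions[:, :, 2].ravel(),
        })


@dataclass
class OccupancyStats:
    """Cavity-visit statistics for a trajectory set."""

    visit_counts: dict[int, int] = field(default_factory=dict)
    mean_residence_time: float = 0.0
    trapped_fraction: float = 0.0
    n_particles: int = 0


def advect(fieldxy: FlowField2D, spec: ParticleSpec, n_particles: int,
           duration: float, dt: float = 1e-3, rng_seed: int = 0,
           fluid: FluidProperties = WATER,
           start_positions: np.ndarray | None = None,
           record_every: int = 1) -> TrajectorySet:
    """Euler-Maruyama advection of ``n_particles`` tracers.

    Update per step: ``x <- x + u(x) dt + sqrt(2 D dt) xi`` with independent
    standard normal ``xi`` per axis; ``z`` additionally settles at the
    Stokes velocity.  Side walls and the upstream edge reflect specularly;
    the downstream edge absorbs; cells whose clearance is below the particle
    diameter reject the in-plane step (particles cannot enter gaps narrower
    than themselves); ``z`` is clipped to ``[r, h(x, y) - r]`` with r the
    particle radius.

    ``dt`` must satisfy the CFL-like guard ``dt <= grid_spacing / max
    speed``.  With a fixed ``rng_seed`` the result is bit-reproducible.
    """
    depth = fieldxy.depth
    d = fieldxy.grid_spacing
    ny, nx = fieldxy.shape
    vmax = float(fieldxy.speed().max())
    if vmax > 0 and dt > d / vmax:
        raise ValueError(
            f"dt={dt} violates the step guard grid_spacing/max_speed="
            f"{d / vmax:.3g}")
    rng = np.random.default_rng(rng_seed)
    D = spec.diffusivity(fluid)
    vz = settling_velocity(spec.diameter, spec.density, fluid)
    radius = spec.diameter / 2.0
    Lx, Ly = nx * d, ny * d
    H = depth.channel_height if depth is not None else 15.0

    if start_positions is None:
        pos = np.column_stack([
            rng.uniform(0.0, 0.05 * Lx, n_particles),
            rng.uniform(0.0, Ly, n_particles),
            rng.uniform(radius, H - radius, n_particles),
        ])
    else:
        pos = np.array(start_positions, dtype=float)
        if pos.shape != (n_particles, 3):
            raise ValueError("start_positions must have shape (n, 3)")

    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_every + 1
    out = np.empty((n_particles, n_rec, 3))
    out[:, 0] = pos
    t_rec = np.empty(n_rec)
    t_rec[0] = 0.0
    exited = np.zeros(n_particles, dtype=bool)
    sq = np.sqrt(2.0 * D * dt)

    def clearance_at(p):
        if depth is None:
            return np.full(p.shape[0], H)
        ix = np.clip((p[:, 0] / d).astype(int), 0, nx - 1)
        iy = np.clip((p[:, 1] / d).astype(int), 0, ny - 1)
        return depth.clearance[iy, ix]

    u, v = fieldxy.u, fieldxy.v
    rec = 1
    for step in range(1, n_steps + 1):
        act = ~exited
        if act.any():
            p = pos[act]
            ix = np.clip((p[:, 0] / d).astype(int), 0, nx - 1)
            iy = np.clip((p[:, 1] / d).astype(int), 0, ny - 1)
            disp = np.empty_like(p)
            disp[:, 0] = u[iy, ix] * dt
            disp[:, 1] = v[iy, ix] * dt
            disp[:, 2] = -vz * dt
            if D > 0:
                disp += sq * rng.standard_normal(p.shape)
            newp = p + disp
            # reflect at side walls and upstream edge
            newp[:, 1] = np.where(newp[:, 1] < 0, -newp[:, 1], newp[:, 1])
            newp[:, 1] = np.where(newp[:, 1] > Ly, 2 * Ly - newp[:, 1],
                                  newp[:, 1])
            newp[:, 0] = np.where(newp[:, 0] < 0, -newp[:, 0], newp[:, 0])
            # narrow-clearance cells reject the in-plane move
            h_new = clearance_at(newp)
            blocked = h_new < spec.diameter
            newp[blocked, 0] = p[blocked, 0]
            newp[blocked, 1] = p[blocked, 1]
            # clip z to the local gap
            h_here = clearance_at(newp)
            newp[:, 2] = np.clip(newp[:, 2], radius,
                                 np.maximum(h_here - radius, radius))
            # absorb at the downstream outlet
            out_now = newp[:, 0] >= Lx
            newp[out_now, 0] = Lx
            pos[act] = newp
            idx_act = np.flatnonzero(act)
            exited[idx_act[out_now]] = True
        if step % record_every == 0:
            out[:, rec] = pos
            t_rec[rec] = step * dt
            rec += 1
    return TrajectorySet(t=t_rec[:rec], positions=out[:, :rec], spec=spec,
                         rng_seed=rng_seed, exited=exited)


def trap_occupancy(traj: TrajectorySet, depth: DepthMap) -> OccupancyStats:
    """Per-cavity visit counts, mean residence time and trapped fraction.

    A particle "visits" a cavity when its (x, y) sample falls in a labeled
    cavity cell; a residence is a maximal run of consecutive samples inside
    any cavity; the trapped fraction is the fraction of particles inside a
    cavity at the final time.
    """
    stats = OccupancyStats(n_particles=traj.n_particles)
    if depth.cavity_labels is None or depth.cavity_labels.max() == 0:
        return stats
    d = depth.grid_spacing
    ny, nx = depth.shape
    pos = traj.positions
    ix = np.clip((pos[:, :, 0] / d).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, :, 1] / d).astype(int), 0, ny - 1)
    lab = depth.cavity_labels[iy, ix]  # (n, nt)
    for c in range(1, int(depth.cavity_labels.max()) + 1):
        entered = (lab == c) & np.concatenate(
            [np.ones((lab.shape[0], 1), bool), lab[:, :-1] != c], axis=1)
        stats.visit_counts[c] = int(np.count_nonzero(entered))
    inside = lab > 0
    dt_samp = float(np.median(np.diff(traj.t))) if traj.t.size > 1 else 0.0
    runs = []
    for row in inside:
        if not row.any():
            continue
        edges = np.diff(row.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if row[0]:
            starts.insert(0, 0)
        if row[-1]:
            ends.append(row.size)
        runs.extend(e - s for s, e in zip(starts, ends))
    if runs:
        stats.mean_residence_time = float(np.mean(runs) * dt_samp)
    stats.trapped_fraction = float(inside[:, -1].mean())
    return stats
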