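"""Synthetic microscope data with ground truth.

Two generators emulate the study's imaging conditions so that every
downstream analysis stage can be validated against known truth:

* :func:`render_video` draws fluorescent tracer particles from a
  :class:`~trapflow.transport.TrajectorySet` as Gaussian spots into an
  image stack (default 500 frames at 25 Hz, i.e. ~20 s of video), with
  Poisson shot noise and additive Gaussian read noise.

* :func:`generate_biofilm_image` places blurred bacterial colonies on a
  microtrap according to one of the three observed localization regimes -
  colonies along the walls (high inoculum, low flow), in the wall corners
  (low inoculum, low flow), or at the centers of the first three cavities
  (low inoculum, high flow, where single cavity vortices retain cells).

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from trapflow.geometry import ChannelSpec, DepthMap, MicrotrapSpec, \
    build_microtrap

__all__ = ["OpticsSpec", "FrameStack", "RegimeSpec", "render_video",
           "generate_biofilm_image", "make_fixture_bundle"]

#: regime table: (concentration_class, flow_class) -> colony pattern
REGIME_PATTERNS = {
    ("high", "low"): "walls",
    ("low", "low"): "corners",
    ("low", "high"): "cavity_centers",
}


@dataclass(frozen=True)
class OpticsSpec:
    """Idealized epifluorescence optics and camera.

    pixel_size in um/px (0.65 um/px, a typical 10x configuration);
    psf_sigma in px (Gaussian spot model); 8-bit output by default.
    """

    pixel_size: float = 0.65
    psf_sigma: float = 1.2
    frame_rate: float = 25.0
    frame_count: int = 500
    background: float = 10.0
    noise_sigma: float = 2.0
    bit_depth: int = 8
    defocus_scale: float = 0.0  # um of |z| that doubles the PSF area; 0 = off

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def max_value(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass
class FrameStack:
    """Grayscale image sequence with optics metadata.

    ``frames`` is (n_frames, ny, nx) float64 clipped to the camera range;
    ``to_uint`` quantizes for writing.
    """

    frames: np.ndarray
    optics: OpticsSpec
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, ny, nx)")
        if self.timestamps.shape[0] != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_uint(self) -> np.ndarray:
        dtype = np.uint8 if self.optics.bit_depth == 8 else np.uint16
        return np.clip(np.round(self.frames), 0,
                       self.optics.max_value).astype(dtype)

    def save(self, path: str) -> None:
        import tifffile

        tifffile.imwrite(path, self.to_uint())


@dataclass(frozen=True)
class RegimeSpec:
    """Biofilm localization regime (inoculum concentration x flow rate).

    The pattern must be the one observed for the class pair: walls for
    high concentration / low flow, corners for low/low, cavity_centers for
    low/high.
    """

    concentration_class: str = "low"
    flow_class: str = "low"
    pattern: str | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        key = (self.concentration_class, self.flow_class)
        if key not in REGIME_PATTERNS:
            raise ValueError(f"unsupported regime classes {key}")
        expected = REGIME_PATTERNS[key]
        if self.pattern is None:
            object.__setattr__(self, "pattern", expected)
        elif self.pattern != expected:
            raise ValueError(
                f"pattern {self.pattern!r} inconsistent with classes {key} "
                f"(expected {expected!r})")


def _add_gaussian_spots(img: np.ndarray, xs, ys, amps, sigmas) -> None:
    """Accumulate 2-D Gaussian spots in place (truncated at 5 sigma)."""
    ny, nx = img.shape
    for x, y, a, s in zip(xs, ys, amps, sigmas):
        r = max(3, int(np.ceil(5 * s)))
        x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        x0c, x1c = max(x0, 0), min(x1, nx)
        y0c, y1c = max(y0, 0), min(y1, ny)
        if x0c >= x1c or y0c >= y1c:
            continue
        xx = np.arange(x0c, x1c) - x
        yy = np.arange(y0c, y1c) - y
        g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2 * s * s))
        img[y0c:y1c, x0c:x1c] += a * g


def render_video(traj, optics: OpticsSpec,
                 frame_shape: tuple[int, int] | None = None,
                 rng_seed: int = 0, noise: bool = True) -> FrameStack:
    """Render a trajectory set as a fluorescence video.

    Each particle becomes a Gaussian spot at its mapped pixel position
    (physical um / ``pixel_size``); the integrated spot intensity scales
    with diameter cubed (fluorophore volume).  Trajectory samples are
    interpolated at the frame times; frames beyond the trajectory span
    raise.  Per-frame Poisson shot noise and Gaussian read noise are added
    when ``noise`` is true.
    """
    rng = np.random.default_rng(rng_seed)
    nt = optics.frame_count
    times = np.arange(nt) * optics.frame_interval
    if traj is not None and traj.t[-1] < times[-1] - 1e-9:
        raise ValueError("trajectories do not cover the video time span")
    if frame_shape is None:
        if traj is None:
            raise ValueError("frame_shape required for empty videos")
        span = traj.positions[:, :, :2].max(axis=(0, 1))
        frame_shape = (int(np.ceil(span[1] / optics.pixel_size)) + 8,
                       int(np.ceil(span[0] / optics.pixel_size)) + 8)
    frames = np.full((nt,) + tuple(frame_shape), float(optics.background))
    if traj is not None:
        # amplitude: integrated intensity ~ d^3 -> peak = I/(2 pi s^2)
        d3 = traj.spec.diameter ** 3
        for f, t in enumerate(times):
            k = np.searchsorted(traj.t, t, side="right") - 1
            k = min(max(k, 0), traj.t.size - 2) if traj.t.size > 1 else 0
            if traj.t.size > 1:
                w = (t - traj.t[k]) / (traj.t[k + 1] - traj.t[k])
                w = np.clip(w, 0.0, 1.0)
                a = traj.positions[:, k]
                p = a + w * (traj.positions[:, k + 1] - a)
            else:
                p = traj.positions[:, 0]
            sig = np.full(p.shape[0], optics.psf_sigma)
            if optics.defocus_scale > 0:
                sig = sig * np.sqrt(
                    1.0 + (np.abs(p[:, 2]) / optics.defocus_scale) ** 2)
            amp = 40.0 * d3 / (2 * np.pi * sig ** 2)
            vis = ~traj.exited if traj.exited is not None else \
                np.ones(p.shape[0], bool)
            _add_gaussian_spots(frames[f], p[vis, 0] / optics.pixel_size,
                                p[vis, 1] / optics.pixel_size, amp[vis],
                                sig[vis])
    if noise:
        shot = rng.poisson(np.clip(frames, 0, None)) - frames
        read = rng.normal(0.0, optics.noise_sigma, frames.shape)
        frames = frames + shot + read
    np.clip(frames, 0.0, optics.max_value, out=frames)
    return FrameStack(frames=frames, optics=optics, timestamps=times)


# ---------------------------------------------------------------------------
# biofilm image generation


def _colony_sites(regime: RegimeSpec, depth: DepthMap, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Colony center positions (um) for the regime pattern."""
    from scipy import ndimage

    if regime.pattern == "walls":
        band = ndimage.binary_dilation(
            depth.solid_mask,
            iterations=max(1, int(4.0 / depth.grid_spacing)))
        iy, ix = np.nonzero(band)
        pick = rng.choice(iy.size, size=n, replace=True)
        jitter = rng.normal(0, depth.grid_spacing, (n, 2))
        return np.column_stack([depth.x[ix[pick]], depth.y[iy[pick]]]) + \
            jitter
    if regime.pattern == "corners":
        corners = np.asarray(depth.landmarks["corners"], dtype=float)
        pick = rng.integers(0, corners.shape[0], n)
        t = depth.landmarks.get("wall_thickness", 20.0)
        return corners[pick] + rng.normal(0, t / 4.0, (n, 2))
    if regime.pattern == "cavity_centers":
        cents = np.asarray(depth.landmarks["cavity_centroids"], dtype=float)
        k = min(3, cents.shape[0])
        # retention decreases cavity by cavity as the through-flux weakens
        w = np.array([0.45, 0.33, 0.22][:k])
        pick = rng.choice(k, size=n, p=w / w.sum())
        return cents[pick] + rng.normal(0, 6.0, (n, 2))
    raise ValueError(f"unknown pattern {regime.pattern!r}")


def generate_biofilm_image(regime: RegimeSpec, depth: DepthMap,
                           optics: OpticsSpec,
                           n_colonies: int | None = None,
                           ) -> tuple[FrameStack, dict]:
    """Single biofilm fluorescence frame plus ground truth.

    Colonies are isotropic Gaussian blobs (sigma 2-5 um) placed per the
    regime pattern; colony count defaults to 20 for the low concentration
    class and 60 for high.  Returns the one-frame stack and a ground-truth
    dict with colony centers (um), the pattern, and a label map of the
    placement region.

    ``n_colonies=0`` yields a uniform background image.
    """
    if depth.cavity_labels is None:
        raise ValueError("biofilm generation requires a microtrap depth map")
    rng = np.random.default_rng(regime.rng_seed)
    if n_colonies is None:
        n_colonies = 60 if regime.concentration_class == "high" else 20
    ny = int(round(depth.ny * depth.grid_spacing / optics.pixel_size))
    nx = int(round(depth.nx * depth.grid_spacing / optics.pixel_size))
    img = np.full((ny, nx), float(optics.background))
    centers = np.empty((0, 2))
    if n_colonies > 0:
        centers = _colony_sites(regime, depth, n_colonies, rng)
        sig_um = rng.uniform(2.0, 5.0, n_colonies)
        amp = rng.uniform(60.0, 140.0, n_colonies)
        _add_gaussian_spots(img, centers[:, 0] / optics.pixel_size,
                            centers[:, 1] / optics.pixel_size, amp,
                            sig_um / optics.pixel_size)
    img += rng.normal(0.0, optics.noise_sigma, img.shape)
    np.clip(img, 0.0, optics.max_value, out=img)
    stack = FrameStack(frames=img[None], optics=optics,
                       timestamps=np.zeros(1))
    truth = {
        "pattern": regime.pattern,
        "colony_centers_um": centers.tolist(),
        "n_colonies": int(n_colonies),
        "seed": int(regime.rng_seed),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# fixture bundle


def make_fixture_bundle(seed: int, out_dir: str,
                        channel: ChannelSpec | None = None) -> dict:
    """Write a deterministic set of fixtures: microtrap geometry, flow
    fields at both study flow rates, a short tracer video, and one biofilm
    image per regime; a manifest (JSON) lists every file with its SHA-256 hash.

    Returns the manifest dict.
    """
    from trapflow import flowsim, transport

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if channel is None:
        channel = ChannelSpec(analysis_area=(650.0, 350.0), grid_spacing=2.0)
    optics = OpticsSpec(frame_count=50)
    dm = build_microtrap(MicrotrapSpec(), channel)
    dm.save(str(out / "microtrap_depth"))
    files = ["microtrap_depth.tif", "microtrap_depth.json"]
    for rate, tag in [(0.5, "low"), (3.0, "high")]:
        ff = flowsim.solve_depth_averaged(dm, rate, channel=ChannelSpec(
            grid_spacing=channel.grid_spacing,
            analysis_area=channel.analysis_area))
        import tifffile

        tifffile.imwrite(out / f"flow_{tag}.tif",
                         np.stack([ff.u, ff.v]).astype(np.float32),
                         photometric="minisblack")
        files.append(f"flow_{tag}.tif")
        spec = transport.ParticleSpec(diameter=2.0)
        vmax = float(ff.speed().max())
        dt = min(1e-3, 0.5 * ff.grid_spacing / vmax) if vmax > 0 else 1e-3
        traj = transport.advect(ff, spec, n_particles=40,
                                duration=optics.frame_count
                                * optics.frame_interval,
                                dt=dt, rng_seed=seed,
                                record_every=max(1, int(round(
                                    optics.frame_interval / dt))))
        video = render_video(traj, optics, rng_seed=seed + 1,
                             frame_shape=(int(350 / optics.pixel_size),
                                          int(650 / optics.pixel_size)))
        video.save(str(out / f"tracers_{tag}.tif"))
        files.append(f"tracers_{tag}.tif")
    for cc, fc in REGIME_PATTERNS:
        regime = RegimeSpec(cc, fc, rng_seed=seed)
        stack, truth = generate_biofilm_image(regime, dm, optics)
        name = f"biofilm_{regime.pattern}"
        stack.save(str(out / f"{name}.tif"))
        with open(out / f"{name}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        files += [f"{name}.tif", f"{name}_truth.json"]
    manifest = {"seed": int(seed), "files": {}}
    for name in sorted(files):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
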