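"""Velocimetry from image stacks: spot detection, mean-flow-guided PTV
linking, PIV cross-correlation, and flow-homogeneity statistics.

PTV (particle tracking velocimetry) follows individual fluorescent
particles: spots are detected per frame as subpixel intensity-weighted
centroids and linked between consecutive frames inside a search disk
centered on the *expected* displacement (mean flow velocity times the
frame interval), the strategy used for sparse tracer suspensions where
classical PIV seeding would clog the channel.  Ambiguous candidates are
dropped rather than guessed, and per-track velocities are aggregated with
a median, so single mislinks do not bias speeds.

PIV (particle image velocimetry) cross-correlates interrogation windows
between a frame pair in the frequency domain with three-point Gaussian
subpixel refinement, yielding a velocity vector grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from trapflow.synthetic import OpticsSpec

__all__ = ["VectorGrid", "HomogeneityReport", "detect", "detect_stack",
           "link_ptv", "track_velocities", "piv", "homogeneity"]


@dataclass
class VectorGrid:
    """PIV output: vector field at window centers.

    ``x, y`` are window-center pixel coordinates; ``u, v`` velocities in
    um/s; ``quality`` in [0, 1] is the normalized correlation peak.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    quality: np.ndarray
    window: int
    overlap: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_px": self.x.ravel(), "y_px": self.y.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(),
            "quality": self.quality.ravel()})


@dataclass
class HomogeneityReport:
    """Speed and direction statistics over a region of interest."""

    roi: tuple[float, float, float, float]
    n_vectors: int
    mean_speed: float
    speed_cv: float
    direction_dispersion_deg: float


# ---------------------------------------------------------------------------
# detection


def detect(frame: np.ndarray, threshold: float | str = "otsu",
           min_separation: int = 3) -> pd.DataFrame:
    """Detect bright spots in a grayscale frame.

    Local maxima above the threshold (Otsu by default, or an absolute
    value) are refined to subpixel positions by intensity-weighted
    centroiding in a ``(2 min_separation + 1)`` window after local
    background subtraction.  Returns a DataFrame with columns
    ``x, y`` (px) and ``mass`` (integrated above-background intensity);
    empty frames yield an empty DataFrame.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold == "otsu":
        if np.ptp(frame) == 0:
            return pd.DataFrame(columns=["x", "y", "mass"])
        thr = float(threshold_otsu(frame))
    else:
        thr = float(threshold)
    peaks = peak_local_max(frame, min_distance=min_separation,
                           threshold_abs=thr, exclude_border=False)
    if peaks.size == 0:
        return pd.DataFrame(columns=["x", "y", "mass"])
    r = int(min_separation)
    ny, nx = frame.shape
    rows = []
    for py, px in peaks:
        y0, y1 = max(py - r, 0), min(py + r + 1, ny)
        x0, x1 = max(px - r, 0), min(px + r + 1, nx)
        win = frame[y0:y1, x0:x1]
        bg = win.min()
        w = np.clip(win - bg, 0.0, None)
        mass = w.sum()
        if mass <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rows.append(((xx * w).sum() / mass, (yy * w).sum() / mass, mass))
    return pd.DataFrame(rows, columns=["x", "y", "mass"])


def detect_stack(frames: np.ndarray, threshold: float | str = "otsu",
                 min_separation: int = 3) -> pd.DataFrame:
    """Run :func:`detect` on every frame; adds a ``frame`` column."""
    dfs = []
    for i, fr in enumerate(frames):
        df = detect(fr, threshold, min_separation)
        df["frame"] = i
        dfs.append(df)
    return pd.concat(dfs, ignore_index=True)


# ---------------------------------------------------------------------------
# PTV linking


def link_ptv(detections: pd.DataFrame, expected_velocity,
             optics: OpticsSpec, radius_factor: float = 0.6,
             min_radius_px: float = 3.0) -> pd.DataFrame:
    """Link per-frame detections into tracks guided by the mean flow.

    ``expected_velocity`` is the mean flow velocity in um/s (scalar =
    downstream +x, or an (u, v) pair); it sets the predicted per-frame
    pixel shift ``s = v * frame_interval / pixel_size``.  For each
    consecutive frame pair, candidates within a disk of radius
    ``max(radius_factor * |s|, min_radius_px)`` around the predicted
    position are matched by mutual nearest neighbors; equal-distance ties
    are dropped.  Linking runs over all consecutive frame pairs of the
    stack.

    Returns a DataFrame with ``track_id, frame, x, y`` (px) and per-step
    ``u, v`` in um/s (NaN on the last detection of each track).
    """
    if optics is None:
        raise ValueError("optics calibration is required for PTV")
    if "frame" not in detections:
        raise ValueError("detections need a 'frame' column")
    frames = np.sort(detections["frame"].unique())
    if frames.size < 2:
        raise ValueError("PTV needs at least 2 frames")
    vexp = np.atleast_1d(np.asarray(expected_velocity, dtype=float))
    if vexp.size == 1:
        vexp = np.array([vexp[0], 0.0])
    shift_px = vexp * optics.frame_interval / optics.pixel_size
    radius = max(radius_factor * float(np.hypot(*shift_px)), min_radius_px)

    per_frame = {f: detections[detections["frame"] == f][["x", "y"]]
                 .to_numpy() for f in frames}
    # active track id per detection index of current frame
    track_of = {i: i for i in range(per_frame[frames[0]].shape[0])}
    next_id = per_frame[frames[0]].shape[0]
    records = []
    for i, (x, y) in enumerate(per_frame[frames[0]]):
        records.append((track_of[i], frames[0], x, y))
    for fa, fb in zip(frames[:-1], frames[1:]):
        A = per_frame[fa]
        B = per_frame[fb]
        new_track_of = {}
        if A.shape[0] and B.shape[0]:
            pred = A + shift_px[None, :]
            d2 = ((pred[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
            d2[d2 > radius ** 2] = np.inf
            fwd = np.argmin(d2, axis=1)
            bwd = np.argmin(d2, axis=0)
            for ia in range(A.shape[0]):
                ib = fwd[ia]
                if not np.isfinite(d2[ia, ib]):
                    continue
                if bwd[ib] != ia:
                    continue  # not mutual
                # drop equal-distance ties (ambiguous assignment)
                row = d2[ia]
                if np.count_nonzero(np.isclose(row, row[ib])) > 1:
                    continue
                col = d2[:, ib]
                if np.count_nonzero(np.isclose(col, col[ia])) > 1:
                    continue
                new_track_of[ib] = track_of.get(ia, None)
        for ib, (x, y) in enumerate(B):
            tid = new_track_of.get(ib)
            if tid is None:
                tid = next_id
                next_id += 1
                new_track_of[ib] = tid
            records.append((tid, fb, x, y))
        track_of = new_track_of
    df = pd.DataFrame(records, columns=["track_id", "frame", "x", "y"])
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    scale = optics.pixel_size * optics.frame_rate  # px/frame -> um/s
    g = df.groupby("track_id")
    df["u"] = g["x"].diff().shift(-1) * scale
    df["v"] = g["y"].diff().shift(-1) * scale
    return df


def track_velocities(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track median velocity (robust to single mislinks): columns
    ``track_id, u, v, speed, n_steps``."""
    g = tracks.dropna(subset=["u"]).groupby("track_id")
    out = g[["u", "v"]].median()
    out["speed"] = np.hypot(out["u"], out["v"])
    out["n_steps"] = g.size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# PIV


def _gauss_subpel(cm: float, cc: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation; 0 for degenerate stencils."""
    cm, cc, cp = max(cm, 1e-12), max(cc, 1e-12), max(cp, 1e-12)
    lm, lc, lp = np.log(cm), np.log(cc), np.log(cp)
    denom = lm - 2.0 * lc + lp
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    return float(0.5 * (lm - lp) / denom)


def piv(frame_a: np.ndarray, frame_b: np.ndarray, window: int = 32,
        overlap: float = 0.5, optics: OpticsSpec | None = None) -> VectorGrid:
    """Window cross-correlation velocimetry between two frames.

    Each ``window x window`` interrogation window of frame_a (spaced by
    ``window * (1 - overlap)``) is mean-subtracted and linearly
    cross-correlated (FFT) against a search region of frame_b extending
    ``window // 2`` beyond the window on each side; the correlation peak
    gives the integer displacement of frame_b relative to frame_a, refined
    along each axis by three-point Gaussian interpolation.  Displacements
    are converted to um/s with the optics calibration (px/frame if
    ``optics`` is None).
    """
    from skimage.feature import match_template

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if window > min(a.shape):
        raise ValueError("window larger than the frame")
    step = max(1, int(round(window * (1.0 - overlap))))
    ys = np.arange(0, a.shape[0] - window + 1, step)
    xs = np.arange(0, a.shape[1] - window + 1, step)
    U = np.zeros((ys.size, xs.size))
    V = np.zeros_like(U)
    Qual = np.zeros_like(U)
    Xc = np.zeros_like(U)
    Yc = np.zeros_like(U)
    n = window
    m = window // 2  # search margin: max resolvable displacement
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            wa = a[y0:y0 + n, x0:x0 + n]
            ry0 = max(y0 - m, 0)
            rx0 = max(x0 - m, 0)
            region = b[ry0:min(y0 + n + m, b.shape[0]),
                       rx0:min(x0 + n + m, b.shape[1])]
            if np.ptp(wa) == 0 or np.ptp(region) == 0:
                Xc[j, i] = x0 + n / 2.0
                Yc[j, i] = y0 + n / 2.0
                continue
            # normalized cross-correlation surface over integer offsets
            ncc = match_template(region, wa, pad_input=False)
            py, px = np.unravel_index(np.argmax(ncc), ncc.shape)
            dy = float(py - (y0 - ry0))
            dx = float(px - (x0 - rx0))
            c0 = float(ncc[py, px])
            Qual[j, i] = float(np.clip(c0, 0.0, 1.0))
            # a perfect lattice match is already exact; otherwise refine
            # each axis on the NCC stencil (log-quadratic for Gaussian
            # particle images)
            if c0 < 1.0 - 1e-9:
                if 0 < px < ncc.shape[1] - 1:
                    dx += _gauss_subpel(ncc[py, px - 1], c0,
                                        ncc[py, px + 1])
                if 0 < py < ncc.shape[0] - 1:
                    dy += _gauss_subpel(ncc[py - 1, px], c0,
                                        ncc[py + 1, px])
            U[j, i] = dx
            V[j, i] = dy
            Xc[j, i] = x0 + n / 2.0
            Yc[j, i] = y0 + n / 2.0
    if optics is not None:
        scale = optics.pixel_size * optics.frame_rate
        U = U * scale
        V = V * scale
    return VectorGrid(x=Xc, y=Yc, u=U, v=V, quality=Qual, window=window,
                      overlap=overlap)


# ---------------------------------------------------------------------------
# homogeneity


def homogeneity(vectors, roi: tuple[float, float, float, float],
                min_vectors: int = 10,
                coords_in: str = "px") -> HomogeneityReport:
    """Speed CV and circular SD of direction over an ROI.

    ``vectors`` is a :class:`VectorGrid` or a per-track velocity DataFrame
    (columns ``u, v`` and positions ``x, y``); ``roi`` is (x0, y0, x1, y1)
    in the same coordinates as the positions.
    """
    from scipy.stats import circstd

    if isinstance(vectors, VectorGrid):
        x = vectors.x.ravel()
        y = vectors.y.ravel()
        u = vectors.u.ravel()
        v = vectors.v.ravel()
    else:
        df = vectors.dropna(subset=["u", "v"])
        x = df["x"].to_numpy()
        y = df["y"].to_numpy()
        u = df["u"].to_numpy()
        v = df["v"].to_numpy()
    x0, y0, x1, y1 = roi
    m = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if m.sum() < min_vectors:
        raise ValueError(
            f"only {int(m.sum())} vectors in ROI (need >= {min_vectors})")
    sp = np.hypot(u[m], v[m])
    ang = np.arctan2(v[m], u[m])
    mean_speed = float(sp.mean())
    cv = float(sp.std() / mean_speed) if mean_speed > 0 else 0.0
    disp = float(np.degrees(circstd(ang)))
    return HomogeneityReport(roi=roi, n_vectors=int(m.sum()),
                             mean_speed=mean_speed, speed_cv=cv,
                             direction_dispersion_deg=disp)
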