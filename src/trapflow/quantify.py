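"""Biofilm image quantification over microtrap geometry.

Mirrors the experimental analysis chain: replicate trap images are
registered by translation against the known trap footprint and averaged;
the averaged image is reduced to a fluorescence intensity profile versus
downstream distance (default window 650 um spanning the 410 um trap plus
margins); above-background intensity is partitioned into wall, corner and
cavity regions; and a rule-based classifier maps the occupancy report to
one of the three biofilm localization regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from trapflow.geometry import DepthMap

__all__ = ["IntensityProfile", "OccupancyReport", "footprint_template",
           "register_and_average", "intensity_profile", "occupancy",
           "classify_regime", "region_masks"]


@dataclass
class IntensityProfile:
    """Mean intensity versus downstream distance.

    ``x`` is in um, anchored at the start of the analysis window (the
    window defaults to starting 120 um upstream of the trap leading edge);
    ``intensity`` is the column-wise mean over the trap's transverse
    extent; ``n_images`` is how many images entered the average upstream.
    """

    x: np.ndarray
    intensity: np.ndarray
    n_images: int = 1


@dataclass
class OccupancyReport:
    """Partition of above-background fluorescence by trap region.

    Fractions are of total above-background intensity in the image;
    wall/corner/cavity are mutually related as: corner is a sub-region of
    the wall band; ``wall_fraction`` excludes the corner disks so that
    wall + corner + cavity + outside = 1.
    """

    wall_fraction: float
    corner_fraction: float
    cavity_fraction: float
    per_cavity_mean: np.ndarray
    background: float
    total_above_background: float

    @property
    def wall_band_fraction(self) -> float:
        """Wall band including corners."""
        return self.wall_fraction + self.corner_fraction

    @property
    def corner_share_of_wall(self) -> float:
        band = self.wall_band_fraction
        return self.corner_fraction / band if band > 0 else 0.0


# ---------------------------------------------------------------------------
# masks and templates


def _px_grid(depth: DepthMap, pixel_size: float) -> tuple[int, int]:
    ny = int(round(depth.ny * depth.grid_spacing / pixel_size))
    nx = int(round(depth.nx * depth.grid_spacing / pixel_size))
    return ny, nx


def _resample_mask(mask: np.ndarray, depth: DepthMap,
                   pixel_size: float) -> np.ndarray:
    """Nearest-neighbor resample of a depth-map raster onto image pixels."""
    ny, nx = _px_grid(depth, pixel_size)
    yy = np.clip(((np.arange(ny) + 0.5) * pixel_size
                  / depth.grid_spacing).astype(int), 0, depth.ny - 1)
    xx = np.clip(((np.arange(nx) + 0.5) * pixel_size
                  / depth.grid_spacing).astype(int), 0, depth.nx - 1)
    return mask[np.ix_(yy, xx)]


def footprint_template(depth: DepthMap, pixel_size: float) -> np.ndarray:
    """Binary image of the feature footprint at the camera pixel size,
    used as the registration reference."""
    return _resample_mask(depth.solid_mask, depth, pixel_size).astype(float)


def region_masks(depth: DepthMap, pixel_size: float) -> dict:
    """Wall / corner / cavity pixel masks for occupancy partitioning.

    wall band = footprint dilated by half a wall thickness (the cavities
    are only a few wall thicknesses across, so a full-thickness dilation
    would swallow them); corner = disks of radius one wall thickness at
    the concave wall junctions, intersected with the wall band; cavity =
    labeled cavity cells minus the wall band.
    """
    t = float(depth.landmarks.get("wall_thickness", 20.0))
    it = max(1, int(round(0.5 * t / depth.grid_spacing)))
    band = ndimage.binary_dilation(depth.solid_mask, iterations=it)
    band_px = _resample_mask(band, depth, pixel_size)
    labels_px = _resample_mask(depth.cavity_labels, depth, pixel_size) \
        if depth.cavity_labels is not None else np.zeros_like(band_px, int)
    ny, nx = band_px.shape
    corner = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cx, cy in depth.landmarks.get("corners", []):
        r2 = ((xx + 0.5) * pixel_size - cx) ** 2 \
            + ((yy + 0.5) * pixel_size - cy) ** 2
        corner |= r2 <= t * t
    corner &= band_px
    cavity = (labels_px > 0) & ~band_px
    wall = band_px & ~corner
    return {"wall": wall, "corner": corner, "cavity": cavity,
            "cavity_labels": np.where(band_px, 0, labels_px),
            "band": band_px}


# ---------------------------------------------------------------------------
# registration and averaging


def register_and_average(images, depth: DepthMap, pixel_size: float,
                         confidence_threshold: float = 0.1,
                         ) -> tuple[np.ndarray, dict]:
    """Align replicate trap images to the footprint and average them.

    Each image is registered by translation-only phase correlation against
    the rendered trap footprint (features are axis-aligned with the flow,
    so rotation is assumed pre-corrected); the template supplies the
    correspondence, and the stack is brought into the frame of the first
    accepted image (identical inputs therefore average to themselves),
    then averaged pixelwise.  Images whose normalized cross-correlation
    with the template after alignment falls below
    ``confidence_threshold`` are excluded (listed in the info dict); if
    all are excluded an error is raised.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) < 1:
        raise ValueError("at least one image is required")
    tmpl = footprint_template(depth, pixel_size)
    tmpl_z = tmpl - tmpl.mean()
    raw = []
    for k, im in enumerate(images):
        if im.shape != tmpl.shape:
            raise ValueError("image shape does not match the reference")
        shift, _, _ = phase_cross_correlation(tmpl, im, upsample_factor=10,
                                              normalization=None)
        moved = ndimage.shift(im, shift, order=1, mode="nearest")
        mz = moved - moved.mean()
        denom = np.linalg.norm(tmpl_z) * np.linalg.norm(mz)
        conf = float((tmpl_z * mz).sum() / denom) if denom > 0 else 0.0
        raw.append((k, np.asarray(shift, dtype=float), conf))
    accepted = [r for r in raw if r[2] >= confidence_threshold]
    excluded = [k for k, _, c in raw if c < confidence_threshold]
    if not accepted:
        raise ValueError("all images fell below the alignment confidence")
    ref_shift = accepted[0][1]
    aligned, shifts = [], []
    for k, shift, _ in accepted:
        rel = shift - ref_shift
        moved = images[k] if np.allclose(rel, 0.0) else \
            ndimage.shift(images[k], rel, order=1, mode="nearest")
        aligned.append(moved)
        shifts.append(tuple(float(s) for s in rel))
    avg = np.mean(aligned, axis=0)
    return avg, {"shifts": shifts, "excluded": excluded,
                 "n_used": len(aligned)}


# ---------------------------------------------------------------------------
# profiles and occupancy


def intensity_profile(image: np.ndarray, depth: DepthMap, pixel_size: float,
                      window: tuple[float, float] | None = None,
                      y_extent: tuple[float, float] | None = None,
                      n_images: int = 1) -> IntensityProfile:
    """Column-wise mean intensity versus downstream distance.

    ``window`` is (x0, x1) in um in depth-map coordinates; the default
    spans 650 um anchored 120 um upstream of the trap leading edge.
    ``y_extent`` defaults to the trap's transverse extent.  The returned
    ``x`` is relative to the window start.
    """
    image = np.asarray(image, dtype=float)
    bbox = depth.landmarks.get("trap_bbox")
    if window is None:
        if bbox is None:
            raise ValueError("window required for featureless geometry")
        window = (bbox[0] - 120.0, bbox[0] + 530.0)
    if y_extent is None:
        y_extent = (bbox[1], bbox[3]) if bbox is not None \
            else (0.0, image.shape[0] * pixel_size)
    x0, x1 = window
    ix0, ix1 = int(round(x0 / pixel_size)), int(round(x1 / pixel_size))
    iy0, iy1 = int(round(y_extent[0] / pixel_size)), \
        int(round(y_extent[1] / pixel_size))
    if ix0 < 0 or ix1 > image.shape[1] or iy0 < 0 or iy1 > image.shape[0] \
            or ix1 <= ix0:
        raise ValueError("profile window outside the image")
    sub = image[iy0:iy1, ix0:ix1]
    x = (np.arange(sub.shape[1]) + 0.5) * pixel_size
    return IntensityProfile(x=x, intensity=sub.mean(axis=0),
                            n_images=n_images)


def occupancy(image: np.ndarray, depth: DepthMap, pixel_size: float,
              saturation_level: float = 255.0) -> OccupancyReport:
    """Partition above-background intensity into wall / corner / cavity.

    Background is the median of pixels outside the trap bounding box
    (robust to colonies on the outer trap walls); intensity above it is
    summed per region mask.  A saturated (degenerate-background) image
    raises.
    """
    image = np.asarray(image, dtype=float)
    masks = region_masks(depth, pixel_size)
    ny, nx = image.shape
    bbox = depth.landmarks.get("trap_bbox")
    if bbox is None:
        raise ValueError("occupancy requires a trap geometry")
    xx = (np.arange(nx) + 0.5) * pixel_size
    yy = (np.arange(ny) + 0.5) * pixel_size
    in_bbox = ((xx[None, :] >= bbox[0]) & (xx[None, :] <= bbox[2])
               & (yy[:, None] >= bbox[1]) & (yy[:, None] <= bbox[3]))
    outside = ~in_bbox
    bg = float(np.median(image[outside]))
    if np.ptp(image) == 0:
        if bg >= saturation_level:
            raise ValueError("degenerate background (saturated image)")
        # featureless frame: nothing above background
        return OccupancyReport(0.0, 0.0, 0.0,
                               np.zeros(int(masks["cavity_labels"].max())),
                               bg, 0.0)
    if bg >= image.max():
        raise ValueError("degenerate background (saturated image)")
    above = np.clip(image - bg, 0.0, None)
    total = float(above.sum())
    if total == 0:
        return OccupancyReport(0.0, 0.0, 0.0,
                               np.zeros(int(masks["cavity_labels"].max())),
                               bg, 0.0)
    wall = float(above[masks["wall"]].sum()) / total
    corner = float(above[masks["corner"]].sum()) / total
    cavity = float(above[masks["cavity"]].sum()) / total
    labels = masks["cavity_labels"]
    ncav = int(labels.max())
    per_cav = np.array([float(above[labels == c].mean())
                        if np.any(labels == c) else 0.0
                        for c in range(1, ncav + 1)])
    return OccupancyReport(wall_fraction=wall, corner_fraction=corner,
                           cavity_fraction=cavity, per_cavity_mean=per_cav,
                           background=bg, total_above_background=total)


def classify_regime(report: OccupancyReport,
                    corner_share_threshold: float = 0.5) -> str:
    """Map an occupancy report to a biofilm localization regime.

    Rule: if the cavity fraction exceeds the wall band (walls + corners),
    the regime is ``cavity_centers``; otherwise the wall band dominates and
    the corner share of the band decides between ``corners`` and
    ``walls``.  An all-zero report returns ``indeterminate``.
    """
    band = report.wall_band_fraction
    if report.total_above_background == 0 or \
            (band == 0 and report.cavity_fraction == 0):
        return "indeterminate"
    if np.isclose(report.cavity_fraction, band):
        return "indeterminate"
    if report.cavity_fraction > band:
        return "cavity_centers"
    if report.corner_share_of_wall >= corner_share_threshold:
        return "corners"
    return "walls"
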