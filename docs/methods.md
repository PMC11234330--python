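# Methods

This note records the models behind `trapflow`, the defaults that
matter, and what the synthetic-data pipeline does and does not show.

## Geometry

All lengths are in micrometres, times in seconds; `x` increases
downstream, `y` across the channel, `z` up from the floor. Rasters are
row-major `[iy, ix]` with physical y increasing with the row index
(matplotlib's default `origin='upper'` therefore displays the channel
mirrored; no computation depends on the display convention).

The channel is a 5 mm-wide, 15 um-high slot; solvers operate on a
rectangular analysis window of it. Features are drawn as thick-segment
("capsule") unions: two side rails plus six chevron walls for the
microtrap, and chevron arrays for the arrow feature. Features are 10 um
high, so the local clearance is 5 um over walls and 15 um elsewhere —
depth maps never contain fully blocked cells.

Unprinted internals of the microtrap were fixed as follows and exposed
as parameters: funnel half-angle 45 degrees; funnel gap width 2 um. The
gap default follows the single-cell funnel-trap concept the feature is
modeled on (constrictions about one bacterium wide). This choice is
load-bearing: gaps of tens of microns would conduct strongly, the
funnels would jet rather than trap, and in-trap velocities would exceed
the observed 0-10 um/s scale by two orders of magnitude. A 2 um gap is
hydraulically negligible and rasterizes sealed at all supported grid
spacings; cavity labeling additionally seals the declared gap rectangles
before counting enclosed regions, so the five-cavity topology is stable
across grids.

Cavity "centers" (used for colony placement and reported as landmarks)
are the open cells farthest from any wall within each labeled cavity —
the raw centroid of a chevron-shaped cavity can fall on a wall.

## Flow models

Three solvers cover the regime Re << 1; all are deterministic sparse
direct solves (no iteration tolerance or initialization to document).

**Plan view (Hele-Shaw).** `div(T grad p) = 0` with transmissibility
`T = h^3 / 12 mu`, harmonic-mean face coefficients, uniform inlet flux
(flow rate spread over the full 5 mm channel width), zero-pressure
outlet, no-flux side walls. Velocities are `-(h^2/12 mu) grad p`. Face
fluxes are retained, so the depth-flux divergence and cross-section flux
invariants are audited exactly. Where h is uniform this model is a
potential flow: it cannot form closed in-plane eddies, and its vorticity
is concentrated in the one-or-two-cell bands where h jumps at feature
edges (and is therefore mesh-sensitive there).

**Vertical slice.** Incompressible 2-D Stokes in an x-z plane over a
clearance profile, on a MAC grid with staircase no-slip at features, a
parabolic inlet/outlet profile, and a tiny uniform pressure
regularization (1e-9/mu) fixing the gauge. It reproduces the
plane-Poiseuille max/mean ratio of 1.5 and resolves closed recirculation
in sufficiently deep slots, but it forces the whole flux over the
features (no lateral diversion).

**Coarse 3-D Stokes.** The quantitative vortex model. MAC grid, default
10 um in-plane and 1.5 um vertical spacing over an 800 x 400 um domain
with the trap centered; symmetry side planes (the device carries a
transverse array of traps), parabolic inlet/outlet at the channel mean
velocity, staircase no-slip on floor, ceiling and features. The direct
factorization keeps the solve around a minute on one CPU at this
resolution; wall thickness spans two cells, the cavity depth about
seven layers.

## Vortex metrics

Vorticity and Q-criterion follow the standard definitions; the 2-D
analytic cases (rigid rotation `Q = omega^2`, simple shear `Q = 0`,
pure strain `Q = -gamma^2`) are tested to discretization accuracy.

The *cavity microvortex metrics* reported by `stokes3d.vortex_metrics`
(and by `scripts/acceptance.py`) are the maxima over the labeled cavity
cells of the in-plane vorticity `omega_z` and the in-plane (2-D)
Q-criterion, evaluated at the lowest cell layer of the 3-D solution —
cell centers 0.75 um above the floor at the default vertical spacing,
about the center height of a surface-associated bacterium. Rationale:
the biologically meaningful swirls are the in-plane ones in the stratum
where trapped cells reside; higher strata are dominated by the
through-flow diving over the walls, and vorticity magnitudes there are
dominated by vertical wall shear (hundreds of 1/s), which is a property
of the carrying channel, not of the trap vortices. This adhesion-plane
stratum also reproduces the observed in-trap velocity scale
(<= ~12 um/s at 0.5 uL/min). Because Stokes flow is linear in the flow
rate, vorticity scales exactly 6-fold and Q 36-fold between the two
study flow rates. Refining the grid or widening the domain shifts the
vorticity maximum by a few tens of percent; the Q maximum is more
grid-sensitive. Both metrics are therefore defined at the declared
default resolution.

## Particle transport

Euler-Maruyama with per-axis noise `sqrt(2 D dt)`; D from
Stokes-Einstein at the fluid temperature (25 C default) unless
overridden; z settles at the Stokes velocity (1.3 g/mL spheres in
water). Composition is 2.5-D: in-plane motion follows the depth-averaged
field; vertical advection is not fed back. Walls: specular reflection at
domain sides and upstream edge; in-plane moves into cells with clearance
below the particle diameter are rejected (a first-order stand-in for
specular collision with feature walls); z is clipped to
`[r, h - r]`; the downstream edge absorbs. The step guard
`dt <= grid_spacing / max speed` rejects unstable settings; `dt`
defaults to 1 ms. Trajectories are bit-reproducible given the seed.

## Synthetic microscopy

Optics defaults: 0.65 um/px (a typical 10x epifluorescence
configuration), Gaussian PSF of sigma 1.2 px, 25 Hz, 500 frames
(~20 s), 8-bit range, background 10 counts, Poisson shot noise plus
2-count Gaussian read noise. Spot amplitude scales with particle
diameter cubed; optional defocus widens the PSF with |z|. Biofilm
images place Gaussian colonies (sigma 2-5 um) per regime: along walls
(60 colonies, high-inoculum default), at concave wall junctions
(20 colonies), or at the centers of the first three cavities with
weights 0.45/0.33/0.22 — the downstream decay mirrors the weakening
of the cavity vortices along the trap. Generators are pure functions of
(inputs, seed); fixture bundles are hashed and byte-reproducible.

What the generator does *not* emulate: photobleaching, drift, uneven
illumination, non-Gaussian PSFs, colony morphology (streamers, comets,
merging), motility, or growth dynamics. Passing the recovery tests
therefore validates the *analysis chain* (detection, linking,
correlation, registration, occupancy partitioning) against known truth,
not the biology of real micrographs.

## Velocimetry

Detection: local maxima above a threshold (Otsu default, absolute
override), intensity-weighted centroid in a `2*min_separation + 1`
window after local background subtraction; min separation 3 px.

PTV: predicted shift = expected velocity x frame interval / pixel size;
search radius `max(0.6 x |shift|, 3 px)`; mutual-nearest-neighbor
matching with equal-distance ties dropped rather than guessed; linking
over all consecutive frame pairs (multi-lag linking is out of scope);
per-track velocity is the median over steps, robust to single mislinks.

PIV: each window is matched against a search region extending
window/2 beyond it using the normalized cross-correlation surface
(`skimage.feature.match_template`); a perfect lattice match (NCC within
1e-9 of 1) is taken as exact, otherwise each axis is refined with
three-point Gaussian interpolation, which is exact for Gaussian
particle images. Quality is the NCC peak in [0, 1]. The resolvable
displacement is limited to half a window.

## Biofilm quantification

Registration is translation-only (features are axis-aligned with the
flow) by phase correlation against the rendered footprint; the stack is
brought into the frame of the first accepted image, so identical inputs
average to themselves; images below 0.1 normalized correlation with the
template are excluded. The 650 um intensity-profile window is anchored
120 um upstream of the trap leading edge so the 410 um trap sits
centrally; the transverse extent defaults to the trap width.

Occupancy masks: wall band = footprint dilated by *half* a wall
thickness — the cavities are only a few wall thicknesses across, so a
full-thickness dilation would swallow them entirely; corner disks of
radius one wall thickness at the twelve concave arm-rail junctions,
intersected with the band; cavity = labeled cells minus the band.
Background is the median outside the trap bounding box (robust to
colonies on the outer walls). The classifier compares the cavity
fraction with the wall band and, within the band, uses the corner share
(threshold 0.5) to separate corner from wall regimes; exact ties and
empty reports return "indeterminate".

## Problem sizes and determinism

Defaults used in tests and the acceptance script: 650 x 350 um analysis
window at 2 um for plan-view work, 800 x 400 um at 10 um (dz 1.5 um)
for the 3-D vortex analysis, 500-frame 256 x 512 px videos for
velocimetry recovery, 30 synthetic biofilm images (3 regimes x 10
seeds) for regime recovery. All stochastic stages take explicit seeds;
all solvers are seed-free direct methods.

## Known limitations

* The Hele-Shaw edge vorticity is mesh-dependent by construction; use
  the 3-D solve for vortex quantities.
* The 3-D solve is deliberately coarse; absolute vortex maxima carry a
  resolution uncertainty of order a factor of 1.5, and the staircase
  walls underestimate boundary-layer gradients.
* 2.5-D transport ignores vertical advection; apparent in-plane
  slowdowns over the trap partly reflect unmodeled z-motion, and 3-D
  tracking is out of scope.
* The regime classifier is tuned to the generator's colony statistics;
  applying it to real images will require re-examining the wall-band
  width and corner-share threshold.
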