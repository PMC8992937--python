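# Methods

This note records the models, numerical choices and known limitations of
`spect-iq`, in the spirit of the methods documentation of established
simulation/reconstruction packages.

## Digital phantom

The NEMA IEC body phantom is modelled as a stadium-shaped torso
cross-section (a 70 × 230 mm rectangle capped by two 115 mm-radius half
discs, 300 × 230 mm overall) extruded over 180 mm, holding six spheres of
internal diameter 37, 28, 22, 17, 13 and 10 mm. The sphere centres sit on
a 114.4 mm-diameter ring at 60° spacing in one transaxial plane — the
standard arrangement — with the largest sphere at 0°; centres and outline
are configurable. The optional cold lung insert (25 mm radius,
μ = 0.04 cm⁻¹) is off by default.

Fill arithmetic mirrors the physical preparation: a stock of
`total_activity / stock_volume` (default 214.2 MBq / 1200 ml →
178.5 kBq/ml) fills the spheres; the residual activity is diluted into the
background compartment, whose 9787 ml is interpreted as the **final**
background volume — the only reading consistent with the resulting
21 kBq/ml and 8.5:1 ratio. The ratio therefore depends only on volumes,
not on total activity.

Voxelization is volume-fraction weighted: sphere and outline boundary
voxels carry the sub-voxel fraction of each compartment, sampled on a
`supersampling`× finer lattice (default 4×; the extruded outline
factorises exactly into an in-plane fraction times an axial overlap). The
attenuation map is μ_water = 0.154 cm⁻¹ (140 keV) times the body
fraction. The grid origin is placed on a voxel centre (index `n//2` per
axis) so the sphere equator coincides with an image slice; with a
symmetric even-grid convention every slice would miss the equator by half
a voxel, biasing the hot-sphere ROI mean for no physical reason.
`supersampling=1` produces a *sharp* binary phantom in which sphere
voxelization and the equatorial ROI membership rule coincide exactly —
the convergence-to-truth tests use it, because only there is "ground
truth RC = 100 %" actually true at 4.8 mm voxels (partial-volume
boundary voxels alone cost ~4 RC points on the supersampled phantom).

## Acquisition model

Dual-head step-and-shoot, 60 views per head, 120 projections evenly
spaced over 360° (3° steps), 4.8 mm detector pixels matching the voxel
grid, circular orbit of radius 250 mm (the patient-contoured orbit of a
clinical scan is not reproducible without contour data). The
collimator-detector response is a distance-dependent 2D Gaussian with
FWHM(d) = 4 mm + 0.05 · d — a generic low-energy high-resolution
parameterization giving ~16 mm FWHM at the orbit centre before
reconstruction. Scatter is not simulated, and consequently no scatter
correction exists anywhere in the chain; the simulation-reconstruction
pair stays internally consistent ("matched model").

The projector is rotation-based: for each view the volume is rotated
in-plane by a precomputed bilinear-interpolation sparse operator, each
constant-distance plane is blurred with its distance's Gaussian (planes
are grouped where σ agrees within 0.25 px), multiplied by the cumulative
attenuation factor exp(−∫μ dl) toward the detector (half-voxel
self-attenuation at the emission plane), and summed along rays. Because
the blur kernel is symmetric with zero padding, the attenuation factors
diagonal, and the rotation a stored sparse matrix, the backprojector is
the **exact adjoint** (verified to ~1e-10 relative in tests), which gives
MLEM its textbook monotonicity and count-conservation properties.

Counts: absolute count levels have no first-principles anchor in a desk
simulation, so sensitivity is calibrated such that the full 15 s
acquisition totals 10⁶ counts by default (`--total-counts`). This
reproduces the background-noise magnitude of a clinical-activity phantom
scan (BV ≈ 8–12 % at 15 s/view, 12 it, 8 mm filter) and is treated as a
fixed study condition, not a tuning knob.

Gating: each view is split into `n_gate_bins` = 15 equal bins; bin *b* is
an independent Poisson draw with mean = rate × (time_per_view / 15) from
its own `SeedSequence(seed, spawn_key=(b,))` substream, so bin counts are
reproducible and adding bins never perturbs existing ones. Partial sums
of one acquisition (bins 1–3, 1–8, 1–15 → 3, 8, 15 s) emulate shorter
scans exactly as a gated phantom experiment does — the three durations
are nested subsets of a single scan, not independent scans, and per-seed
replication re-simulates the gated stack, which is why the sweep takes
the noise-free projections rather than a realized stack as input.

## Reconstruction

Classic OSEM: x ← x · backprojectₛ(y_s / forwardₛ(x)) / backprojectₛ(1),
views assigned to 8 subsets by stride (view *i* → subset *i* mod 8) for
maximal angular spread; an "iteration" is a full pass over all subsets
(the study grid 4–24 iterations × 8 subsets spans 32–192 updates).
The initial estimate is a uniform 1.0 inside the inscribed transaxial
cylinder; the multiplicative update fixes the global scale after the
first subset, so the initial level is immaterial. Ratios where the
forward projection falls below 1e-12 of its mean are set to 0 (not 1);
sensitivity-image divisions are guarded at 1e-8 of the maximum.
Attenuation correction uses the true simulated μ map (perfect
registration). The post-filter is an isotropic 3D Gaussian with
σ = FWHM / (2√(2 ln 2)); the truncated kernel is renormalized by the
filtered indicator so a uniform volume is exactly preserved and interior
sums are unchanged. Within the sweep, higher iteration counts reuse the
running OSEM state (snapshots of one pass), valid because iterations
compose.

## ROI layout and metrics

The central slice passes through the sphere centres; four more analysis
slices sit at ±1 and ±2 slices (±4.8 / ±9.6 mm — with 4.8 mm slices the
±2 slice approximates the standard ±1 cm). Sphere ROIs are circles of
the sphere's internal diameter on the central slice. Twelve 37 mm
background positions are found by a deterministic, seed-free greedy scan
of a polar candidate grid (outer radii first, 5 mm arc steps, half-voxel
radial steps), subject to: ≥ 15 mm edge distance to the phantom margin,
≥ 15 mm edge distance to every sphere, and ≥ 37 mm centre separation so
background ROIs do not overlap. Concentric smaller ROIs share the 37 mm
centres; 12 positions × 5 slices = 60 background ROIs per diameter.

Pixel membership defaults to the centre rule (a pixel belongs to the ROI
if its centre lies in the circle); fractional-area weighting is available
(`roi_weighting="area"`). C_H,s uses the central slice only; C_B,s and
SDₛ pool all 60 ROIs. SD_ROI in the CNR is ambiguous in common usage;
the default equates it to SDₛ (the between-ROI SD is the only noise
statistic the metric suite defines), with `sd_roi_mode="within"`
switching to the mean within-ROI pixel SD; the choice is recorded in
each result's provenance. On a noiseless degenerate image SD_ROI = 0 and
the CNR is reported as NaN (uniform) or ±∞ rather than raising, so RC
and BV remain available.

Convergence is detected on the sampled iteration grid: the smallest grid
iteration after which every successive relative RC change stays below
the threshold (default 3.5 %); the last grid point alone never
qualifies. Both the ~8-iteration onset and the 12-iteration stability
plateau are visible in the simulated curves depending on duration and
sphere; the threshold is configurable rather than canonical.

## Scaled-down study conditions

Tests and the acceptance script run a reduced version of the full study:
64 × 64 × 40 voxels at 4.8 mm (the 300 mm outline needs the full 64-pixel
transaxial extent; 40 slices cover the 180 mm phantom), 120 views, 10⁶
total counts at 15 s, iteration snapshots {4, 12, 24} (tests) or the full
{4…24} grid (acceptance script), filters {0, 8} mm, ten seeds. At this
count level single-seed small-sphere statistics are noisy — the
reconstructed hot-sphere ROI mean has a seed-to-seed SD of 5–12 RC points
for the 13–22 mm spheres because Poisson noise is signal-dependent — so
qualitative trends (RC and CNR monotone in sphere size, BV ordering
3 s > 8 s > 15 s, BV rising with iterations and falling with filter
width, the unfiltered-contrast gain largest for the smallest sphere, and
visibility duration ordered by sphere size) are asserted on the mean over
the ten seeds; single-realization orderings of adjacent small spheres are
not stable properties at this noise level and are not claimed.

## What the generator does and does not emulate

Emulated: partial-volume contrast loss, distance-dependent resolution,
attenuation, Poisson count statistics and their scaling with acquisition
time, gated-bin nesting of durations, iteration/filter trade-offs.
Not emulated: scatter and its correction, septal penetration, detector
energy resolution and dead time, the non-circular orbit, CT acquisition
(the attenuation map is analytic), vendor-specific OSEM internals, and
inter-scan repositioning. Passing trend tests therefore demonstrates the
behaviour of an idealized, matched-model chain; absolute RC/BV/CNR
levels from physical scanners — where residual scatter and model mismatch
depress large-sphere contrast — are not comparable (our large-sphere RC
is ~20 points higher than scanner-derived values at the same nominal
conditions, while small-sphere RC agrees closely).

## Known limitations

- nx must equal ny (square transaxial grid); detector rows equal axial
  slices.
- The projector's bilinear rotation slightly smooths; since acquisition
  and reconstruction share the operator this cancels in matched-model
  studies but adds ~1 voxel of effective blur relative to an analytic
  projector.
- Background ROI placement assumes the default outline leaves room for
  twelve 37 mm ROIs; a much smaller custom outline raises `LayoutError`
  with the count found.
- The centre-membership ROI rule carries a few-pixel digitization bias at
  4.8 mm; the area-weighting mode removes most of it.
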