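# Methods

This note documents the models behind each quantification stage, the
parameters that matter (with units and defaults), what the synthetic
generators do and do not emulate, and the numerical choices made where
the procedure left room for interpretation.

## Microtubule Distribution Index

The MDI summarizes the radial distribution of tubulin intensity in a
cell given a manually chosen central point and boundary polygon.  Rays
are cast at angles `k·Δθ` (counterclockwise from +x in image
coordinates, pixel-center convention, `k = 0 … ⌊360/Δθ⌋−1`; 120 rays at
the default Δθ = 3°), each ending at the *first* intersection with the
boundary so that profiles stay inside concave cells.  Intensities are
sampled along each ray at ~1-pixel arc spacing with bilinear
interpolation.  Per ray, `I_i` aggregates the samples in the inner
fraction of the length (default 0.10, adjacent to the center) and `I_o`
those in the outer fraction (default 0.40, adjacent to the boundary);
the middle 50% is ignored.  The aggregate is the mean by default (max
is available).  `R = I_o / I_i`; the MDI is the average of the defined
per-ray ratios.

Numerical choices:

* A ray whose inner aggregate is exactly zero has an undefined ratio
  and is excluded from the average; an error is raised only when every
  ray is undefined.  This avoids infinite ratios on background-free
  synthetic images without biasing the remaining rays.
* The sample count per ray is `⌈L − 10⁻⁹⌉ + 1` (endpoints included);
  the epsilon keeps the count stable when the ray length sits on an
  integer boundary.
* The MDI is invariant under global intensity scaling (ratios), and
  invariant under rotating image and geometry together by a multiple of
  Δθ up to interpolation error (exactly for 90° grid rotations).

Against a 10,001-point trapezoid integration of an analytic
exponential radial profile, the sampled MDI agrees to ~0.3%; agreement
degrades for profiles with structure finer than a pixel.

## Filament counting

`enhance_tubular` computes the Hessian of the image at a chosen
Gaussian scale (γ-normalized by `σ²`, derivative filters with edge
replication) and returns `max(0, −λ_min)`, the magnitude of the most
negative eigenvalue.  Bright 1-D ridges give strong responses; flat
regions and blob interiors are suppressed, which also removes the solid
centrosome core from the segmentation.  The default scale equals the
PSF sigma (1 px at 0.1 µm/pixel), matching the apparent width of a
diffraction-limited MT.

`skeletonize_and_count` binarizes the response (Otsu by default),
applies topological thinning to 1-pixel skeletons and labels
8-connected components.  Path length is the sum of edge lengths of the
minimum spanning tree of the skeleton's 8-neighbor pixel graph (axial
steps 1, diagonal √2, times the pixel size); the MST avoids
double-counting the axial+diagonal triangles that raw neighbor-pair
counting produces at corners.  A single-pixel component counts one
pixel of footprint.  An upper size bound (µm) removes objects longer
than plausible single MTs — the explicit, reproducible counterpart of
removing visually identified overlaps — and a lower bound discards
specks.  Raising the binarization threshold never increases the
foreground pixel count.

De novo calling: an object is de novo iff no skeleton pixel, dilated by
1 px (default) to tolerate channel-registration jitter, exceeds the
acetyl-channel threshold.  De novo and acetylated counts partition the
object set.

Aster area: in `roi` mode the area of the hand-drawn polygon times the
pixel area; in `seeded` mode (an automation convenience) an
Otsu-on-local-window threshold around the seed, returning the area of
the connected above-threshold region containing the seed.

## Dynamic instability

`segment_phases` implements the static rule: per consecutive-frame
pair, displacement `d` (Euclidean, µm) below 0.3 µm/frame is pause;
otherwise growth or shrinkage by the sign of the projection of the
displacement onto the unit vector away from a per-track reference point
(a minus-end proxy; at the reference itself the outward direction
degenerates and the step counts as outward).  Tracks with skipped
frames must be split first (`split_on_gaps`) because the rule is a
per-frame rule.  Per-interval speed is `d / Δt` in µm/min.

`summarize_dynamics` pools intervals: phase percentages are time
fractions (pause computed as the exact complement so the three sum to
100); speeds average over intervals of the matching phase; catastrophe
frequency is transitions into shrinkage (from growth or pause) per
minute of growth+pause time and rescue frequency transitions into
growth per minute of shrinkage+pause time.  This at-risk-time
denominator is the standard dynamic-instability convention; a
per-total-time variant is available via `denominator="total"`.
Frequencies with zero exposure time are reported as `None` (undefined),
not zero.

Frequency estimation from states sampled at interval Δt carries a
discretization bias ≈ `(k_cat + k_res)·Δt/2` (opposite transitions
within one interval cancel).  At the 3 s frame interval typical of live
imaging this is a few percent for rates of 1–4 min⁻¹; the recovery
tests therefore sample the simulator's state history at 0.1–0.5 s so
that the bias is well below the counting error, while the
position-based classifier is validated separately at 3 s against the
recorded true states.

## Comet origin classification

Tracks followed for fewer than `min_frames` (default 4, i.e. more than
three frames) are excluded.  A track is centrosomal when its first
sample lies within `centrosomal_radius_um` (default 2 µm) of the
user-supplied centrosome *and* its initial velocity points away from
it; non-centrosomal when it starts beyond `radius ×
ambiguity_factor` (default 2); anything in between — or starting near
the centrosome but moving inward — is excluded as ambiguous.  The
explicit radii replace a visual judgement and make the call
reproducible; the classification is invariant under rigid transforms of
all coordinates.

`detect_time_zero` sets time zero at the first fluorescence burst: the
baseline is the median of the first 10 frames, its robust deviation
1.4826×MAD floored at 1% of the baseline (so a flat trace never
triggers), and the burst is the first frame exceeding baseline + 8×
deviation.  The short baseline window makes the MAD noisy, hence the
conservative factor; on simulated washout traces (baseline 100, noise
σ = 2, burst +50 and ramping) the onset is recovered within ±1 frame.

## In vitro quantification

`quantify_field` thresholds at a fixed minimum intensity, labels
8-connected components and discards components below `min_area_px`
(default 4 px, suppressing single-pixel noise).  Counts are
non-increasing in both the threshold and the area floor for
single-peaked spots.  `aggregate_fields` reports mean ± SEM (sample SD)
of per-field count and mean size, warning below 25 fields; the SEM of a
single field is undefined (`None`).

`particle_density` is particles per µm of polyline length.  Gold
particles are input coordinates associated to a filament within a
capture distance (default 25 nm ≈ gold radius + antibody reach), making
"bound" explicit where the original counting was visual.

`density_length_correlation` ranks densities and lengths with average
ranks for ties and computes Pearson on the ranks.  The p-value is the
exact two-sided permutation probability (all n! pairings, streamed in
chunks) for n ≤ 10 and the t approximation with n−2 degrees of freedom
otherwise.  Constant inputs yield NaN (undefined), and fewer than 3
filaments is an error.

## Synthetic data: what it emulates, what it does not

Filament images render straight 1-pixel anti-aliased segments of unit
amplitude (overlaps saturate rather than add), convolve with a Gaussian
PSF (default σ = 1 px at 0.1 µm/pixel), add a constant background and
optional Gaussian or Poisson noise.  Aster layouts emanate radially
from a centrosome point; dispersed layouts place midpoints uniformly
with uniform orientation.  Non-overlap is enforced by rejection
sampling (10,000 attempts, then a "no placement area" error).  The
ground truth records every segment, its length (consistent with the
rendered polyline to 10⁻⁶) and its acetylation flag; acetylated
segments are also rendered into channel 2.  Not emulated: curved or
crossing filaments beyond what the size threshold removes, centrosome
body fluorescence, photobleaching, 3-D stacks.  Passing count-recovery
tests on these images demonstrates the pipeline's correctness on
well-separated diffraction-limited filaments, not its robustness to
dense real-cell networks.

The dynamic-instability simulator is a continuous-time three-state
process: growth advances the tip at `v_g` (default 12 µm/min),
shrinkage retreats at `v_s` (default 18 µm/min), catastrophe and rescue
are exponential with rates `k_cat`, `k_res`; at each transition a pause
is interposed with probability `p_pause` and exits after an exponential
dwell (default rate 1 min⁻¹) into the original target state — a minimal
three-phase model sufficient for recovery testing, since pause kinetics
beyond phase occupancy are not part of the extracted parameters.
Positions are sampled at the frame interval (default 3 s, default 40
frames ≈ a 2-min movie) with isotropic Gaussian localization jitter
(default σ = 0.05 µm, deliberately far below the 0.3 µm/frame
threshold); the true state at each sample time and the exact event
history are recorded.  The jitter magnitude is a free simulation
parameter: the localization precision of manual tracking is not a
measured quantity.

Comet tracks move ballistically at a constant speed (default 15
µm/min, 5 s frames): centrosomal tracks start within 0.5 µm of the
centrosome and move radially outward; non-centrosomal tracks start
uniformly at least 6 µm away (3× the default classification radius, so
labels are unambiguous by construction) with random direction, all
constrained to the cell polygon.

EM filaments are straight segments with lengths from a configurable
distribution and particle counts Poisson with intensity
`density_fn(L)·L`, positions uniform along the filament with lateral
offsets within the capture distance.  The inverse-density condition
`density_fn(L) = c/L` reproduces a strongly negative density–length
rank correlation.

All generators are bit-deterministic given their seed.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses 256–512 px images, 50 seeds for the
MDI-ordering and filament-count checks, 10 two-channel images for de
novo calls, 500 ten-minute tracks for frequency recovery (states
sampled at 0.1 s), 20×20 comet tracks, 200 EM filaments for the
correlation and 500 for density recovery, and 25 nucleation fields of
37 spots — sizes at which the sampling error of each statistic is a few
percent or less.

## Known limitations

* Filament counting resolves overlaps only by exclusion (the size
  bound), not by untangling crossings.
* The MDI assumes the center lies strictly inside a simple polygon;
  cells touching the image border should be outlined conservatively.
* Frequency estimates from coarsely sampled tracks are biased low by
  the discretization term above; at 3 s intervals and rates ≥ 2 min⁻¹
  this approaches 10% and should be corrected or sampled faster when it
  matters.
* The exact permutation p-value enumerates n! pairings and is
  practical only up to n = 10, where the t approximation takes over.
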