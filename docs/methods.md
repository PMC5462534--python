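# Methods

This note documents the models, conventions and numerical choices
behind `nmjquant`, and what the synthetic validation does and does not
establish about real data.

## Coordinate and unit conventions

Arrays are indexed `(channel, z, y, x)`; voxel indices are 0-based;
all reported geometry is physical (μm, μm², μm³). Confocal stacks are
anisotropic — the default voxel is (0.44, 0.25, 0.25) μm in (z, y, x),
the 0.44 μm axial step being the standard acquisition convention for
this assay — so every length is computed from inter-voxel physical
steps, never voxel counts. A stack without a physical calibration (in
OME metadata or supplied explicitly) is rejected: the decision rules
are physical lengths and guessing a pixel size would silently change
them.

## Segmentation

Each channel is smoothed with a Gaussian (σ = 0.2 μm, roughly the
lateral PSF width) and thresholded by Otsu. Two refinements matter:

- **Signal floor.** Otsu always splits a histogram, even of pure
  noise; a channel with no real signal (the nerve channel of a fully
  denervated junction) would otherwise grow a mask out of the noise
  tail. A foreground is kept only when its mean exceeds the background
  mean by 6 background standard deviations — a conventional z-score
  detection floor.
- **Smoothing scale.** A heavier prefilter (σ ≈ 0.5 μm) on top of the
  microscope PSF measurably erodes ~1 μm-radius tubular structures at
  Otsu's threshold (mask Jaccard vs truth ≈ 0.7); σ = 0.2 μm keeps
  masks faithful (Jaccard ≥ 0.95 on noiseless phantoms) while still
  suppressing 10%-amplitude noise. The value is configurable.

The largest connected AChR component is taken as the NMJ (an empty
AChR channel yields a record flagged `nmj_found=False`, not an error).
Nuclei are split by watershed on the anisotropy-aware Euclidean
distance transform, seeded by distance peaks at a minimum separation
of 2 μm; objects below 8 μm³ are discarded.

## Skeleton and branch geometry

The post-synaptic mask is thinned (scikit-image `skeletonize`); the
skeleton graph (26-connectivity) is decomposed into branches — maximal
paths whose interior voxels have degree 2 — with geodesic length the
sum of physical inter-voxel steps. Two standard cleanups follow:
leaf twigs shorter than 2 μm hanging off a junction are pruned (voxel
skeletons sprout such twigs at tube-surface bumps, and the fake
junctions they create would fragment uncovered runs), and junction
voxels whose neighbours remain mutually connected without them are
removed so through-paths re-merge. Thinning can erase a compact patch
entirely; the patch's distance-transform maximum is then kept as a
one-voxel skeleton so coverage remains defined. Branch counts use the
same strict >5 μm rule as classification.

## Coverage ("covered" = within reach)

Pre- and post-synaptic labels sit on apposed membranes; they are near
each other, not colocalized, so coverage is defined by proximity: a
skeleton voxel is covered iff a pre-synaptic voxel center lies within
the reach radius (default 1.0 μm; exact Euclidean distance transform).
Per branch, the maximal *contiguous* uncovered geodesic run is
reported — the partial-innervation rule speaks of a single uncovered
stretch of branch, not a sum of gaps. The devoid fraction weights each
skeleton step by the mean uncovered state of its endpoints, so an
empty pre-synaptic mask gives exactly 1 and full apposition exactly 0.
Enlarging the pre-synaptic mask can only shrink uncovered runs and the
devoid fraction (monotonicity), and the implementation agrees with a
brute-force all-pairs distance computation to floating-point rounding.

## Classification rules

Denervation is tested first: devoid fraction > 0.90 → completely
denervated; else any branch run > 5 μm → partially innervated; else
innervated. "Vast majority covered" is thus implemented as the
complement of the two degeneration rules, which makes the three labels
exhaustive and mutually exclusive. Post-synaptic state is independent:
fewer than 2 elaborate (>5 μm) branches → degenerated ("a patch");
the count is configurable (`min_elaborate_branches = 1` reads the rule
as "zero branches"). Myonuclei count when their overlap fraction with
the post-synaptic mask dilated by the apposition radius (1.0 μm)
strictly exceeds 0.25. The overlap is computed in 3D; a 2D
max-projection reading of the same rule is possible but conflates
nuclei stacked in z, so 3D is the default. All thresholds are strict
inequalities, matching the ">" of the rule statements.

## The NMJ phantom

The generator builds what the scoring procedure assumes:

- **Pretzel.** A central arc ("trunk", default ~15 μm) on a gently
  curved sheet (radius 60 μm — the muscle-fiber surface; the concave
  side faces the fiber), with 3–5 smooth side branches (Bézier curves,
  8–15 μm). Tubes of radius 1.2 μm around these centerlines form the
  post-synaptic mask. Side branches keep ≥(2·radius + 0.8) μm
  clearance from each other: touching tubes would merge into loops the
  branch-wise truth model does not describe. A post-synaptically
  degenerated NMJ is a short (≈3 μm) thick (1.8 μm) patch.
- **Pre-synaptic terminal.** A tube (radius 0.9 μm) along the covered
  intervals of the centerline, offset 1.2 μm toward the convex side.
  `coverage_fraction` sets the covered arclength exactly; explicit
  gaps are carved as geodesic intervals on side branches (clear of the
  trunk, whose attached branches would otherwise re-cover them), each
  widened by the geometric reach margin √((reach+r_pre)² − offset²) per
  side so the nominal gap length equals the reach-measured uncovered
  run.
- **Ground-truth coverage** is computed from the *continuous* geometry
  (point-to-tube distances on the densely sampled centerlines), not
  from the voxel grid the measurement pipeline sees — an independent
  oracle with the same coverage definition.
- **Nuclei.** Ellipsoids (semi-axes 1.8 × 2.4 × 2.4 μm) are placed by
  bisection along a downward ray until the voxel-exact overlap with
  the dilated post-synaptic tube hits the target; the achieved
  fraction is recorded as truth. Overlaps much above ~0.6 are
  geometrically unattainable against a thin tube, so random draws use
  targets in [0.35, 0.55] — comfortably above the 0.25 rule — and
  non-synaptic nuclei are placed with zero overlap. A patch phantom
  carries at most one synaptic nucleus (two cannot be separated).
- **Optics and noise.** Channels are amplitude × mask (amplitude 100),
  blurred with a Gaussian PSF (σ = 0.4, 0.2, 0.2 μm), then Gaussian
  read noise (optionally Poisson shot noise) is added. Ground truth is
  exact pre-noise.

`sample_phantom_params` draws parameters for a requested
(pre, post) class combination and verifies the draw against the
continuous oracle with the reach radius perturbed ±0.5 μm — redrawing
when branch interference or voxel-scale ambiguity could blur the
intended label. The margins (runs > 6 μm for partial innervation,
devoid > 0.93 for denervation, < 0.05 for innervation) are the
generator's definition of an unambiguous phantom. "Partially
innervated + degenerated" is geometrically impossible (a patch has no
branch long enough to carry a >5 μm run), leaving five attainable
class combinations.

## The fiber-section phantom and typing

Fibers are a Lloyd-relaxed Voronoi mosaic (dart-thrown seeds with a
minimum distance derived from the minimum fiber area; areas default to
1200–3200 μm², typical of fast-twitch muscle). The laminin channel is
bright where the distances to the two nearest seeds differ by less
than the boundary width (2 μm); MyHC-IIA/IIB channels are bright
inside fibers of that type (per-fiber ±20% intensity jitter), IIX
fibers are dark in both. Types are assigned by largest-remainder
apportionment so the section's composition equals the requested
proportions exactly.

Typing segments fibers as watershed basins of the distance transform
inside the laminin boundary, with one marker per fiber taken as the
superlevel set at 0.6 of each region's distance maximum — on a convex
region the distance function is concave, so that set is connected and
convex fibers are never split, while two fibers merged through a small
boundary gap meet at a shallow neck and stay split. When several
high-level blobs appear, they only count as separate fibers if still
disconnected at a lower level (hysteresis). Border-touching regions
(truncated CSA) and regions under 100 μm² are excluded. Positivity
uses an Otsu cut over the pooled per-fiber mean intensities of both
MyHC channels (bimodal whenever anything is stained; invariant to
uniform rescaling), with a guard that rejects a meaningless split of
all-background data; a fiber positive in both channels is reported as
`hybrid`, never silently binned. CSA recovery is calibrated at
pixel sizes ≤ 0.5 μm; at 1 μm pixels the half-pixel boundary
uncertainty on a ~45 μm-side fiber is itself ~5%.

## Statistics

The replication unit is the mouse: per-NMJ labels are aggregated to
per-mouse proportions first, then to group mean ± s.e.m. (a
single-mouse group is flagged; its s.e.m. is NaN). Size-vs-myonuclei
regressions are ordinary least squares of volume and cumulative AChR
intensity on the count, pooled across mice with mouse annotation
retained. Two-group comparisons are unpaired two-sided t-tests;
factorial designs use a two-way ANOVA with type-II sums of squares
(robust to the mildly unbalanced mouse counts typical of such
cohorts) and pairwise cell comparisons on the pooled residual
variance, Sidak-adjusted (`p_adj = 1 − (1−p)^m`) over an explicitly
named comparison family — family sizes are never implicit.
Significance is declared at 0.05.

## Problem sizes and limitations

Validation cohorts use 150–200 phantoms per condition at stack extents
of ~38 × 38 × 14 μm (≈150×150×32 voxels) — the package's chosen
balance of coverage and turnaround; accuracy is not sensitive to the
cohort size. Known limitations: the phantom has no autofluorescent
background, no bleed-through, no Schwann-cell or axon signal outside
the terminal field, and its branches do not form loops — real pretzels
can. Absolute volumes and intensities depend on the segmentation
threshold (the original interactive reconstruction published no
algorithm), so cross-study comparisons should fix the configuration;
classification is far less threshold-sensitive than the raw volumes.
Passing the synthetic checks demonstrates the rules and geometry are
implemented faithfully, not that segmentation is optimal on any
particular microscope's data.
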