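# Methods

This note documents the models and algorithms implemented in `perfusemri`,
the choices made where the design was genuinely open, and what the
phantom-based validation does and does not establish.

## Synthetic vascular phantoms

The phantom generator exists so that every analysis stage can be judged by
parameter recovery against a known ground truth rather than against
external image data.

**Tree model.**  Vessels are modelled as a binary bifurcating tree: one
inlet segment, then `tree_depth − 1` generations in which every branch
splits into two children.  Every internal node therefore has coordination
number 3, matching the near-3 mean coordination numbers observed in hepatic
venous networks.  Radii taper by a fixed factor per generation; the default
`radius_decay = 2^(−1/3) ≈ 0.794` is Murray's law for a symmetric
bifurcation (total cube of radii conserved).  Defaults — root radius 5 mm,
segment length 20 mm decaying by 0.8 per generation, 0.66 mm isotropic
voxels on a 168×144×144 grid — put the largest vessels at the several-mm
scale and the finest at ~2.5 mm, inside the radius range a T2-weighted
acquisition at this resolution can segment.  Children leave a bifurcation
at ±37.5° from the parent direction in a plane of seeded random azimuth, so
the tree spreads through the volume without leaving the grid for any seed.

**Tortuosity.**  Each segment is a straight chord plus a single half-sine
lateral bow of amplitude `tortuosity_amplitude_mm` (default 1.5 mm).  The
arc length of the bow is computable in closed form, so the true tortuosity
of every segment is known analytically; the default amplitude puts the
median tortuosity near 1.05, typical of healthy hepatic vessels.  This is a
single-frequency model: it does not emulate the multi-scale wiggles of
diseased vasculature.

**Rasterization.**  A voxel is foreground iff its centre lies within the
local radius of any polyline interval — a union of capsules (cylinders with
spherical caps).  Capsules make junctions and tips smoothly rounded; the
voxel count of a rasterized straight segment converges to the analytic
capsule volume `πr²L + 4/3·πr³` as spacing shrinks.  Radii below half a
voxel trigger a warning because such branches are not resolvable on the
grid (sampling limit).

**Signal models.**  T2-like contrast is two Gaussians (vessel
200, parenchyma 100, SD 5 by default), clipped at zero.  DWI signals follow
`S = S0·exp(−D·b)` with optional magnitude-of-complex-Gaussian (Rician)
noise — the standard MR noise model, configurable off.  DCE series use a
bolus front advancing along the tree at constant speed: a voxel starts
enhancing when the front's path distance (graph shortest path from the
inlet plus within-segment arc length) reaches its nearest centerline point.
The default kernel is step-and-hold, which makes the first-maximum TTP
exactly the arrival frame; a gamma-variate kernel is available for
rise-and-fall curve shapes.  An optional `bolus_delay_s` postpones the
injection relative to scan start so pre-contrast baseline frames exist even
at the inlet.

**Histology simulation.**  A category score is drawn as
`floor(m) + Bernoulli(m − floor(m))` — whose expectation equals the target
mean `m` exactly — plus an integer perturbation `round(N(0, dispersion))`,
clipped to {0..3}.  A mean exactly on a rubric boundary (0 or 3) pins the
category: the rubric admits no score beyond the boundary, so such a group
shows no sampling spread.  Dispersion defaults to 0.3 (roughly one-in-ten
biopsies one grade off), a choice the data cannot constrain because only
group means are available.

## Volume handling

Volumes are `(x, y, z[, t])` grids with voxel spacing in mm; the world
position of voxel `(i,j,k)` is `origin + (index + 0.5)·spacing` (0-based
indices, voxel centres).  NIfTI-1 is the on-disk format, with the frame
interval in the time-spacing header field.

Isotropic resampling uses separable cubic BC-kernels with the
Mitchell–Netravali parameters B = C = 1/3; `linear` and `nearest` are
available as alternatives.  The implementation resamples all three axes
when needed, the slice direction being the common case.  Border samples
clamp to the edge with weight renormalisation, so constants are reproduced
exactly (partition of unity) and linear ramps survive resampling away from
borders.  The anti-aliasing width equals the scale factor when
downsampling.  The mapping from field of view to target spacing is left to
configuration — 0.66–0.83 mm are the typical targets at liver field of
views.

## Segmentation

Region growing is an absolute-band flood fill: voxels connected to a seed
through intensities in `[low, high]`, 26-connected by default for
consistency with the skeletonization stage.  An absolute band (rather than
a seed-relative tolerance) keeps runs reproducible.  Per-plane masks are
merged by voxel-wise union.  Tests pin the output to a brute-force BFS
flood fill on small grids.

## Skeletonization and graph extraction

1. **Chamfer distance map.**  The ⟨face, edge, corner⟩ = ⟨3, 4, 5⟩ chamfer
   transform over the 26-neighbourhood, computed with the classic two-pass
   raster scan.  For this weight set the two passes equal the exact
   weighted-graph shortest path to in-grid background, which a
   Dijkstra-oracle property test verifies on random masks.  Chamfer units
   convert to mm via the face weight and the voxel spacing.
2. **Distance-ordered thinning.**  Voxels are visited in increasing
   distance; one is removed only if it is a (26, 6) simple point (removal
   preserves the local connectivity of foreground and background) and not a
   line end (≤ 1 foreground neighbour).  Each distance layer is eroded to
   stability before the next begins, so removal never races ahead of the
   distance ordering.  Ties within a layer are broken by the sum of the 26
   neighbours' distances, then lexicographic index: a layer erodes from the
   structure's rim inward, which keeps surviving line ends centred on the
   medial axis (on a radius-3-voxel cylinder the skeleton lies exactly on
   the axis, shortened by about one radius at each end — the classic
   behaviour of homotopic thinning).  Terminal branches shorter than
   `min_end_length` voxels (default 2) are pruned afterwards to suppress
   spurious spurs from surface roughness.
3. **Line tracing.**  Skeleton voxels with two 26-neighbours form chains;
   all others are node voxels.  Adjacent branch voxels (degree ≥ 3) are
   merged into one node at their centroid so a bifurcation blurred over two
   voxels still counts once.  Isolated cycles receive one artificial
   degree-2 node and a closed polyline.
4. **Smoothing.**  Interior polyline points iterate
   `p ← p + smoothing·(mean(neighbours) − p) + attach·(p_original − p)`
   (defaults 10 iterations, 0.5, 0.25) with segment end points fixed.  The
   attach term limits the contraction that pure Laplacian smoothing would
   cause.
5. **Radii.**  Each polyline point takes the chamfer distance at its voxel,
   converted to mm — the inscribed-ball radius, which is well defined even
   off-axis.  The 3-4-5 metric under-measures oblique directions by up to
   ~6% and the voxel lattice adds up to about half a voxel of quantisation,
   which bounds the radius accuracy; recovery tests on rasterized cylinders
   hold radii to ±0.5 mm at 1 mm voxels.

The reference protocol this reconstructs was specified through proprietary
software modules whose exact removal rules are not published; equivalence
is therefore established at the level of invariants (topology preservation,
axis accuracy, parameter recovery), not bit-exactness.

## Morphometrics

Per segment: curved length (sum of polyline steps), straight length
(chord), tortuosity (curved/straight, defined as 1 for closed loops),
mean radius, and frustum volume `Σ π·r̄ᵢ²·δlᵢ`.  Per network: totals,
terminal (degree-1) and branching (degree ≥ 3) node counts — degree-2
cycle markers count as neither — terminal fraction, mean coordination
number over branching nodes, and segment medians (linear interpolation
between order statistics).  Vessel volume is reported from the
radius-annotated graph; the voxel count of the mask gives an independent
volume estimate where a mask is available.

## Diffusion (ADC)

`ln S` is regressed on `b` per voxel: `D = −slope`, `S0 = exp(intercept)`.
The log-linear fit is closed-form, deterministic and exact on noise-free
monoexponential input; a nonlinear refinement was considered and rejected
as the primary route because it adds iteration-dependent behaviour without
changing the noise-free answer.  Voxels with non-positive signals are
flagged invalid (log undefined) rather than zero-filled; negative fitted D
is clipped to 0 and flagged.  Direction maps are fitted independently and
averaged arithmetically — three orthogonal directions are averaged, not
tensor-fitted.  Parenchymal statistics exclude voxels below a background
threshold on the lowest-b volume (default 10% of its 99th percentile) and
voxels inside the vessel mask; the vessel mask is resampled
nearest-neighbour when grids differ, preserving binarity.  Units are mm²/s
throughout.

## DCE (perfusion)

Enhancement is signal minus the mean of the baseline frames; no
signal-to-concentration conversion is applied (none is calibrated).
TTP takes the *first* frame attaining the maximum — a deterministic tie
rule that equals the arrival frame under the step kernel.  Voxels whose
peak enhancement does not exceed the noise floor are flagged invalid.

Bolus-front tracking marks a path point as "arrived" when its enhancement
reaches half its eventual maximum (half-max arrival, threshold
configurable); the front position at a frame is the arc length of the
farthest arrived point, forced non-decreasing by cumulative maximum.
Velocity is the least-squares slope of front distance versus time over the
*advancing window*: plateaus before bolus entry and after traversal are
excluded, and the sample in which the front reaches its final position is
dropped when enough samples remain, because it only interval-censors the
true arrival.  The quoted uncertainty is the SD of frame-to-frame speeds.
Volumetric flow is `Q = ¼·π·d²·v` with the diameter taken as twice the
graph radius at the measurement location, linking the DCE estimate to the
skeleton-graph radii.

## Histology

The rubric grades each feature 0–3; necrosis by percentage of hepatocytes
affected (0 → 0; under 10% → 1; 10–30% → 2; over 30% → 3, boundaries taking
the higher grade), the qualitative features by a severity ladder.  Multiple
examined fields are graded by the most severe observation.  The composite
is the category sum (0–12), asserted on ingest for every record.  Group
summaries are arithmetic means per (group, timepoint) cell; by linearity
the mean composite equals the sum of category means, which is verified
rather than assumed.  `compare_groups` reports an independent two-sample
t-test on composites with Shapiro–Wilk and Levene diagnostics; it is a
reporting convenience over user-supplied or simulated biopsy scores, not an
inferential claim about any particular dataset.

## Pipeline and reproducibility

A YAML config with one flat namespace per stage drives the full run;
unknown keys are rejected.  All randomness flows through explicit seeds
(one per stochastic stage, derived from the run seed), so identical configs
give identical outputs.  Each run directory contains the resolved config
and a log alongside the artifacts (NIfTI volumes, graph JSON/CSV, stats
JSON).

## Problem sizes

The validation suite uses a depth-4 phantom (15 segments, ~23 000
foreground voxels at 0.66 mm), a 120 mm straight-vessel DCE phantom at 24
frames, 12³-voxel noisy ADC phantoms, and 50 random ≤ 24³ masks for the
chamfer/Dijkstra equivalence — sizes at which each check runs in seconds
while exercising the same code paths as full-size data.

## Known limitations

- The tree phantom has a single inlet; the liver's dual inflow (hepatic
  artery + portal vein) and the separation of portal from hepatic venous
  trees are not modelled.
- Phantoms are pre-aligned: no registration between orthogonal
  acquisitions, no motion or susceptibility artefacts.
- Chamfer-based radii inherit the 3-4-5 metric's ~6% directional bias and
  half-voxel quantisation; sub-voxel radius accuracy would need a Euclidean
  distance transform with parabolic interpolation.
- Passing phantom-recovery tests shows the chain is self-consistent and
  correctly implemented at realistic geometry and noise levels; it does not
  certify accuracy on real scanner data, whose artefacts the generators do
  not emulate.
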