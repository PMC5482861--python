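# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order data flows through it.

## Synthetic cast phantoms

**Domain.** A cast occupies a flat cylindrical disc (height = 0.8 ×
radius), the idealised placental disc. The default tissue volume is
8 cm³ — a deliberately scaled-down organ (a term placenta is ~500–600 g),
chosen because length density is scale-free: the group medians used for
calibration are densities, so a desk-scale domain carries the same
targets while keeping volumes near 300³ voxels at the modelled 0.09 mm
voxel size. `tissue_volume_cm3` is a preset field; nothing in the
pipeline assumes the default.

**Tree growth.** Growth is breadth-first stochastic bifurcation from a
single trunk entering at the top-centre of the disc (the cord insertion).
Each tip extends by one inter-branch segment, then splits into two
children with diameters `d_child = clamp(d_parent · taper · e^{N(0,σ_t)},
floor, d_parent)`; the clamp to the parent diameter keeps radii
monotonically non-increasing along every root-to-leaf path, and the floor
(90 µm) represents the smallest lumen the resin fills. Segment length is
log-normal around `max(base, ratio · d)` — vessels branch at intervals of
a few diameters (`length_diameter_ratio = 4`), floored at `segment_length_mm
= 1.3` for the thinnest vessels and capped at half the domain radius so
scaled-down phantoms keep room to manoeuvre. Course deviations (bends)
occur as a Poisson process along the centreline (`bend_rate = 0.4 /mm`)
with deviation angles `N(45°, 12°)`; bifurcation opening angles are
`N(70°, 12°)` overall. These rates are realism choices, fixed once; no
published bend statistics exist to calibrate them, which is also why
tortuosity is validated only for internal consistency, not against
printed values.

**Collision avoidance.** A corrosion cast is a solid replica: distinct
lumens may touch but cannot interpenetrate. Proposed growth steps whose
capsule would enter an existing vessel are re-aimed (up to 25 attempts,
then the tip terminates — or, if it already grew ≥30% of its segment,
bifurcates in place and lets its children search for space). Edges
touching the junction ball around the current anchor are exempt, since
parent and sibling lumens legitimately merge at a branch point. Without
this the dense cohorts produce crossing vessels whose images fuse, which
no real cast exhibits. A cast that walls itself in before reaching its
target density is regrown from a fresh deterministic substream (up to 20
attempts).

**Exact target density.** Growth stops exactly when total centreline
length reaches `target × tissue_volume`; the final segment is truncated
to the remaining budget. The ground-truth density of a returned tree
therefore equals its target to machine precision, and is always
recomputable from the tree file as Σ edge lengths / volume. If the
generation cap or crowding kills the tree below 95% of target, the error
reports the achieved density.

**Breakage.** Casts lose small fragile branches. Each terminal with
diameter below 100 µm is truncated, with probability 0.3, together with
its maximal run of sub-threshold bend points; the walk stops at the first
branch point or at-threshold point, so the tree stays connected and no
vessel at or above the analysis threshold is altered.

**Voxelisation.** A voxel is foreground iff its centre lies within the
locally interpolated radius of the nearest centreline point (a union of
cone-frustum capsules). Intensities are 1/0 plus optional additive
Gaussian noise (default SD 0.08) — a nuisance parameter, not a CT physics
model, because cast CT contrast is high enough for automatic
segmentation. Vessels thinner than about one voxel render one voxel
thick or fragment, reproducing the scanner's ~80 µm resolution floor.

**Cohort calibration.** Each of the four presets carries its group's
published median length density and an IQR-matched log-scale spread
`σ = ln(q75/q25) / (2 · 0.67449)`. Per-cast targets follow a
*truncated* log-normal: the log-deviate is capped at ±1.5 standard
normal units and rescaled so the quartiles — hence the IQR — are
preserved exactly. The truncation is itself a calibration to the
published data: the two arterial groups' printed IQRs are disjoint and
their printed Mann-Whitney p-values (0.009 at n = 6+6, i.e. U ≤ 2) imply
near-complete separation of the groups, which the far tails of an
untruncated log-normal would contradict. Cohorts are drawn by
**stratified quantiles** — one jittered draw from each of n equal-
probability slices, assigned to casts in random order — so a 6-cast
cohort is a balanced sample of its group: its median and spread reflect
the group's rather than the luck of six independent draws. (Six iid
log-normal draws at σ ≈ 0.57 have a sample median swinging ±30%, which
would make any 6-cast study non-reproducible by construction; the
stratified design is the phantom-study analogue of drawing a
representative case series.) Stratified draws are not iid; the
Mann-Whitney permutation null is still applied to them as it would be to
any observed case series.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning, keyed per preset, per cast and per
regrow attempt: same seed, byte-identical cohorts.

## Measurement pipeline

**Segmentation.** Global Otsu threshold (or a fixed value), then removal
of 26-connected components below 5 voxels. 26-connectivity is used
throughout for foreground, preventing artefactual breaks in diagonal
vessels. At the modelled noise level the background produces no speckle;
the component filter exists for real data and heavier noise. Subvolume
tiling (default 800×500×300, soft cap 9) is a deterministic raster
partition kept purely as a memory device: tiles partition the volume, so
additive quantities sum exactly, and all measurements are made on the
globally re-assembled graph so border vessels are never double-counted.

**Skeletonisation and graph.** 3D thinning (Lee's algorithm via
scikit-image) gives a one-voxel-thick, topology-preserving skeleton.
Voxels with ≥3 skeleton neighbours are junction candidates; mutually
adjacent ones collapse to a single node at the member nearest the
cluster centroid. Degree-2 runs become edges with their ordered voxel
polyline. The container is a multigraph: anastomotic loops (e.g.
Hyrtl's anastomosis between the umbilical arteries) are legal here and
only the tree-map stage breaks them.

**Edge length.** Edge length is the sum of Euclidean inter-voxel steps
(× voxel size). A moving-average smoothing of the polyline is available
(`SMOOTH_WINDOW`), but the default is the raw chain: on phantoms of
known length the raw chain's small staircase over-measure (+3–8%
depending on orientation) offsets the junction-confluence and
corner-rounding losses of thinning almost exactly, making the raw
measure the least biased overall. This cancellation was established on
straight and bent tubes and isolated bifurcations of 2–20 voxel radius,
and on whole phantom cohorts, where per-cast filtered length-density
error is a few percent with no systematic sign.

**Radii.** The per-voxel radius is `(EDT − 0.5) × voxel` — distance from
the skeleton voxel centre to the nearest background voxel centre, pulled
back half a voxel to the foreground/background face; a one-voxel line
reports half a voxel by this convention. Because the EDT quantises hard
at the resolution floor (any sub-voxel vessel reports half a voxel,
whatever its true calibre), a second, *volume-equivalent* estimate is
computed: every foreground voxel is assigned to its nearest skeleton
voxel, and the local cross-section follows from assigned volume per unit
centreline length (the expected voxel count per unit length equals the
true cross-sectional area, so this estimate is unbiased down to
sub-voxel calibres). The per-voxel diameter is the larger of the two;
edge mean diameter is the length-weighted mean along the polyline with
junction-cluster voxels excluded (their EDT is inflated by the
confluence). This keeps near-threshold vessels on the correct side of
the 100 µm filter; genuinely sub-threshold vessels still fall below it,
as in the real scans.

**Artefact repair.** Thinning a thick curved tube can leave a medial
*sheet* that reduces to duplicate near-parallel paths, i.e. spurious
cycles confined inside the tube. Parallel edges whose Hausdorff
separation is under 1.5 × the local radius, and cycles whose spatial
extent (over edge paths, not just nodes) is under 3 × the largest local
radius, are collapsed by dropping the longer duplicate; genuine
anastomoses span far larger extents and are kept. Terminal twigs shorter
than 1.5 × the junction radius are pruned as thinning spurs, and nodes
left at degree 2 are contracted so edges stay maximal. Finally, thinning
retracts free vessel ends — by about the local radius for thin vessels
but only a few voxels for thick ones — so min(local radius, 3 voxels) is
added back at every degree-1 node. The 3-voxel cap is the empirical
retraction scale of the 26-connected thinning at rounded caps.

**Node classification.** Degree 1 → terminal, degree ≥3 → true branch
point. Along each remaining polyline, the local direction change is
measured over a ±5-voxel arc (the polyline is smoothed first so the
digitisation staircase does not register); wherever it exceeds 30° a
bend node is inserted, with non-maximum suppression keeping bends at
least one arc apart. The 30°/5-voxel rule is an explicit, configurable
surrogate for the proprietary node-placement rule of commercial
packages, which is not published; tortuosity results should always be
read relative to these two parameters. Bends subdivide edges by exact
partial sums of the stored step lengths, so total length is invariant
under classification.

## Morphometry

The working container is the segment table: one row per edge between
consecutive nodes of any class. The 100 µm filter keeps segments with
mean diameter ≥ the threshold (inclusive); end-node classes are then
recomputed on the surviving subgraph (a branch point reduced to two
segments becomes a bend, to one a terminal). Total nodes = branch points
+ bends (terminals excluded); tortuosity = total nodes − true branch
points, which is the bend count by construction and is reported alongside
the alternative published phrasing segments − true branches
(`tortuosity_segments`), since the source text uses both. The diameter
census uses half-open bins [eᵢ, eᵢ₊₁) starting at 100–200 µm with an
open-ended last bin, so counts always sum to the filtered segment count.
Densities divide by tissue mass in grams at 1 g = 1 cm³; for synthetic
casts the mass is the domain volume.

## Tree maps

The rooted tree is built on the largest connected component; the root is
the node nearest a user hint, else the largest-radius terminal (the cut
umbilical trunk). Breadth-first spanning breaks each cycle by dropping
the edge farthest from the root in traversal order. A *branch* is a
maximal path between consecutive true branch points (bends pass
through); the trunk is level 1 and each true branch point increments the
level, root excluded. Decile binning splits L levels into ten contiguous
groups of ⌊L/10⌋ levels with the remainder front-loaded one extra level
per group (80 levels → ten groups of eight; 83 → 9,9,9,8,…); fewer than
ten levels leaves trailing groups at zero with a logged warning. The
remainder rule is a documented convention — the source material only
specifies the divisible case.

## Statistics

Mann-Whitney U is exact for combined n ≤ 20: the null is the full
enumeration of label assignments over the pooled mid-ranks, so ties are
handled exactly; the two-sided p is min(1, 2 × smaller tail). Above
n = 20 the normal approximation with tie and continuity correction is
used; the two branches agree to <0.01 at the crossover. Per-decile
comparisons are per-bin Mann-Whitney with Šidák adjustment
`1 − (1−p)¹⁰`. This replaces the two-way repeated-measures ANOVA used in
the original analyses: with six casts per cell and an unspecified
sphericity/interaction structure that model is under-determined, while
per-bin tests with Šidák protection are fully specified and carry the
same family-wise error control — a deliberate, documented deviation.
Medians and IQRs use numpy's inclusive linear-interpolation quantile
rule everywhere.

## What the phantoms do and do not show

Passing the round-trip tests shows the measurement chain recovers known
centreline length, radii, node classes and cohort statistics from
realistic voxel data with the study's resolution, filter and sample
sizes. The phantoms do **not** claim anatomical fidelity: no validated
villous branching statistics, no Hyrtl's anastomosis in the generated
arterial trees (loops are handled but not generated), no CT projection
physics or beam hardening, no resin perfusion modelling, and terminal
capillaries below the filter are absent by design. Conclusions about
real casts therefore rest on the measurement chain being unbiased on
tube-like geometry, not on the phantoms resembling placentas in every
respect.

## Problem sizes

Default phantom domains are 8 cm³ at 0.09 mm voxels (~300³-voxel
grids); a full 4-cohort × 6-cast analysis runs in about 1–2 minutes on
one CPU, and the seed sweep for the direction-of-effect check uses
ground-truth trees through the morphometry route (no voxelisation),
50 seeds × 12 casts. The voxel pipeline and the ground-truth route agree
to within 10% per cast, which is what justifies the cheaper route for
the sweep.
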