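# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `vesimap`. It is written for users deciding whether the
defaults fit their data, and for maintainers wondering why something is the
way it is.

## Conventions

All internal lengths are nanometres; Ångström and voxel units exist only at
I/O boundaries (STAR coordinates are voxels and are converted with the
user-supplied pixel size in Å/voxel; the CSV dialect is nm by definition).
Orientations use intrinsic ZYZ Euler angles (rot, tilt, psi) with
A = Rz(psi)·Ry(tilt)·Rz(rot) mapping the tomogram frame to the particle
reference frame; the particle's outward axis in the tomogram frame is
Aᵀ·(0,0,1). Particle tables produced with the opposite sense are read with
`euler_sense="particle_to_reference"`, which uses A·(0,0,1); the choice is
recorded in logs. Voxel coordinates are treated as distances from the
tomogram origin with no half-voxel shift; a reader flag adds +0.5 voxel for
dialects that center voxels. The beam axis is the tomogram z axis: the
missing wedge is symmetric about the tilt plane, and the orientation bias
it causes depends only on the angle to z.

## Vesicle reconstruction

**Model.** A particle anchored on a spherical vesicle satisfies
a = c + R·u, where a = p − h·u is the membrane anchor, c the center, R the
radius and u the outward axis. Two particles on the same vesicle share c,
which gives the closed-form pair radius
R* = (aᵢ−aⱼ)·(uᵢ−uⱼ)/|uᵢ−uⱼ|² and a residual center mismatch (gap).

**Grouping.** Particles within a tomogram are nodes of a compatibility
graph. An edge requires: non-parallel axes, gap < `center_merge_eps`
(default 5 nm — about half the smallest vesicle radius analyzed, so
distinct vesicles at realistic packing cannot satisfy it), R* within
`radius_bounds` (default 12–60 nm, spanning synaptic-vesicle to
clathrin-coated-vesicle scales), and both axes within
`axis_consistency_max_deg` (default 15°; generous relative to the few
degrees of angular error typical of subtomogram alignment, strict enough
to reject accidental ray intersections) of the candidate outward radial
direction. Connected components become vesicles. Ordering is deterministic:
particles are sorted by id, components by their smallest member.

**Fitting.** Each multi-particle component is fitted by linear least
squares of the 3k equations a = c + R·u in the four unknowns (c, R) —
exact on noiseless data. When membrane points are supplied, points within
`membrane_snap_eps` (default 5 nm) of the fitted sphere surface join a
geometric sphere fit (algebraic initialization, Gauss–Newton refinement of
radial residuals, ≤50 steps, tolerance 1e-9 nm); the snap-and-refit runs
twice so the second round re-selects membrane points against the refined
sphere rather than the axis-only initialization.

**Singletons.** A single particle determines the center ray but not the
radius. With membrane points, every candidate point implies a closed-form
radius along the ray (|m − a + R·u| = R gives R = −|d|²/(2 d·u), d = m−a);
the densest 1-nm bin of implied radii identifies the vesicle's own surface
points, robust to membrane points of neighboring vesicles inside the
search radius (2·R_max around the anchor), and a constrained 1-D least
squares on those inliers gives the radius (`radius_source="membrane_fit"`).
Fits whose radial rms exceeds `membrane_snap_eps` are rejected. Otherwise
the singleton takes the dataset prior — the mode (0.5 nm resolution) of the
multi-particle radii in the same dataset, falling back to `default_radius`
(20 nm) — and is flagged `radius_source="default_prior"` so radius-based
analyses can exclude it (the selection stage always does).

**Precision.** With 2–3 particles per vesicle, anchor noise of 0.5 nm and
axis noise of 3°, the radius information in the particles alone is limited:
an efficient weighted estimator still leaves an RMSE above 1 nm, dominated
by pairs subtending a small central angle. Sub-half-nanometre radius
accuracy therefore relies on membrane support; with a modest segmentation
sampling (30 points per vesicle, 1 nm radial noise) the pipeline measures
~0.2 nm RMSE with >99% membership accuracy. This is a property of the
problem, not of the implementation, and is why the copy-number-versus-
radius analysis should either supply membranes or restrict itself to
fitted (non-prior) radii.

## Spatial randomness test

**Distances.** On a fitted vesicle, the pairwise geodesic distance is
d = R·arccos(û₁·û₂) with û the unit direction from the center to the
member position; dot products are clamped to [−1, 1].

**Selection.** The analysis runs on vesicles with exactly k members and
radii in a stated range. Two range rules are provided: closed interval,
and rounded-to-integer-nm membership (default, matching how radii are
reported as whole nanometres). Prior radii are always excluded.

**Orientation bias.** Under isotropy q = |cos θ| between a radial particle
axis and the beam is uniform on [0, 1], so the empirical histogram of q is
directly proportional to detection weight per orientation. The bias model
uses 18 equal-width bins with a Laplace pseudo-count of 1 (avoids
zero-acceptance bins) normalized to maximum weight 1. Estimating from a
few hundred axes is adequate; the type-I calibration below holds with the
bias estimated from an independent dataset-scale sample, mirroring
estimation from a full particle set rather than from the tested subset.

**Null.** Complete spatial randomness on a sphere of the selected
vesicles' mean radius (a per-vesicle-radius variant cycles the observed
radii), with each direction accepted with probability weight(q) and
redrawn until k survive per vesicle. The default null size is 2000
vesicles. With the bias disabled the central angle has density sin(θ)/2
(mean π/2), the module's primary analytic oracle.

**Comparison.** Two-sample Kolmogorov–Smirnov: D is the supremum of the
ECDF difference over pooled jump points (ties handled by the pooled-jump
definition); p-values are asymptotic with effective size n₁n₂/(n₁+n₂), or
exact (scipy's enumeration) — "auto" switches to exact when both samples
have ≤10 values. A calibration caveat worth knowing: with *equal* sample
sizes the D statistic lives on the coarse lattice m/n, so p-values are
discrete in steps that can reach ~0.07 near the center of the Kolmogorov
distribution; distributional checks of p-value uniformity should use
unequal sample sizes (as the experimental-versus-null comparison naturally
does), where the lattice is much finer.

## Membrane proximity

Object-to-membrane distance is the minimum Euclidean distance to the
membrane point cloud (KD-tree), or the exact minimum point-triangle
distance in mesh mode (exhaustive over triangles). For a planar grid of
spacing s the point-cloud discretization error is bounded by √(0.5)·s.
Class comparisons report per-class mean/median/n and a symmetric matrix of
two-sided p-values; the default test is two-sample KS (the only test the
headline analyses name), with Mann–Whitney as an alternative and optional
Holm adjustment (off by default: raw pairwise p-values are what the
analyses report).

## Annotation consensus and histograms

Per structural class, counts are averaged over annotators per vesicle,
then over vesicles. "Presence" of a class on a vesicle is not uniquely
defined by a count table, so two rules are reported side by side:
per-vesicle annotator mean ≥ 0.5 (majority-of-annotators evidence; the
threshold is configurable) and any-annotator-saw-≥1. Length summaries
report exact min/max and the center of the heaviest histogram bin as the
mode (leftmost on ties) — a histogram-style estimator matching how such
values are reported, deliberately not a KDE. Radius histograms use
fixed-width bins anchored at the data minimum; peaks are strict local
maxima, optionally after a 3-bin moving average whose purpose is to kill
single-count jitter peaks in sparse tails (the reported counts stay raw).

## Synthetic scenes

The generator emulates the coordinate-level structure of a vesicle-surface
particle dataset: vesicle centers uniform in a box with a minimum
separation (default 60 nm) enforced by rejection; radii truncated-normal
N(20, 1.5²) on [15, 30] nm, the synaptic-vesicle scale; per-vesicle copy
numbers from a categorical law defaulting to {1: 0.63, 2: 0.26, 3: 0.08,
4: 0.03}; surface placement uniform (CSR) or von Mises–Fisher about a
random per-vesicle mean direction — the minimal one-parameter clustering
family on the sphere, giving a monotone power axis in κ. Axes are outward
radial, perturbed by a rotation of angle ~N(0, axis_noise) about a random
perpendicular direction; positions get the anchor offset plus isotropic
Gaussian noise. Detection bias accepts a particle with probability
(1−q)^β (default β = 2, a moderate suppression of beam-parallel views), or
per an empirical bias table; by default counts are preserved by redrawing
within the vesicle (so copy-number and spatial analyses can be tested
independently), with a `thin_counts` mode that models realistic count
loss. Membrane point clouds are sampled uniformly on each sphere with
radial noise. Identical config+seed gives byte-identical outputs.

What the generator does *not* emulate: image formation (no volumes, CTF,
or tilt geometry — the bias is a 1-D reweighting, exactly as the analyses
impose it), non-spherical vesicles, false-positive picks, or per-tomogram
heterogeneity of the bias. Passing tests therefore demonstrate correctness
of the geometry and statistics on well-specified input, not robustness to
segmentation or picking artifacts.

The proximity-scene generator places objects above a planar membrane grid
(1 nm spacing) at class-specific distances, by default normal laws with
means 150/190/228 nm (coated vesicles / baskets / synaptic vesicles) and
standard deviations 40/50/60 nm — spreads chosen so the class
distributions overlap substantially, as the real distributions do.

## Problem sizes used in the checks

The simulation-based checks run at the scale the analyses describe where
that scale is known — 320 selected vesicles with k = 2 for the randomness
test, 2000 replicate pairs for KS calibration, 200 vesicles for geometry
recovery, 500 seeds for coverage — and at a few hundred replicates for
power curves, where the effect sizes are large enough that sampling error
is negligible.

## Known limitations

- Vesicles carrying only particles with (near-)parallel axes cannot be
  fitted from particles; they fall back to the dataset prior.
- The compatibility graph uses single-linkage components; pathological
  geometries (two vesicles sharing a compatible particle pair through
  near-coincident centers) would merge. With the default thresholds and
  ≥60 nm center separation this does not occur in practice.
- The KS comparison assumes the null radius summarizes the selected
  vesicles; strongly heterogeneous radius mixtures should use the
  per-vesicle-radius null variant.
- Exact KS p-values are only computed for small samples by default; the
  asymptotic p at n ≈ 320 is accurate to a few parts in a hundred and
  slightly conservative.
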