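# vesimap

Spatial statistics for membrane proteins on synaptic-vesicle surfaces,
reconstructed from cryo-electron-tomography particle tables.

Cryo-ET of synapses yields, after subtomogram averaging, a table of picked
protein complexes (V-ATPases, clathrin-coated vesicles, clathrin baskets):
a 3-D position and a ZYZ Euler orientation per particle. The vesicles
themselves are not in the table — but a membrane protein's outward axis
points away from the vesicle center, so the vesicle geometry can be
recovered from the particles alone. `vesimap` turns such tables into
quantitative answers for questions like:

- How many V-ATPases does each vesicle carry, and does the copy number
  correlate with vesicle radius?
- Are the proton pumps placed at random on the vesicle surface, or do they
  cluster?
- Do clathrin baskets, coated vesicles, and synaptic vesicles sit at
  different distances from the cell membrane?

## The core model

Each particle *i* has position **p**ᵢ and outward unit axis **u**ᵢ. Its
membrane anchor is **a**ᵢ = **p**ᵢ − h **u**ᵢ (h = offset from the picked
reference to the membrane mid-plane), and the center of its vesicle lies a
radius R further inward: **c** = **a**ᵢ − R **u**ᵢ. For any pair the best
shared-center radius has the closed form

    R* = (aᵢ − aⱼ)·(uᵢ − uⱼ) / |uᵢ − uⱼ|²,

with residual center mismatch ("gap") zero exactly when a common center
exists. Pairs with a small gap, an admissible R*, and radially consistent
axes form a compatibility graph; connected components are vesicles, fitted
jointly by least squares of **a**ᵢ = **c** + R **u**ᵢ and refined against
nearby membrane segmentation points when available.

On each fitted sphere the separation of two particles is the geodesic
("spherical") distance d = R·arccos(**û**₁·**û**₂). Because the missing
wedge suppresses detection of particles whose axis is parallel to the
electron beam, the observed distance distribution is compared not to plain
uniformity but to complete spatial randomness *thinned by an empirical
orientation-bias model*: under isotropy q = |cos θ| (axis vs. beam) is
uniform on [0, 1], so the histogram of q over the dataset directly gives
per-orientation detection weights, which the null simulation imposes by
rejection sampling. Experimental and null distance distributions are
compared with a two-sample Kolmogorov–Smirnov test.

## Worked example

Simulate a ground-truthed scene (200 vesicles, radii ~ N(20, 1.5²) nm
truncated to [15, 30], 1–4 particles per vesicle), reconstruct the
vesicles, and test spatial randomness:

```sh
vesimap simulate --seed 7 --out-dir scene
vesimap fit --particles scene/particles.csv --out vesicles.csv
```

```
{
 "n_particles": 299,
 "n_vesicles": 200,
 "count_fractions": {"1": 0.68, "2": 0.185, "3": 0.095, "4": 0.04},
 "mean_count": 1.4949999999999999,
 "pearson_count_radius": {"r": -0.1236..., "p_value": 0.0811..., "n": 200}
}
```

All 299 particles were assigned; the mean copy number (1.49) reproduces the
generating law, and copy number is not significantly correlated with radius
at the 5% level. Single-particle vesicles in a scene without membrane
points carry a dataset-prior radius (flagged `radius_source=default_prior`,
excluded from radius-based selections); supply `--membranes` to measure
their radii instead.

```python
import vesimap as vm

particles = vm.read_particle_table("scene/particles.csv")
vesicles = vm.read_vesicle_table("vesicles.csv")
selected = vm.select_vesicles(vesicles, (19, 20), k=2)   # 19-20 nm, 2 copies
bias = vm.estimate_bias(particles)
ks, exp, null = vm.randomness_test(selected, particles, bias,
                                   n_null=2000, seed=1)
print(len(selected), exp.values.mean(), null.values.mean(), ks.D, ks.p_value)
```

```
selected vesicles: 18
experimental mean distance: 29.99 nm
null mean distance: 31.33 nm
KS D = 0.1518, p = 0.746
```

The experimental pairwise geodesic distances are statistically
indistinguishable from the bias-matched random null (p = 0.75): placement
on these simulated vesicles is random, as constructed.

The same library covers membrane-proximity comparisons
(`vesimap membdist`), annotator-consensus protein abundances
(`vesimap consensus`), radius histograms with peak detection
(`vesimap radii`), and an end-to-end YAML-configured pipeline
(`vesimap report`).

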