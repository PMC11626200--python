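"""Geodesic distance statistics and the bias-aware randomness test.

The question: are proton pumps placed at random on vesicle surfaces, or do
they cluster? Raw pairwise geodesic ("spherical") distances between
particles on a vesicle are not compared to a plain uniform null, because
cryo-ET particle picking under-detects particles whose axis is parallel to
the electron beam (the missing wedge). The null is therefore complete
spatial randomness on the sphere *thinned by an empirical orientation-bias
model* estimated from the dataset itself, and the experimental and null
distance distributions are compared with a two-sample Kolmogorov-Smirnov
test.

Under isotropy, q = |cos(theta)| between a radial particle axis and the
beam axis (tomogram z) is uniform on [0, 1]; the empirical histogram of q
is therefore directly proportional to the relative detection weight per
orientation bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateGeometryError
from .geometry import Vesicle
from .io import Particle

__all__ = [
    "BiasModel",
    "DistanceSample",
    "KSResult",
    "geodesic_distances",
    "select_vesicles",
    "estimate_bias",
    "simulate_null",
    "ks_two_sample",
    "randomness_test",
    "uniform_sphere",
]


@dataclass
class BiasModel:
    """Relative detection weight per |cos theta| bin (theta = axis vs beam).

    Weights are normalized so the best-detected bin has weight 1; bins
    partition [0, 1] without gaps.
    """

    bin_edges: np.ndarray
    weights: np.ndarray
    n_source: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.bin_edges) != len(self.weights) + 1:
            raise ConfigurationError("bin_edges must have len(weights)+1 entries")
        if not (np.isclose(self.bin_edges[0], 0.0) and np.isclose(self.bin_edges[-1], 1.0)):
            raise ConfigurationError("bias bins must cover [0, 1]")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ConfigurationError("bias bin edges must be increasing")
        if np.any(self.weights < 0) or np.any(self.weights > 1 + 1e-12):
            raise ConfigurationError("bias weights must lie in [0, 1]")
        if not np.isclose(self.weights.max(initial=0.0), 1.0):
            raise ConfigurationError("at least one bias weight must equal 1")

    def weight_at(self, q: np.ndarray) -> np.ndarray:
        """Detection weight for |cos theta| values (vectorized)."""
        q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
        idx = np.clip(np.searchsorted(self.bin_edges, q, side="right") - 1,
                      0, len(self.weights) - 1)
        return self.weights[idx]

    def mean_acceptance(self) -> float:
        """Integral of the weight over q (= expected acceptance under isotropy)."""
        return float(np.sum(self.weights * np.diff(self.bin_edges)))

    @classmethod
    def from_cosine_power(cls, beta: float, n_bins: int = 18) -> "BiasModel":
        """Binned version of the analytic weight (1 - q)^beta."""
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = (1.0 - mids) ** beta
        return cls(bin_edges=edges, weights=w / w.max(), n_source=0)


@dataclass
class DistanceSample:
    """Labeled scalar distances (nm) with provenance metadata."""

    values: np.ndarray
    label: str
    provenance: str  # "experimental" | "simulated"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov outcome."""

    D: float
    p_value: float
    n1: int
    n2: int
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("D must lie in [0, 1]")
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p must lie in [0, 1]")


def geodesic_distances(vesicle: Vesicle, particles: Sequence[Particle]) -> np.ndarray:
    """All pairwise great-circle distances d = R*arccos(u_i . u_j).

    Directions are taken from the fitted center to each member position;
    the dot product is clamped to [-1, 1] before arccos.
    """
    if len(particles) < 2:
        raise ValueError("geodesic distances need at least 2 member particles")
    vecs = np.array([p.position for p in particles]) - vesicle.center
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("member particle coincides with vesicle center")
    units = vecs / norms[:, None]
    iu, ju = np.triu_indices(len(particles), 1)
    dots = np.clip(np.einsum("ij,ij->i", units[iu], units[ju]), -1.0, 1.0)
    return vesicle.radius * np.arccos(dots)


def select_vesicles(
    vesicles: Sequence[Vesicle],
    radius_range: tuple[float, float],
    k: int,
    rule: str = "rounded",
) -> list[Vesicle]:
    """Vesicles with radius in range, exactly k members, and a fitted radius.

    rule="rounded" admits radii whose nearest-integer nm falls inside the
    range (matching reporting of radii as whole nm); rule="interval" uses
    closed-interval membership. Vesicles with radius_source="default_prior"
    are always excluded.
    """
    lo, hi = radius_range
    if lo > hi:
        raise ValueError(f"inverted radius range: {radius_range}")
    if rule == "rounded":
        in_range = lambda r: lo <= round(r) <= hi  # noqa: E731
    elif rule == "interval":
        in_range = lambda r: lo <= r <= hi  # noqa: E731
    else:
        raise ValueError(f"unknown radius rule: {rule!r}")
    return [v for v in vesicles
            if v.count == k and v.radius_source != "default_prior"
            and in_range(v.radius)]


def estimate_bias(
    particles_or_axes, n_bins: int = 18, alpha: float = 1.0
) -> BiasModel:
    """Empirical orientation-bias model from observed particle axes.

    Histograms q = |u_z| into n_bins equal-width bins over [0, 1]; because q
    is uniform under isotropy, raw counts are proportional to detection
    weight. Laplace smoothing (pseudo-count alpha) avoids zero-acceptance
    bins; weights are normalized to max 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    items = list(particles_or_axes)
    if not items:
        raise ValueError("cannot estimate bias from an empty particle set")
    if isinstance(items[0], Particle):
        axes = np.array([p.axis for p in items])
    else:
        axes = np.asarray(items, dtype=float).reshape(-1, 3)
    q = np.abs(axes[:, 2])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(q, bins=edges)
    smoothed = counts + alpha
    return BiasModel(bin_edges=edges, weights=smoothed / smoothed.max(),
                     n_source=len(axes))


def uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on S^2."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _biased_directions(rng: np.random.Generator, n: int,
                       bias: BiasModel | None) -> np.ndarray:
    """n directions, uniform then thinned by the bias acceptance weight."""
    if bias is None:
        return uniform_sphere(rng, n)
    if np.all(bias.weights == 0):
        raise ConfigurationError("bias model with all-zero weights accepts nothing")
    accepted = []
    need = n
    # batch rejection sampling; expected batches ~ 1/mean_acceptance
    batch = max(256, int(1.5 * need / max(bias.mean_acceptance(), 1e-3)))
    while need > 0:
        cand = uniform_sphere(rng, batch)
        keep = rng.random(batch) < bias.weight_at(np.abs(cand[:, 2]))
        got = cand[keep]
        accepted.append(got[:need])
        need -= min(need, len(got))
    return np.vstack(accepted)


def simulate_null(
    radius: float | np.ndarray,
    n_vesicles: int,
    k: int,
    bias: BiasModel | None = None,
    seed: int | np.random.Generator = 0,
) -> DistanceSample:
    """Pairwise geodesic distances under bias-thinned spatial randomness.

    Per vesicle, k directions are drawn uniformly on the sphere and thinned
    by rejection with acceptance probability weight(|u_z|), redrawing until
    k are accepted (per-vesicle counts preserved); all k(k-1)/2 pairwise
    distances per vesicle are returned. `radius` may be a scalar (single
    radius for the whole null) or an array of per-vesicle radii.
    """
    if n_vesicles < 1 or k < 2:
        raise ValueError("need n_vesicles >= 1 and k >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radii = np.broadcast_to(np.asarray(radius, dtype=float), (n_vesicles,))
    dirs = _biased_directions(rng, n_vesicles * k, bias).reshape(n_vesicles, k, 3)
    iu, ju = np.triu_indices(k, 1)
    dots = np.clip(np.einsum("vid,vid->vi", dirs[:, iu], dirs[:, ju]), -1.0, 1.0)
    dists = (radii[:, None] * np.arccos(dots)).ravel()
    return DistanceSample(
        values=dists, label="null", provenance="simulated",
        metadata={"radius": np.unique(radii).tolist() if np.ptp(radii) else float(radii[0]),
                  "k": k, "n_vesicles": n_vesicles,
                  "seed": None if isinstance(seed, np.random.Generator) else int(seed),
                  "bias": "none" if bias is None else "model"},
    )


def ks_two_sample(x, y, mode: str = "auto") -> KSResult:
    """Two-sample KS test: D = sup |F1 - F2| over the pooled sample.

    mode="exact" enumerates the exact null distribution (feasible for small
    samples); "asymptotic" uses the Kolmogorov limit with effective size
    n1*n2/(n1+n2); "auto" switches to exact for n1, n2 <= 10. Ties are
    handled by evaluating D at the pooled jump points.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    if mode == "auto":
        method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymp"
    elif mode == "exact":
        method = "exact"
    elif mode == "asymptotic":
        method = "asymp"
    else:
        raise ValueError(f"unknown KS mode: {mode!r}")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return KSResult(D=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                    n1=len(x), n2=len(y),
                    mode="exact" if method == "exact" else "asymptotic")


def randomness_test(
    vesicles: Sequence[Vesicle],
    particles: Sequence[Particle],
    bias: BiasModel | None,
    n_null: int = 2000,
    seed: int | np.random.Generator = 0,
    radius_mode: str = "mean",
    ks_mode: str = "auto",
) -> tuple[KSResult, DistanceSample, DistanceSample]:
    """Bias-aware spatial-randomness test for particles on selected vesicles.

    Computes the experimental pairwise geodesic distances over the selected
    vesicles (which must share the same member count k), simulates the
    bias-matched null, and compares the two distance distributions with a
    two-sample KS test. radius_mode="mean" simulates the null at the mean
    selected radius; "per_vesicle" cycles through the selected radii.
    """
    vesicles = list(vesicles)
    if len(vesicles) < 2:
        raise ValueError("randomness test needs at least 2 selected vesicles")
    ks_counts = {v.count for v in vesicles}
    if len(ks_counts) != 1:
        raise ValueError(f"selected vesicles must share one member count, got {ks_counts}")
    k = ks_counts.pop()
    by_id = {p.particle_id: p for p in particles}
    exp_values = np.concatenate([
        geodesic_distances(v, [by_id[pid] for pid in v.member_particle_ids])
        for v in vesicles
    ])
    radii = np.array([v.radius for v in vesicles])
    exp = DistanceSample(
        values=exp_values, label="experimental", provenance="experimental",
        metadata={"radius": float(radii.mean()), "k": k, "n_vesicles": len(vesicles)},
    )
    if radius_mode == "mean":
        null_radius = float(radii.mean())
    elif radius_mode == "per_vesicle":
        null_radius = np.resize(radii, n_null)
    else:
        raise ValueError(f"unknown radius_mode: {radius_mode!r}")
    null = simulate_null(null_radius, n_null, k, bias=bias, seed=seed)
    ks = ks_two_sample(exp.values, null.values, mode=ks_mode)
    return ks, exp, null
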