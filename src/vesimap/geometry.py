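"""Vesicle reconstruction from oriented particles.

A membrane protein picked on a vesicle surface sits at its anchor point
``a = p - h*u`` (position minus an offset along its outward axis) and the
vesicle center lies a radius R further inward along the same axis:
``c = a - R*u``. Two particles on the same vesicle therefore share a center,
which gives a one-parameter consistency test per particle pair
(:func:`pair_radius`). Pairs passing the test form a compatibility graph
whose connected components are vesicles; each component's center and radius
come from a joint linear least-squares fit of ``a_i = c + R*u_i``, refined
against nearby membrane points when available. Singletons fall back to a
membrane-constrained fit along their axis ray, or to a dataset prior.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .errors import DegenerateGeometryError, UndefinedCorrelationError
from .io import MembraneSurface, Particle

__all__ = [
    "Vesicle",
    "GeometryParams",
    "anchor_point",
    "pair_radius",
    "fit_sphere",
    "assign_vesicles",
    "count_distribution",
    "pearson_count_radius",
]

logger = logging.getLogger(__name__)

#: axes closer than this to parallel carry no center information
_PARALLEL_TOL = 1e-12


@dataclass
class Vesicle:
    """A fitted sphere with its member particles.

    ``radius_source`` records provenance: "joint_fit" (multi-particle axis
    fit, optionally with membrane points), "membrane_fit" (singleton fitted
    to membrane points along its axis ray), "default_prior" (dataset prior),
    or "ground_truth" (synthetic scenes).
    """

    vesicle_id: str
    tomogram_id: str
    center: np.ndarray
    radius: float
    member_particle_ids: list[str]
    radius_source: str
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"vesicle {self.vesicle_id}: radius must be positive")
        if self.fit_rms < 0:
            raise ValueError(f"vesicle {self.vesicle_id}: fit_rms must be >= 0")

    @property
    def count(self) -> int:
        return len(self.member_particle_ids)


@dataclass
class GeometryParams:
    """Tunable knobs of the reconstruction, all in nm / degrees.

    anchor_offset_h
        Distance from the particle reference position to the membrane
        mid-plane along the axis; 0 assumes positions are already anchors.
    center_merge_eps
        Maximum center mismatch (gap) for two particles to be compatible;
        default 5 nm, about half the smallest vesicle radius analyzed.
    radius_bounds
        Admissible sphere radii, spanning synaptic-vesicle to
        clathrin-coated-vesicle scales.
    axis_consistency_max_deg
        Maximum angle between a particle axis and the outward radial
        direction of the candidate sphere.
    default_radius
        Last-resort prior radius when a singleton has no membrane support
        and the dataset has no multi-particle vesicles.
    membrane_snap_eps
        Membrane points within this distance of the fitted sphere surface
        join the refinement fit.
    """

    anchor_offset_h: float = 0.0
    center_merge_eps: float = 5.0
    radius_bounds: tuple[float, float] = (12.0, 60.0)
    axis_consistency_max_deg: float = 15.0
    default_radius: float = 20.0
    membrane_snap_eps: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.radius_bounds
        if not lo < hi:
            raise ValueError("radius_bounds must satisfy R_min < R_max")
        if self.center_merge_eps <= 0:
            raise ValueError("center_merge_eps must be positive")


def anchor_point(particle: Particle | np.ndarray, h: float,
                 axis: np.ndarray | None = None) -> np.ndarray:
    """Membrane anchor a = p - h*u for a particle (or a raw position+axis)."""
    if isinstance(particle, Particle):
        return particle.position - h * particle.axis
    return np.asarray(particle, dtype=float) - h * np.asarray(axis, dtype=float)


def pair_radius(a_i, u_i, a_j, u_j) -> tuple[float, float]:
    """Shared-center radius for two anchored, oriented particles.

    Minimizes |(a_i - R u_i) - (a_j - R u_j)| over R; the minimizer is
    R* = (a_i - a_j).(u_i - u_j) / |u_i - u_j|^2 and the minimized distance
    (gap) is 0 exactly when the two implied centers coincide.
    """
    a_i, u_i = np.asarray(a_i, float), np.asarray(u_i, float)
    a_j, u_j = np.asarray(a_j, float), np.asarray(u_j, float)
    du = u_i - u_j
    n2 = float(du @ du)
    if n2 < _PARALLEL_TOL:
        raise DegenerateGeometryError("parallel axes give no finite shared-center radius")
    r_star = float((a_i - a_j) @ du) / n2
    gap = float(np.linalg.norm((a_i - r_star * u_i) - (a_j - r_star * u_j)))
    return r_star, gap


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through a point cloud.

    Algebraic initialization (linear LS on the |x|^2 expansion) followed by
    Gauss-Newton refinement of orthogonal radial residuals (<=50 steps,
    tol 1e-9 nm). Exact on noiseless spherical data.

    Returns (center, radius, rms radial residual).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {n}")
    design = np.column_stack([2.0 * pts, np.ones(n)])
    rhs = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("rank-deficient sphere fit (coplanar points?)")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit gave non-positive radius")
    radius = float(np.sqrt(r2))
    # Gauss-Newton on residuals r_i = |p_i - c| - R over (c, R)
    for _ in range(50):
        diff = pts - center
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist < 1e-12):
            break
        res = dist - radius
        jac = np.column_stack([-diff / dist[:, None], -np.ones(n)])
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        center = center + step[:3]
        radius = radius + step[3]
        if np.linalg.norm(step) < 1e-9:
            break
    dist = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return center, float(radius), rms


def _fit_center_radius_from_axes(anchors: np.ndarray, axes: np.ndarray):
    """Joint linear LS for (c, R) from a_i = c + R*u_i (3 eqs per particle).

    Exact on noiseless data whenever two axes differ. Returns
    (center, radius, rms radial residual) or None when rank-deficient
    (all axes parallel).
    """
    k = len(anchors)
    design = np.zeros((3 * k, 4))
    design[:, :3] = np.tile(np.eye(3), (k, 1))
    design[:, 3] = axes.reshape(-1)
    rhs = anchors.reshape(-1)
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        return None
    center, radius = sol[:3], float(sol[3])
    if radius <= 0:
        return None
    dist = np.linalg.norm(anchors - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return center, radius, rms


def _compatibility_edges(anchors, axes, params):
    """Vectorized pair test: yields (i, j) for compatible particle pairs."""
    k = len(anchors)
    iu, ju = np.triu_indices(k, 1)
    du = axes[iu] - axes[ju]
    n2 = np.einsum("ij,ij->i", du, du)
    ok = n2 >= _PARALLEL_TOL
    r_star = np.zeros(len(iu))
    da = anchors[iu] - anchors[ju]
    r_star[ok] = np.einsum("ij,ij->i", da[ok], du[ok]) / n2[ok]
    lo, hi = params.radius_bounds
    ok &= (r_star >= lo) & (r_star <= hi)
    ci = anchors[iu] - r_star[:, None] * axes[iu]
    cj = anchors[ju] - r_star[:, None] * axes[ju]
    gap = np.linalg.norm(ci - cj, axis=1)
    ok &= gap < params.center_merge_eps
    # both axes must point along the outward radial direction of the
    # candidate sphere (center = midpoint of the two implied centers)
    cmid = 0.5 * (ci + cj)
    cos_max = np.cos(np.deg2rad(params.axis_consistency_max_deg))
    for idx, vec in ((iu, anchors[iu]), (ju, anchors[ju])):
        radial = vec - cmid
        nrm = np.linalg.norm(radial, axis=1)
        good = nrm > 1e-12
        cosang = np.full(len(iu), 1.0)
        cosang[good] = np.einsum("ij,ij->i", radial[good], axes[idx][good]) / nrm[good]
        ok &= cosang >= cos_max
    return list(zip(iu[ok].tolist(), ju[ok].tolist()))


def _membrane_points_near(membrane, center, radius, eps):
    if membrane is None:
        return np.empty((0, 3))
    dist = np.linalg.norm(membrane.points - center, axis=1)
    return membrane.points[np.abs(dist - radius) < eps]


def _singleton_membrane_fit(anchor, axis, membrane, params):
    """Sphere constrained to center on the particle's inward ray.

    Minimizes the mean squared radial residual of membrane points within
    2*R_max of the anchor over R in radius_bounds.
    """
    lo, hi = params.radius_bounds
    near = membrane.points[
        np.linalg.norm(membrane.points - anchor, axis=1) < 2.0 * hi]
    if len(near) < 4:
        return None
    # each point implies a closed-form radius: |m - c(R)| = R with
    # c(R) = a - R*u gives R = -|d|^2 / (2 d.u), d = m - a. The median of
    # in-bounds implied radii is robust to membrane points of neighboring
    # vesicles caught by the search radius.
    d = near - anchor
    denom = 2.0 * (d @ axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = -np.einsum("ij,ij->i", d, d) / denom
    valid = np.isfinite(implied) & (implied >= lo) & (implied <= hi)
    if valid.sum() < 4:
        return None
    # mode-seek: the vesicle's own surface points concentrate sharply
    # around the true radius while stray points scatter broadly
    counts, edges = np.histogram(implied[valid], bins=np.arange(lo, hi + 1.0))
    best = int(np.argmax(counts))
    mode_center = 0.5 * (edges[best] + edges[best + 1])
    core = implied[valid]
    core = core[np.abs(core - mode_center) <= 2.0]
    if len(core) < 4:
        return None
    radius = float(np.median(core))

    def fit_once(pts):
        def cost(r):
            c = anchor - r * axis
            return float(np.mean((np.linalg.norm(pts - c, axis=1) - r) ** 2))

        res = optimize.minimize_scalar(
            cost, bounds=(max(lo, radius - 5.0), min(hi, radius + 5.0)),
            method="bounded", options={"xatol": 1e-10})
        return float(res.x), float(np.sqrt(cost(float(res.x))))

    center = anchor - radius * axis
    inliers = near[np.abs(np.linalg.norm(near - center, axis=1) - radius)
                   < params.membrane_snap_eps]
    if len(inliers) < 4:
        return None
    radius, rms = fit_once(inliers)
    center = anchor - radius * axis
    if rms > params.membrane_snap_eps:
        return None
    return center, radius, rms


def assign_vesicles(
    particles: list[Particle],
    membranes: list[MembraneSurface] | MembraneSurface | None = None,
    params: GeometryParams | None = None,
) -> list[Vesicle]:
    """Partition particles into vesicles and fit each vesicle's sphere.

    Every input particle is assigned to exactly one vesicle. Grouping is by
    tomogram; ordering is deterministic (particles sorted by id).
    """
    params = params or GeometryParams()
    if isinstance(membranes, MembraneSurface):
        membranes = [membranes]
    mem_by_tomo = {m.tomogram_id: m for m in (membranes or [])}
    by_tomo: dict[str, list[Particle]] = defaultdict(list)
    for p in particles:
        by_tomo[p.tomogram_id].append(p)

    vesicles: list[Vesicle] = []
    for tomo in sorted(by_tomo):
        group = sorted(by_tomo[tomo], key=lambda p: p.particle_id)
        membrane = mem_by_tomo.get(tomo)
        anchors = np.array([anchor_point(p, params.anchor_offset_h) for p in group])
        axes = np.array([p.axis for p in group])

        graph = nx.Graph()
        graph.add_nodes_from(range(len(group)))
        graph.add_edges_from(_compatibility_edges(anchors, axes, params))
        components = [sorted(c) for c in nx.connected_components(graph)]
        components.sort(key=lambda c: c[0])

        fitted, singletons, degenerate = [], [], []
        for comp in components:
            if len(comp) == 1:
                singletons.append(comp)
                continue
            fit = _fit_center_radius_from_axes(anchors[comp], axes[comp])
            if fit is None:
                degenerate.append(comp)
                continue
            center, radius, rms = fit
            # two snap-and-refit rounds: the second re-selects membrane
            # points against the refined sphere, recovering from a poor
            # axis-only initialization
            for _ in range(2):
                near = _membrane_points_near(membrane, center, radius,
                                             params.membrane_snap_eps)
                if len(near) == 0 or len(comp) + len(near) < 4:
                    break
                try:
                    center, radius, rms = fit_sphere(
                        np.vstack([anchors[comp], near]))
                except DegenerateGeometryError:
                    break
            fitted.append((comp, center, radius, rms, "joint_fit"))

        # dataset prior: mode of multi-particle radii (0.5 nm resolution)
        if fitted:
            multi_r = np.array([f[2] for f in fitted])
            prior = float(stats.mode(np.round(multi_r * 2) / 2, keepdims=False).mode)
        else:
            prior = params.default_radius

        for comp in singletons:
            i = comp[0]
            fit = None
            if membrane is not None:
                fit = _singleton_membrane_fit(anchors[i], axes[i], membrane, params)
            if fit is not None:
                fitted.append((comp, *fit, "membrane_fit"))
            else:
                center = anchors[i] - prior * axes[i]
                fitted.append((comp, center, prior, 0.0, "default_prior"))
        for comp in degenerate:
            logger.warning("tomogram %s: component of %d parallel-axis particles; "
                           "using prior radius", tomo, len(comp))
            center = np.mean(anchors[comp] - prior * axes[comp], axis=0)
            fitted.append((comp, center, prior, 0.0, "default_prior"))

        fitted.sort(key=lambda f: f[0][0])
        for idx, (comp, center, radius, rms, source) in enumerate(fitted):
            vesicles.append(Vesicle(
                vesicle_id=f"{tomo}:v{len(vesicles):05d}",
                tomogram_id=tomo, center=center, radius=radius,
                member_particle_ids=[group[i].particle_id for i in comp],
                radius_source=source, fit_rms=rms,
            ))

    assert sum(v.count for v in vesicles) == len(particles), \
        "particle conservation violated"
    return vesicles


def count_distribution(vesicles: list[Vesicle]) -> tuple[dict[int, float], float]:
    """Copy-number distribution: fraction of vesicles with k members, and mean."""
    if not vesicles:
        raise ValueError("count_distribution requires at least one vesicle")
    counts = Counter(v.count for v in vesicles)
    n = len(vesicles)
    fractions = {k: counts[k] / n for k in sorted(counts)}
    mean = sum(k * f for k, f in fractions.items())
    return fractions, mean


def pearson_count_radius(vesicles: list[Vesicle]) -> tuple[float, float, int]:
    """Pearson correlation between per-vesicle copy number and radius."""
    if len(vesicles) < 3:
        raise ValueError("need at least 3 vesicles for a correlation")
    counts = np.array([v.count for v in vesicles], dtype=float)
    radii = np.array([v.radius for v in vesicles], dtype=float)
    if np.ptp(counts) == 0 or np.ptp(radii) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for constant counts or radii")
    r, p = stats.pearsonr(counts, radii)
    return float(r), float(p), len(vesicles)
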