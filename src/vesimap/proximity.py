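"""Distances from object centers to the cell membrane, compared by class.

Clathrin baskets, clathrin-coated vesicles and synaptic vesicles occupy
different positions relative to the plasma membrane; this module measures
each object's minimum distance to a membrane surface (point cloud or
triangle mesh) and tests whether the per-class distance distributions
differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .io import MembraneSurface
from .sphere_stats import ks_two_sample

__all__ = [
    "ProximityRecord",
    "ProximityComparison",
    "distance_to_membrane",
    "distances_to_membrane",
    "compare_proximity",
]


@dataclass
class ProximityRecord:
    """One object's distance (nm) to the reference membrane."""

    object_id: str
    class_label: str
    tomogram_id: str
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class ProximityComparison:
    """Per-class summary statistics and the pairwise p-value matrix."""

    class_stats: pd.DataFrame  # index: class; columns: mean, median, n
    p_matrix: pd.DataFrame     # symmetric, diagonal 1
    test: str
    adjust: str | None = None


def distances_to_membrane(points: np.ndarray, surface: MembraneSurface) -> np.ndarray:
    """Minimum distance from each query point to the membrane surface.

    Point-cloud mode: nearest surface point (KD-tree). Mesh mode (surface
    has faces): exact minimum point-triangle distance.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(points)):
        raise ValueError("query points must be finite")
    if surface.points is None or len(surface.points) == 0:
        raise ValueError("membrane surface is empty")
    if surface.faces is not None and len(surface.faces) > 0:
        import trimesh

        mesh = trimesh.Trimesh(vertices=surface.points, faces=surface.faces,
                               process=False)
        # exhaustive point-triangle distance; exact and dependency-light
        _, dist, _ = trimesh.proximity.closest_point_naive(mesh, points)
        return np.asarray(dist, dtype=float)
    tree = cKDTree(surface.points)
    dist, _ = tree.query(points)
    return np.asarray(dist, dtype=float)


def distance_to_membrane(point, surface: MembraneSurface) -> float:
    """Minimum distance (nm) from a single point to the membrane."""
    return float(distances_to_membrane(np.asarray(point, float)[None, :], surface)[0])


def compare_proximity(
    records: Sequence[ProximityRecord],
    test: str = "ks",
    adjust: str | None = None,
) -> ProximityComparison:
    """Per-class distance summaries and all pairwise two-sided tests.

    test="ks" (two-sample Kolmogorov-Smirnov, the default) or
    test="mann_whitney". adjust="holm" applies Holm step-down correction to
    the off-diagonal p-values; default is unadjusted.
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.class_label, []).append(r.distance)
    if len(groups) < 2:
        raise ValueError("need at least 2 classes to compare")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"class {name!r} has fewer than 2 records")
    classes = sorted(groups)
    stats_rows = {
        name: {"mean": float(np.mean(groups[name])),
               "median": float(np.median(groups[name])),
               "n": len(groups[name])}
        for name in classes
    }
    p = pd.DataFrame(np.eye(len(classes)) * 0 + 1.0, index=classes, columns=classes)
    pairs, raw = [], []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            if test == "ks":
                pv = ks_two_sample(groups[a], groups[b], mode="asymptotic").p_value
            elif test == "mann_whitney":
                pv = float(stats.mannwhitneyu(groups[a], groups[b],
                                              alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test: {test!r}")
            pairs.append((a, b))
            raw.append(pv)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        raw = multipletests(raw, method="holm")[1].tolist()
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    for (a, b), pv in zip(pairs, raw):
        p.loc[a, b] = p.loc[b, a] = pv
    return ProximityComparison(
        class_stats=pd.DataFrame(stats_rows).T[["mean", "median", "n"]],
        p_matrix=p, test=test, adjust=adjust,
    )
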