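"""Annotator-consensus abundances, protrusion-length summaries, radius histograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError
from .io import AnnotationTable

__all__ = [
    "ClassAbundance",
    "RadiusHistogram",
    "aggregate_annotations",
    "summarize_lengths",
    "radius_histogram",
]


@dataclass
class ClassAbundance:
    """Consensus abundance of one structural class across annotated vesicles.

    per_vesicle_means averages the annotators per vesicle; overall_mean then
    averages those over vesicles. Two presence rules are reported side by
    side: presence_fraction uses the per-vesicle annotator mean against a
    threshold (majority-of-annotators evidence), presence_fraction_any
    counts a vesicle as positive when any single annotator saw >= 1.
    """

    class_name: str
    per_vesicle_means: np.ndarray
    overall_mean: float
    presence_fraction: float
    presence_fraction_any: float
    max_count: int


@dataclass
class RadiusHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: list[float]  # bin-center nm values of local maxima


def aggregate_annotations(
    table: AnnotationTable, presence_threshold: float = 0.5
) -> list[ClassAbundance]:
    """Per-class consensus: mean over annotators per vesicle, then over vesicles."""
    counts = table.counts
    if counts.ndim != 3 or counts.shape[2] != len(table.class_names):
        raise FormatError("annotation tensor shape does not match class names")
    n_annot, n_vesicles, _ = counts.shape
    if n_annot < 1 or n_vesicles < 1:
        raise FormatError("need at least one annotator and one vesicle")
    out = []
    for c, name in enumerate(table.class_names):
        per_vesicle = counts[:, :, c].mean(axis=0)
        out.append(ClassAbundance(
            class_name=name,
            per_vesicle_means=per_vesicle,
            overall_mean=float(per_vesicle.mean()),
            presence_fraction=float(np.mean(per_vesicle >= presence_threshold)),
            presence_fraction_any=float(np.mean(counts[:, :, c].max(axis=0) >= 1)),
            max_count=int(counts[:, :, c].max()),
        ))
    return out


def summarize_lengths(lengths, bin_width: float) -> tuple[float, float, float]:
    """(min, max, mode) of a length sample; mode = highest-bin center.

    Bins are bin_width wide anchored at the minimum; ties go to the leftmost
    bin, matching histogram-style reporting of a most-abundant value.
    """
    lengths = np.asarray(lengths, dtype=float).ravel()
    if len(lengths) == 0:
        raise ValueError("empty length sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(lengths.min()), float(lengths.max())
    edges = _anchored_edges(lo, hi, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    best = int(np.argmax(counts))  # argmax takes the leftmost maximum
    mode = float(0.5 * (edges[best] + edges[best + 1]))
    return lo, hi, mode


def _anchored_edges(lo: float, hi: float, width: float) -> np.ndarray:
    n_bins = max(1, int(np.ceil((hi - lo) / width))) if hi > lo else 1
    edges = lo + width * np.arange(n_bins + 1)
    if edges[-1] < hi:  # guard against float rounding at the top edge
        edges = np.append(edges, edges[-1] + width)
    return edges


def radius_histogram(radii, bin_size: float, smooth: bool = False) -> RadiusHistogram:
    """Fixed-width histogram of radii with strict-local-maximum peak detection.

    Bins are anchored at the data minimum. With smooth=True a 3-bin moving
    average is applied before peak detection (the reported counts stay raw).
    A bin is a peak when strictly greater than both neighbors; boundary bins
    need only beat their single neighbor.
    """
    radii = np.asarray(radii, dtype=float).ravel()
    if len(radii) == 0:
        raise ValueError("empty radius sample")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    edges = _anchored_edges(float(radii.min()), float(radii.max()), bin_size)
    counts, _ = np.histogram(radii, bins=edges)
    profile = counts.astype(float)
    if smooth and len(profile) >= 3:
        profile = np.convolve(profile, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = []
    for i in range(len(profile)):
        left_ok = i == 0 or profile[i] > profile[i - 1]
        right_ok = i == len(profile) - 1 or profile[i] > profile[i + 1]
        if left_ok and right_ok and profile[i] > 0:
            peaks.append(float(centers[i]))
    return RadiusHistogram(bin_edges=edges, counts=counts, peaks=peaks)
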