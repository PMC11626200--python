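"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from vesimap.geometry import GeometryParams, _fit_center_radius_from_axes


def _partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_partition(anchors, axes, params: GeometryParams,
                          rms_tol: float = 1e-6):
    """Exhaustive minimum-block partition oracle for small particle sets.

    A block of >= 2 particles is feasible when the joint linear fit of
    a_i = c + R*u_i exists, its radial rms is <= rms_tol and R lies inside
    radius_bounds; singletons are always feasible. Among feasible
    partitions the oracle returns the one with fewest blocks, breaking
    ties by total rms. Independent of the production compatibility-graph
    path.
    """
    anchors = np.asarray(anchors, float)
    axes = np.asarray(axes, float)
    lo, hi = params.radius_bounds
    n = len(anchors)
    best = None
    for part in _partitions(range(n)):
        total_rms = 0.0
        feasible = True
        for block in part:
            if len(block) == 1:
                continue
            fit = _fit_center_radius_from_axes(anchors[block], axes[block])
            if fit is None:
                feasible = False
                break
            _, radius, rms = fit
            if rms > rms_tol or not lo <= radius <= hi:
                feasible = False
                break
            total_rms += rms
        if not feasible:
            continue
        key = (len(part), total_rms)
        if best is None or key < best[0]:
            best = (key, part)
    assert best is not None, "no feasible partition found"
    return sorted(tuple(sorted(block)) for block in best[1])


def ks_exact_p_enumeration(x, y):
    """Exact two-sample KS p by full enumeration over pooled assignments.

    P(D >= d_obs) over all C(n1+n2, n1) ways to split the pooled sample,
    assuming exchangeability. Brute force; feasible for n1+n2 <= ~16.
    """
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    grid = np.unique(pooled)

    def d_stat(a, b):
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    d_obs = d_stat(x, y)
    total = 0
    hits = 0
    idx = range(n1 + n2)
    for chosen in itertools.combinations(idx, n1):
        mask = np.zeros(n1 + n2, bool)
        mask[list(chosen)] = True
        total += 1
        if d_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def membership_accuracy(vesicles, truth):
    """Fraction of particles whose reconstructed co-members match truth."""
    true_members: dict[str, set] = {}
    for pid, vid in truth.particle_to_vesicle.items():
        true_members.setdefault(vid, set()).add(pid)
    n_total = sum(len(m) for m in true_members.values())
    n_ok = 0
    for v in vesicles:
        ids = set(v.member_particle_ids)
        tv = truth.particle_to_vesicle[v.member_particle_ids[0]]
        if ids == true_members[tv]:
            n_ok += len(ids)
    return n_ok / n_total


def radius_errors(vesicles, truth):
    """Per-vesicle fitted-radius minus true-radius (majority-vote matching)."""
    true_r = dict(zip(truth.vesicle_ids, truth.radii))
    errs = []
    for v in vesicles:
        votes = [truth.particle_to_vesicle[p] for p in v.member_particle_ids]
        tv = max(set(votes), key=votes.count)
        errs.append(v.radius - true_r[tv])
    return np.asarray(errs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
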