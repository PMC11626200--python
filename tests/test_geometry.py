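"""Vesicle reconstruction: anchors, pair radii, sphere fits, assignment."""

import numpy as np
import pytest

from conftest import brute_force_partition, membership_accuracy

from vesimap import (DegenerateGeometryError, GeometryParams,
                     UndefinedCorrelationError, anchor_point, assign_vesicles,
                     count_distribution, fit_sphere, pair_radius,
                     pearson_count_radius, generate_scene, SceneConfig)
from vesimap.io import Particle
from vesimap.geometry import Vesicle


def _make_vesicle(count, radius, vid="v"):
    return Vesicle(vesicle_id=vid, tomogram_id="t", center=np.zeros(3),
                   radius=radius, member_particle_ids=[f"{vid}_p{i}" for i in range(count)],
                   radius_source="joint_fit")


class TestAnchorPoint:
    @pytest.mark.parametrize("p,u,h,expected", [
        ((0, 0, 24), (0, 0, 1), 4.0, (0, 0, 20)),
        ((1, 2, 3), (0, 0, 1), 0.0, (1, 2, 3)),
        ((3, 4, 0), (0.6, 0.8, 0), 5.0, (0, 0, 0)),
    ])
    def test_offset_along_axis(self, p, u, h, expected):
        got = anchor_point(np.array(p, float), h, axis=np.array(u, float))
        assert np.allclose(got, expected)


class TestPairRadius:
    def test_antipodal_pair_shares_center_at_origin(self):
        r, gap = pair_radius([20, 0, 0], [1, 0, 0], [-20, 0, 0], [-1, 0, 0])
        assert r == pytest.approx(20.0) and gap == pytest.approx(0.0)

    def test_orthogonal_pair(self):
        r, gap = pair_radius([20, 0, 0], [1, 0, 0], [0, 20, 0], [0, 1, 0])
        assert r == pytest.approx(20.0) and gap == pytest.approx(0.0)

    def test_parallel_axes_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            pair_radius([0, 0, 0], [0, 0, 1], [5, 0, 0], [0, 0, 1])


class TestFitSphere:
    def test_exact_on_octahedral_points(self):
        pts = np.array([[20, 0, 0], [-20, 0, 0], [0, 20, 0], [0, -20, 0],
                        [0, 0, 20]], float)
        center, radius, rms = fit_sphere(pts)
        assert np.allclose(center, 0, atol=1e-9)
        assert radius == pytest.approx(20.0, abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_sphere(self, rng):
        d = rng.standard_normal((100, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        center, radius, _ = fit_sphere(np.array([5.0, -3.0, 7.0]) + 22.0 * d)
        assert np.allclose(center, [5, -3, 7], atol=1e-6)
        assert radius == pytest.approx(22.0, abs=1e-6)

    def test_three_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.eye(3) * 20)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        d = rng.standard_normal((50, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = np.array([1.0, 2.0, 3.0]) + 18.0 * d + rng.normal(0, 0.1, (50, 3))
        c0, r0, _ = fit_sphere(pts)
        rot = Rotation.from_rotvec([0.3, -0.5, 1.1]).as_matrix()
        shift = np.array([100.0, -40.0, 7.0])
        c1, r1, _ = fit_sphere(pts @ rot.T + shift)
        assert r1 == pytest.approx(r0, rel=1e-9)
        assert np.allclose(c1, rot @ c0 + shift, atol=1e-6)


class TestAssignVesicles:
    def test_empty_input_gives_empty_output(self):
        assert assign_vesicles([]) == []

    def test_two_separated_vesicles_match_partition_oracle(self):
        cfg = SceneConfig(n_vesicles=2, seed=7, count_law={3: 1.0},
                          min_separation_nm=200.0, box_size_nm=500.0)
        particles, _, truth = generate_scene(cfg)
        params = GeometryParams()
        vesicles = assign_vesicles(particles, params=params)
        assert len(vesicles) == 2
        assert membership_accuracy(vesicles, truth) == 1.0
        order = sorted(particles, key=lambda p: p.particle_id)
        oracle = brute_force_partition(
            np.array([p.position for p in order]),
            np.array([p.axis for p in order]), params)
        ids = [p.particle_id for p in order]
        got = sorted(tuple(sorted(ids.index(pid) for pid in v.member_particle_ids))
                     for v in vesicles)
        assert got == oracle

    def test_singleton_with_membrane_recovers_exact_radius(self):
        cfg = SceneConfig(n_vesicles=1, seed=11, count_law={1: 1.0},
                          membrane_points_per_vesicle=200)
        particles, membranes, truth = generate_scene(cfg)
        (v,) = assign_vesicles(particles, membranes)
        assert v.radius_source == "membrane_fit"
        assert v.radius == pytest.approx(truth.radii[0], abs=1e-6)

    def test_singleton_without_membrane_gets_prior(self):
        p = Particle(particle_id="p0", tomogram_id="t0",
                     position=np.array([0.0, 0.0, 24.0]), axis=np.array([0.0, 0.0, 1.0]))
        (v,) = assign_vesicles([p], params=GeometryParams(default_radius=21.0))
        assert v.radius_source == "default_prior"
        assert v.radius == pytest.approx(21.0)
        assert np.allclose(v.center, [0, 0, 3.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_particle_conservation(self, seed):
        cfg = SceneConfig(n_vesicles=40, seed=seed, axis_noise_deg=3,
                          position_noise_nm=0.5)
        particles, _, _ = generate_scene(cfg)
        vesicles = assign_vesicles(particles)
        assert sum(v.count for v in vesicles) == len(particles)
        all_ids = sorted(pid for v in vesicles for pid in v.member_particle_ids)
        assert all_ids == sorted(p.particle_id for p in particles)


class TestCountDistribution:
    def test_small_example(self):
        vesicles = [_make_vesicle(1, 20, "a"), _make_vesicle(1, 20, "b"),
                    _make_vesicle(2, 20, "c")]
        fractions, mean = count_distribution(vesicles)
        assert fractions == {1: pytest.approx(2 / 3), 2: pytest.approx(1 / 3)}
        assert mean == pytest.approx(4 / 3)

    def test_constructed_population_mean(self):
        vesicles = (
            [_make_vesicle(1, 20, f"a{i}") for i in range(63)]
            + [_make_vesicle(2, 20, f"b{i}") for i in range(26)]
            + [_make_vesicle(3, 20, f"c{i}") for i in range(8)]
            + [_make_vesicle(4, 20, f"d{i}") for i in range(3)])
        fractions, mean = count_distribution(vesicles)
        assert fractions == {1: 0.63, 2: 0.26, 3: 0.08, 4: 0.03}
        assert mean == pytest.approx(1.51, abs=1e-12)

    def test_uniform_counts(self):
        fractions, mean = count_distribution(
            [_make_vesicle(2, 20, f"v{i}") for i in range(10)])
        assert mean == 2.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            count_distribution([])


class TestPearsonCountRadius:
    def test_perfect_positive(self):
        vesicles = [_make_vesicle(k, float(k), f"v{k}") for k in (1, 2, 3, 4)]
        r, p, n = pearson_count_radius(vesicles)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 4

    def test_perfect_negative(self):
        vesicles = [_make_vesicle(k, 10.0 - k, f"v{k}") for k in (1, 2, 3, 4)]
        r, _, _ = pearson_count_radius(vesicles)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        vesicles = [_make_vesicle(1, 1.0, "a"), _make_vesicle(2, 3.0, "b"),
                    _make_vesicle(3, 2.0, "c")]
        r, _, _ = pearson_count_radius(vesicles)
        assert r == pytest.approx(0.5)

    def test_constant_variable_rejected(self):
        vesicles = [_make_vesicle(2, float(k), f"v{k}") for k in (1, 2, 3)]
        with pytest.raises(UndefinedCorrelationError):
            pearson_count_radius(vesicles)
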