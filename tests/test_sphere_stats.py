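"""Geodesic distances, bias model, null simulation, KS, randomness test."""

import numpy as np
import pytest
from scipy import stats

from conftest import ks_exact_p_enumeration

from vesimap import (BiasModel, ConfigurationError, DegenerateGeometryError,
                     estimate_bias, geodesic_distances, ks_two_sample,
                     randomness_test, select_vesicles, simulate_null)
from vesimap.geometry import Vesicle
from vesimap.io import Particle
from vesimap.sphere_stats import uniform_sphere


def _vesicle_with_members(directions, radius=20.0, vid="v0"):
    particles = [
        Particle(particle_id=f"{vid}_p{i}", tomogram_id="t",
                 position=radius * np.asarray(d, float), axis=np.asarray(d, float))
        for i, d in enumerate(directions)]
    vesicle = Vesicle(vesicle_id=vid, tomogram_id="t", center=np.zeros(3),
                      radius=radius,
                      member_particle_ids=[p.particle_id for p in particles],
                      radius_source="joint_fit")
    return vesicle, particles


class TestGeodesicDistances:
    def test_antipodal_pair_is_half_circumference(self):
        v, ps = _vesicle_with_members([(0, 0, 1), (0, 0, -1)])
        assert geodesic_distances(v, ps)[0] == pytest.approx(np.pi * 20)

    def test_orthogonal_pair_is_quarter_circle(self):
        v, ps = _vesicle_with_members([(1, 0, 0), (0, 1, 0)])
        assert geodesic_distances(v, ps)[0] == pytest.approx(np.pi * 20 / 2)

    def test_coincident_directions_give_zero(self):
        v, ps = _vesicle_with_members([(1, 0, 0), (1, 0, 0)])
        assert geodesic_distances(v, ps)[0] == 0.0

    def test_center_coincident_member_is_degenerate(self):
        v, ps = _vesicle_with_members([(1, 0, 0), (0, 1, 0)])
        ps[0].position = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            geodesic_distances(v, ps)

    def test_pair_count_and_range(self, rng):
        dirs = uniform_sphere(rng, 6)
        v, ps = _vesicle_with_members(dirs)
        d = geodesic_distances(v, ps)
        assert len(d) == 15
        assert np.all((d >= 0) & (d <= np.pi * v.radius + 1e-9))


class TestSelectVesicles:
    def _population(self):
        radii = [18.2, 19.5, 20.4, 25.0]
        return [Vesicle(vesicle_id=f"v{i}", tomogram_id="t", center=np.zeros(3),
                        radius=r, member_particle_ids=["a", "b"],
                        radius_source="joint_fit")
                for i, r in enumerate(radii)]

    def test_closed_interval_rule(self):
        chosen = select_vesicles(self._population(), (19, 20), 2, rule="interval")
        assert [v.radius for v in chosen] == [19.5]

    def test_rounded_rule_admits_nearby_radii(self):
        chosen = select_vesicles(self._population(), (19, 20), 2, rule="rounded")
        assert [v.radius for v in chosen] == [19.5, 20.4]

    def test_wrong_member_count_excluded(self):
        population = self._population()
        population[1].member_particle_ids.append("c")
        chosen = select_vesicles(population, (19, 20), 2, rule="interval")
        assert chosen == []

    def test_prior_radii_excluded(self):
        population = self._population()
        population[1].radius_source = "default_prior"
        assert select_vesicles(population, (19, 20), 2, rule="interval") == []

    def test_empty_input(self):
        assert select_vesicles([], (19, 20), 2) == []

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            select_vesicles(self._population(), (20, 19), 2)


class TestEstimateBias:
    def test_isotropic_axes_give_flat_weights(self):
        # n chosen so the per-bin sampling noise (~0.7% relative SD at
        # 5e5/18 per bin) keeps min/max weight above 0.95 with wide margin
        rng = np.random.default_rng(42)
        model = estimate_bias(uniform_sphere(rng, 500_000))
        assert model.weights.min() >= 0.95
        assert model.weights.max() == 1.0

    def test_in_plane_axes_concentrate_first_bin(self):
        axes = np.array([[np.cos(t), np.sin(t), 0.0]
                         for t in np.linspace(0, np.pi, 50)])
        model = estimate_bias(axes, n_bins=10)
        assert model.weights[0] == 1.0
        assert np.all(model.weights[1:] < 0.1)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_bias(np.eye(3), n_bins=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_bias([])

    def test_all_zero_weights_invalid(self):
        with pytest.raises(ConfigurationError):
            BiasModel(bin_edges=np.linspace(0, 1, 4), weights=np.zeros(3))


class TestSimulateNull:
    def test_same_seed_reproduces_sample(self):
        a = simulate_null(20.0, 100, 2, seed=9)
        b = simulate_null(20.0, 100, 2, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_unbiased_mean_matches_analytic_law(self):
        # central angle of a uniform pair has density sin(theta)/2, mean pi/2
        sample = simulate_null(20.0, 20_000, 2, bias=None, seed=1)
        se = sample.values.std() / np.sqrt(len(sample.values))
        assert abs(sample.values.mean() - np.pi * 10) < 3 * se

    def test_unbiased_angle_density_chi2(self):
        sample = simulate_null(20.0, 20_000, 2, bias=None, seed=2)
        theta = sample.values / 20.0
        edges = np.linspace(0, np.pi, 21)
        observed, _ = np.histogram(theta, bins=edges)
        cdf = 0.5 * (1 - np.cos(edges))
        expected = len(theta) * np.diff(cdf)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_rejection_sampling_matches_weight_profile(self):
        # accepted q values are distributed proportional to the bin weights
        bias = BiasModel.from_cosine_power(2.0, n_bins=18)
        sample_dirs = simulate_null(20.0, 30_000, 2, bias=bias, seed=3)
        # re-generate directions to inspect orientation marginal
        rng = np.random.default_rng(3)
        from vesimap.sphere_stats import _biased_directions

        dirs = _biased_directions(rng, 60_000, bias)
        q = np.abs(dirs[:, 2])
        observed, _ = np.histogram(q, bins=bias.bin_edges)
        expected = bias.weights * np.diff(bias.bin_edges)
        expected = len(q) * expected / expected.sum()
        assert stats.chisquare(observed, expected).pvalue > 0.01
        assert len(sample_dirs.values) == 30_000

    def test_acceptance_rate_matches_weight_integral(self):
        bias = BiasModel.from_cosine_power(2.0, n_bins=18)
        rng = np.random.default_rng(4)
        n = 200_000
        cand = uniform_sphere(rng, n)
        accepted = rng.random(n) < bias.weight_at(np.abs(cand[:, 2]))
        rate = accepted.mean()
        expected = bias.mean_acceptance()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_null(20.0, 0, 2)
        with pytest.raises(ValueError):
            simulate_null(20.0, 10, 1)


class TestKSTwoSample:
    def test_identical_multisets(self):
        res = ks_two_sample([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.D == 0.0 and res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [10, 11])
        assert res.D == 1.0

    def test_symmetry(self, rng):
        x = rng.normal(size=37)
        y = rng.normal(size=53)
        a = ks_two_sample(x, y)
        b = ks_two_sample(y, x)
        assert a.D == b.D and a.p_value == b.p_value

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=rng.integers(3, 5))
        res = ks_two_sample(x, y, mode="exact")
        oracle = ks_exact_p_enumeration(x, y)
        assert res.p_value == pytest.approx(oracle, abs=1e-10)

    def test_auto_switches_to_exact_for_small_samples(self):
        assert ks_two_sample([1, 2], [3, 4], mode="auto").mode == "exact"
        assert ks_two_sample(np.arange(50), np.arange(50) + 0.5,
                             mode="auto").mode == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestRandomnessTest:
    def _selected(self, n, seed, radius=19.5):
        rng = np.random.default_rng(seed)
        vesicles, particles = [], []
        for i in range(n):
            v, ps = _vesicle_with_members(uniform_sphere(rng, 2), radius, f"v{i}")
            vesicles.append(v)
            particles.extend(ps)
        return vesicles, particles

    def test_requires_two_vesicles(self):
        vesicles, particles = self._selected(1, 0)
        with pytest.raises(ValueError):
            randomness_test(vesicles, particles, None)

    def test_mixed_member_counts_rejected(self):
        vesicles, particles = self._selected(3, 1)
        extra = Particle(particle_id="x", tomogram_id="t",
                         position=np.array([19.5, 0, 0]), axis=np.array([1.0, 0, 0]))
        vesicles[0].member_particle_ids.append("x")
        particles.append(extra)
        with pytest.raises(ValueError):
            randomness_test(vesicles, particles, None)

    def test_uniform_scene_is_compatible_with_null(self):
        vesicles, particles = self._selected(320, 2)
        ks, exp, null = randomness_test(vesicles, particles, None,
                                        n_null=2000, seed=5)
        assert ks.n1 == 320 and ks.n2 == 2000
        assert ks.p_value > 0.05
        assert exp.provenance == "experimental"
        assert null.provenance == "simulated"

    def test_null_vs_independent_null_p_is_uniform(self):
        # probability integral transform: comparing the null against an
        # independent draw of itself gives uniform p over seeds
        bias = BiasModel.from_cosine_power(2.0)
        ps = []
        for seed in range(500):
            x = simulate_null(19.5, 320, 2, bias=bias, seed=2 * seed)
            y = simulate_null(19.5, 2000, 2, bias=bias, seed=2 * seed + 1)
            ps.append(ks_two_sample(x.values, y.values).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_per_vesicle_radius_mode_runs(self):
        vesicles, particles = self._selected(10, 3)
        ks, _, null = randomness_test(vesicles, particles, None, n_null=50,
                                      seed=7, radius_mode="per_vesicle")
        assert len(null.values) == 50
        assert 0 <= ks.p_value <= 1
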