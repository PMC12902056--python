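"""Egocentric likelihood components, map combination, simulation and fitting."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from sacbias.circular_stats import circular_cross_correlation, circular_kde, horizontal_bias
from sacbias.image_features import SaliencyMap, saliency_direction_samples
from sacbias.target_model import (
    CombinationWeights,
    EgocentricParams,
    LikelihoodMap,
    VonMisesLobe,
    cauchy_radial,
    combined_map,
    egocentric_map,
    fit_egocentric_params,
    match_lobes,
    mixture_direction_distribution,
    simulate_scanpath,
    small_saccade_penalty,
    vonmises_mixture,
)


class TestEgoComponents:
    @pytest.mark.parametrize("a,expected", [(1.0, 1 / math.pi), (2.0, 1 / (2 * math.pi))])
    def test_cauchy_peak(self, a, expected):
        assert cauchy_radial(0.0, 0.0, a) == pytest.approx(expected)

    @pytest.mark.parametrize("a", [0.5, 1.0, 3.0])
    def test_cauchy_half_width(self, a):
        assert cauchy_radial(a, 0.0, a) == pytest.approx(cauchy_radial(0, 0, a) / 2)

    def test_vonmises_uniform_limit(self):
        lobes = (VonMisesLobe(0, 0.0, 1.0),)
        th = np.linspace(0, 2 * math.pi, 7)
        assert np.allclose(vonmises_mixture(th, lobes), 1 / (2 * math.pi))

    def test_vonmises_cardinal_symmetry(self):
        lobes = tuple(VonMisesLobe(m, 2.0, 0.25) for m in (0, 90, 180, 270))
        assert vonmises_mixture(0.0, lobes) == pytest.approx(
            vonmises_mixture(math.pi / 2, lobes)
        )

    def test_vonmises_against_quadrature(self):
        """Normalization of the unnormalized kernel matches quadrature."""
        lobes = (VonMisesLobe(0, 4.0, 0.5), VonMisesLobe(180, 4.0, 0.5))
        val = vonmises_mixture(0.0, lobes)
        kernel = lambda t: 0.5 * (
            math.exp(4 * math.cos(t)) + math.exp(4 * math.cos(t - math.pi))
        )
        norm, _ = integrate.quad(kernel, 0, 2 * math.pi)
        assert val == pytest.approx(kernel(0.0) / norm, rel=1e-9)

    def test_vonmises_against_scipy(self):
        """One-lobe mixture equals scipy's von Mises density."""
        lobes = (VonMisesLobe(30.0, 3.0, 1.0),)
        th = np.linspace(0, 2 * math.pi, 9)
        ref = stats.vonmises.pdf(th, 3.0, loc=math.radians(30.0))
        np.testing.assert_allclose(vonmises_mixture(th, lobes), ref, rtol=1e-9)

    @pytest.mark.parametrize(
        "r,expected", [(0.0, 0.0), (0.9, 1 - math.exp(-0.5)), (10.0, 1.0)]
    )
    def test_small_saccade_penalty(self, r, expected):
        assert small_saccade_penalty(r, 0.0) == pytest.approx(expected, abs=1e-6)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            EgocentricParams(1.0, tuple(VonMisesLobe(m, 1, 0.3) for m in (0, 90, 180, 270)))


class TestMaps:
    def test_ego_map_normalized_and_horizontal(self, truth_params):
        m = egocentric_map((11.2, 11.2), (64, 64), 0.35, truth_params)
        assert m.prob.sum() == pytest.approx(1.0, abs=1e-9)
        mid = m.prob[31:33, :].sum()
        assert mid > m.prob[:, 31:33].sum() * 1.2  # horizontal lobes dominate

    def test_ego_map_radially_symmetric_with_flat_lobes(self):
        params = EgocentricParams(
            2.0, tuple(VonMisesLobe(m, 0.0, 0.25) for m in (0, 90, 180, 270))
        )
        m = egocentric_map((11.2, 11.2), (64, 64), 0.35, params)
        assert np.allclose(m.prob, m.prob[::-1, ::-1], rtol=1e-6)

    def test_combined_degenerate_exponents(self, truth_params):
        shape = (32, 32)
        allo = SaliencyMap.from_unnormalized(np.random.default_rng(0).random(shape), 0.35)
        ego = egocentric_map((5.6, 5.6), shape, 0.35, truth_params)
        c_allo = combined_map(allo, ego, CombinationWeights(alpha=0.0, beta=1.0))
        np.testing.assert_allclose(c_allo.prob, allo.prob, rtol=1e-9)
        c_ego = combined_map(allo, ego, CombinationWeights(alpha=1.0, beta=0.0))
        np.testing.assert_allclose(c_ego.prob, ego.prob, rtol=1e-9)

    def test_uniform_allo_identity(self, truth_params, uniform_map):
        ego = egocentric_map((11.2, 11.2), (64, 64), 0.35, truth_params)
        c = combined_map(uniform_map, ego, CombinationWeights(alpha=1.0, beta=1.0))
        np.testing.assert_allclose(c.prob, ego.prob, rtol=1e-9)


class TestSimulation:
    def test_deterministic_under_seed(self, truth_params, uniform_map):
        a = simulate_scanpath(uniform_map, truth_params, n_saccades=30, rng=7)
        b = simulate_scanpath(uniform_map, truth_params, n_saccades=30, rng=7)
        np.testing.assert_array_equal(a.fixations, b.fixations)

    def test_ego_only_is_horizontally_biased(self, truth_params, uniform_map):
        sp = simulate_scanpath(
            uniform_map, truth_params, CombinationWeights(1.0, 0.0), 1500, rng=2
        )
        d = circular_kde(np.deg2rad(sp.directions_deg))
        assert horizontal_bias(d) > 0.16

    def test_two_blob_allo_only_bimodal(self, truth_params):
        m = np.zeros((64, 64))
        m[32, 10] = m[32, 54] = 1.0
        sal = SaliencyMap.from_unnormalized(m, 0.35)
        sp = simulate_scanpath(
            sal, truth_params, CombinationWeights(0.0, 1.0), 800, rng=3
        )
        moved = np.abs(np.cos(np.deg2rad(sp.directions_deg))) > 0.9
        assert moved.mean() > 0.45

    def test_alpha_zero_matches_iid_saliency_sampling(self, truth_params):
        from sacbias.synthetic_data import gen_saliency_map

        sal = gen_saliency_map(64, 0.35, rng=0)
        sp = simulate_scanpath(
            sal, truth_params, CombinationWeights(0.0, 1.0), 2000, rng=1
        )
        _, d2 = saliency_direction_samples(sal, 2000, rng=2)
        bins = np.linspace(0, 360, 13)
        h1, _ = np.histogram(sp.directions_deg, bins)
        h2, _ = np.histogram(d2, bins)
        _, p, *_ = stats.chi2_contingency(np.vstack([h1, h2]))
        assert p > 0.01

    def test_beta_zero_rotated_lobes_rotate_directions(self, truth_params):
        big = SaliencyMap(np.full((96, 96), 1.0 / 96**2), 0.35)
        delta = 25
        rot = EgocentricParams(
            truth_params.a,
            tuple(
                VonMisesLobe(l.mu_deg + delta, l.kappa, l.weight)
                for l in truth_params.lobes
            ),
        )
        s0 = simulate_scanpath(big, truth_params, CombinationWeights(0.7, 0.0), 4000, rng=3)
        s1 = simulate_scanpath(big, rot, CombinationWeights(0.7, 0.0), 4000, rng=4)
        k0 = circular_kde(np.deg2rad(s0.directions_deg))
        k1 = circular_kde(np.deg2rad(s1.directions_deg))
        assert abs(circular_cross_correlation(k0, k1) - delta) <= 1


class TestFitting:
    def test_uniform_directions_fit_is_flat(self, uniform_map):
        """Directionally uniform data drive the fitted mixture toward
        uniformity: its horizontal bias lands at the uniform value."""
        flat = EgocentricParams(
            1.5, tuple(VonMisesLobe(m, 0.0, 0.25) for m in (0, 90, 180, 270))
        )
        sp = simulate_scanpath(
            uniform_map, flat, CombinationWeights(1.0, 0.0), 1500, rng=5
        )
        res = fit_egocentric_params(
            sp.to_saccades(), (64, 64), 0.35, n_starts=2, seed=0, maxiter=200
        )
        mix = mixture_direction_distribution(res.params)
        assert horizontal_bias(mix) == pytest.approx(0.16, abs=0.02)

    def test_fit_beats_truth_likelihood(self, truth_params, uniform_map):
        from sacbias.target_model import _EgoObjective, _encode

        sp = simulate_scanpath(
            uniform_map, truth_params, CombinationWeights(1.0, 0.0), 1500, rng=6
        )
        sacs = sp.to_saccades()
        res = fit_egocentric_params(sacs, (64, 64), 0.35, n_starts=3, seed=0)
        obj = _EgoObjective(sacs, (64, 64), 0.35)
        ll_truth = -obj(_encode(truth_params))
        assert res.log_likelihood >= ll_truth - len(sacs) * 1e-3

    def test_too_few_saccades_raises(self, truth_params, uniform_map):
        sp = simulate_scanpath(uniform_map, truth_params, n_saccades=5, rng=0)
        with pytest.raises(ValueError, match="few"):
            fit_egocentric_params(sp.to_saccades(), (64, 64), 0.35)


class TestParamsIO:
    def test_round_trip(self, tmp_path, truth_params):
        path = tmp_path / "params.json"
        truth_params.save(path)
        back = EgocentricParams.load(path)
        assert back.a == pytest.approx(truth_params.a)
        for lb, ref in zip(back.lobes, truth_params.lobes):
            assert lb.mu_deg == pytest.approx(ref.mu_deg)
            assert lb.kappa == pytest.approx(ref.kappa)
            assert lb.weight == pytest.approx(ref.weight)

    def test_match_lobes_resolves_permutation(self, truth_params):
        shuffled = EgocentricParams(
            truth_params.a,
            (truth_params.lobes[2], truth_params.lobes[0], truth_params.lobes[3], truth_params.lobes[1]),
        )
        matched = match_lobes(shuffled, truth_params)
        assert [l.mu_deg for l in matched] == [l.mu_deg for l in truth_params.lobes]
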