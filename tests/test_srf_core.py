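"""Stochastic cliques, weights, energies and the layer optimizer.

Brute-force oracles here re-derive regional distances and weights by
explicit patch extraction and per-pair loops, independent of the
vectorized per-offset implementation they check.
"""

import math
from collections import defaultdict

import numpy as np
import pytest

from srfdenoise import (
    EdgeSet,
    NoiseParams,
    SRFConfig,
    compute_weights,
    connection_probability,
    denoise,
    deterministic_weights,
    gradient_step,
    pairwise_energy,
    regional_distance,
    sample_edges,
    total_energy,
    unary_energy,
)
from srfdenoise.srf_core import WeightMap, half_offsets


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def reflect_index(y: int, n: int) -> int:
    # mirror without repeating the edge sample
    while y < 0 or y >= n:
        y = -y if y < 0 else 2 * (n - 1) - y
    return y


def oracle_patch(state, center, region_size):
    r = region_size // 2
    h, w = state.shape
    vals = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            vals.append(
                state[reflect_index(center[0] + dy, h),
                      reflect_index(center[1] + dx, w)]
            )
    return np.array(vals)


def oracle_distance(state, i, j, region_size):
    pi = oracle_patch(state, i, region_size)
    pj = oracle_patch(state, j, region_size)
    return float(np.linalg.norm(pi - pj)) / region_size**2


def oracle_weights(state, pairs, sigma, region_size):
    raw = {}
    sums = defaultdict(float)
    for i, j in pairs:
        w = math.exp(-oracle_distance(state, i, j, region_size) ** 2 / sigma**2)
        raw[(i, j)] = w
        sums[i] += w
        sums[j] += w
    return {
        (i, j): w / max(sums[i], sums[j], 1.0) for (i, j), w in raw.items()
    }


def all_window_pairs(shape, neighborhood_size):
    h, w = shape
    pairs = []
    for y in range(h):
        for x in range(w):
            for dy, dx in half_offsets(neighborhood_size):
                jy, jx = y + dy, x + dx
                if 0 <= jy < h and 0 <= jx < w:
                    pairs.append(((y, x), (jy, jx)))
    return pairs


def random_edges(shape, neighborhood_size, rng, p=0.4):
    pairs = [pr for pr in all_window_pairs(shape, neighborhood_size)
             if rng.random() < p]
    return EdgeSet.from_pairs(shape, pairs), pairs


# ---------------------------------------------------------------------------
# Regional distances
# ---------------------------------------------------------------------------

class TestRegionalDistance:
    def test_constant_image_all_zero(self):
        u = np.full((6, 6), 3.0)
        for i, j in [((0, 0), (2, 3)), ((5, 5), (1, 0))]:
            assert regional_distance(u, i, j, 3) == 0.0

    def test_identical_sites(self, texture):
        assert regional_distance(texture, (4, 4), (4, 4), 3) == 0.0

    def test_single_bright_pixel_hand_value(self):
        u = np.zeros((5, 5))
        u[2, 2] = 9.0
        # both patches contain the bright pixel, at different positions,
        # so the patch difference holds +/-9 at two entries
        assert regional_distance(u, (2, 1), (2, 3), 3) == pytest.approx(
            oracle_distance(u, (2, 1), (2, 3), 3)
        )
        assert oracle_distance(u, (2, 1), (2, 3), 3) == pytest.approx(
            math.sqrt(2 * 81.0) / 9.0
        )

    @pytest.mark.parametrize("region", [1, 3, 5])
    def test_matches_patch_extraction_oracle(self, texture, region, rng):
        for _ in range(20):
            i = tuple(rng.integers(0, 16, 2))
            j = tuple(rng.integers(0, 16, 2))
            assert regional_distance(texture, i, j, region) == pytest.approx(
                oracle_distance(texture, i, j, region), rel=1e-12
            )


class TestConnectionProbability:
    def test_zero_distance(self):
        assert connection_probability(0.0, 1.0) == 1.0

    def test_half_life(self):
        assert connection_probability(2.0 * math.log(2), 2.0) == pytest.approx(0.5)

    def test_monotone_decreasing(self):
        ds = np.linspace(0.1, 10, 50)
        ps = connection_probability(ds, 1.0)
        assert np.all(np.diff(ps) < 0)

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            connection_probability(1.0, 0.0)


# ---------------------------------------------------------------------------
# Edge sampling
# ---------------------------------------------------------------------------

class TestSampleEdges:
    def test_large_q_gives_complete_graph(self, texture):
        cfg = SRFConfig(neighborhood_size=5, q=1e9, seed=0)
        edges = sample_edges(texture, cfg, seed=0)
        assert edges.n_edges == len(all_window_pairs(texture.shape, 5))

    def test_small_q_gives_empty_graph(self, texture):
        cfg = SRFConfig(neighborhood_size=5, q=1e-9, seed=0)
        assert sample_edges(texture, cfg, seed=0).n_edges == 0

    def test_constant_image_fully_connected_any_q(self):
        u = np.full((12, 12), 4.0)
        cfg = SRFConfig(neighborhood_size=5, q=0.01, seed=3)
        edges = sample_edges(u, cfg, seed=3)
        assert edges.n_edges == len(all_window_pairs(u.shape, 5))

    def test_seed_determinism(self, texture):
        cfg = SRFConfig(seed=11)
        assert sample_edges(texture, cfg) == sample_edges(texture, cfg)
        assert sample_edges(texture, cfg, 1) != sample_edges(texture, cfg, 2)

    def test_symmetry_and_no_self_edges(self, texture):
        edges = sample_edges(texture, SRFConfig(neighborhood_size=5, q=2.0), 4)
        for i, j in edges.pairs()[:100]:
            assert i != j
            assert edges.contains(j, i)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

class TestWeights:
    def test_constant_image_raw_weights_one(self):
        u = np.full((5, 5), 2.0)
        edges = EdgeSet.from_pairs(u.shape, all_window_pairs(u.shape, 3))
        wm = compute_weights(u, edges, sigma=0.7, region_size=3, normalize=False)
        for (i, j), w in wm.items():
            assert w == 1.0

    def test_distance_sigma_gives_inv_e(self):
        sigma = 1.7
        u = np.array([[0.0, sigma]])
        edges = EdgeSet.from_pairs(u.shape, [((0, 0), (0, 1))])
        wm = compute_weights(u, edges, sigma=sigma, region_size=1, normalize=False)
        assert wm.weight((0, 0), (0, 1)) == pytest.approx(math.exp(-1))

    def test_matches_brute_force_pair_by_pair(self, rng):
        u = rng.uniform(0, 5, (4, 4))
        pairs = all_window_pairs(u.shape, 3)
        edges = EdgeSet.from_pairs(u.shape, pairs)
        wm = compute_weights(u, edges, sigma=1.3, region_size=3)
        expect = oracle_weights(u, pairs, 1.3, 3)
        for pr, w in expect.items():
            assert wm.weight(*pr) == pytest.approx(w, rel=1e-10)
            assert wm.weight(pr[1], pr[0]) == pytest.approx(w, rel=1e-10)

    def test_normalized_incident_sums_at_most_one(self, texture):
        edges = sample_edges(texture, SRFConfig(neighborhood_size=7, q=5.0), 6)
        wm = compute_weights(texture, edges, sigma=2.0, region_size=3)
        deg = wm.degree()
        assert deg.max() <= 1.0 + 1e-12
        raw = compute_weights(texture, edges, 2.0, 3, normalize=False)
        for _, w in raw.items():
            assert 0.0 <= w <= 1.0

    def test_deterministic_baseline_threshold(self, texture):
        cfg = SRFConfig(neighborhood_size=5, sigma=1.0)
        plain = deterministic_weights(texture, cfg, "plain")
        huge_t = deterministic_weights(texture, cfg, "hard_threshold", t=1e12)
        for off in plain.offsets:
            assert np.array_equal(plain.weights[off], huge_t.weights[off])
        small_t = deterministic_weights(texture, cfg, "hard_threshold", t=0.3)
        from srfdenoise.srf_core import distance_fields

        fields = distance_fields(texture, 3, half_offsets(5))
        for off in plain.offsets:
            d = fields[off]
            assert np.all(small_t.weights[off][d > 0.3] == 0.0)
            keep = np.isfinite(d) & (d <= 0.3)
            assert np.array_equal(
                small_t.weights[off][keep], plain.weights[off][keep]
            )

    def test_mean_srf_weight_is_plain_times_probability(self):
        # expectation oracle: E[w_sampled] = w_raw * P(connect), per edge
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 5, (6, 6))
        cfg = SRFConfig(neighborhood_size=3, q=1.0, sigma=1.0)
        n_seeds = 10_000
        acc = None
        for s in range(n_seeds):
            edges = sample_edges(u, cfg, seed=s)
            wm = compute_weights(u, edges, 1.0, 3, normalize=False)
            stack = {off: wm.weights[off] for off in wm.offsets}
            if acc is None:
                acc = {off: w.copy() for off, w in stack.items()}
            else:
                for off in acc:
                    acc[off] += stack[off]
        plain = deterministic_weights(u, cfg, "plain")
        from srfdenoise.srf_core import distance_fields

        fields = distance_fields(u, 3, half_offsets(3))
        for off, total in acc.items():
            mean_w = total / n_seeds
            p = np.exp(-fields[off] / cfg.q)
            expect = np.where(np.isfinite(fields[off]), plain.weights[off] * p, 0.0)
            assert np.allclose(mean_w, expect, atol=0.02)


# ---------------------------------------------------------------------------
# Energies and gradient
# ---------------------------------------------------------------------------

class TestEnergies:
    def test_unary_identity_and_closed_form(self, texture):
        assert unary_energy(texture, texture) == 0.0
        assert unary_energy(np.array([[3.0]]), np.array([[1.0]])) == 4.0

    def test_unary_matches_brute_sum(self, rng):
        a, b = rng.normal(0, 1, (8, 8)), rng.normal(0, 1, (8, 8))
        expect = sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel()))
        assert unary_energy(a, b) == pytest.approx(expect, rel=1e-12)

    def test_unary_shape_mismatch(self):
        with pytest.raises(ValueError):
            unary_energy(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_pairwise_constant_zero(self):
        u = np.full((5, 5), 7.0)
        edges = EdgeSet.from_pairs(u.shape, all_window_pairs(u.shape, 3))
        wm = compute_weights(u, edges, 1.0, 3)
        assert pairwise_energy(u, wm) == 0.0

    def test_pairwise_two_pixel_closed_form(self):
        u = np.array([[0.0, 2.0]])
        wm = WeightMap(u.shape, {(0, 1): np.array([[0.5, 0.0]])})
        assert pairwise_energy(u, wm) == pytest.approx(2.0)

    def test_pairwise_matches_brute_loop(self, rng):
        u = rng.normal(0, 2, (8, 8))
        edges, pairs = random_edges(u.shape, 5, rng)
        wm = compute_weights(u, edges, 1.5, 3)
        expect = sum(
            wm.weight(i, j) * (u[i] - u[j]) ** 2 for i, j in pairs
        )
        assert pairwise_energy(u, wm) == pytest.approx(expect, rel=1e-10)

    def test_total_energy_composition(self, rng):
        u = rng.normal(5, 2, (6, 6))
        obs = rng.normal(5, 2, (6, 6))
        edges, _ = random_edges(u.shape, 3, rng)
        wm = compute_weights(u, edges, 1.0, 3)
        assert total_energy(u, obs, wm, 0.0) == unary_energy(u, obs)
        assert total_energy(u, obs, wm, 0.7) == pytest.approx(
            unary_energy(u, obs) + 0.7 * pairwise_energy(u, wm), rel=1e-12
        )
        const = np.full((6, 6), 3.0)
        wm_c = compute_weights(const, EdgeSet.from_pairs(const.shape, []), 1.0, 3)
        assert total_energy(const, const, wm_c, 1.0) == 0.0


class TestGradientStep:
    def test_stationary_point_unchanged(self):
        u = np.full((6, 6), 5.0)
        edges = EdgeSet.from_pairs(u.shape, all_window_pairs(u.shape, 3))
        wm = compute_weights(u, edges, 1.0, 3)
        out = gradient_step(u, u, wm, lam=1.0, step=0.5)
        assert np.allclose(out, u)

    def test_single_pixel_closed_form(self):
        out = gradient_step(
            np.array([[1.0]]), np.array([[0.0]]),
            WeightMap((1, 1), {}), lam=1.0, step=0.5,
        )
        assert out[0, 0] == pytest.approx(0.0)

    def test_matches_finite_differences(self, rng):
        for _ in range(5):
            u = rng.normal(0, 2, (4, 4))
            obs = rng.normal(0, 2, (4, 4))
            edges, _ = random_edges(u.shape, 3, rng)
            wm = compute_weights(u, edges, 1.0, 3)
            lam, step = 0.8, 0.25
            grad = (u - gradient_step(u, obs, wm, lam, step)) / step
            h = 1e-6
            for y in range(4):
                for x in range(4):
                    up, dn = u.copy(), u.copy()
                    up[y, x] += h
                    dn[y, x] -= h
                    fd = (
                        total_energy(up, obs, wm, lam)
                        - total_energy(dn, obs, wm, lam)
                    ) / (2 * h)
                    assert grad[y, x] == pytest.approx(fd, abs=1e-6)


# ---------------------------------------------------------------------------
# Full denoiser
# ---------------------------------------------------------------------------

class TestDenoise:
    PARAMS = NoiseParams(g0=1.0, m=12.0, sigma_eps=0.5)

    def test_zero_layers_is_vst_round_trip(self, rng):
        obs = rng.uniform(20, 100, (16, 16))
        out = denoise(obs, self.PARAMS, SRFConfig(layers=0, seed=0))
        assert np.allclose(out, obs, rtol=1e-9)

    def test_constant_noise_free_image_fixed_point(self):
        obs = np.full((16, 16), 50.0)
        out = denoise(obs, NoiseParams(), SRFConfig(layers=5, seed=1))
        assert np.allclose(out, obs, atol=1e-6)

    def test_tiny_q_approximates_identity(self, texture):
        obs = texture + 20.0
        cfg = SRFConfig(layers=3, q=1e-9, seed=2)
        out = denoise(obs, self.PARAMS, cfg)
        assert np.allclose(out, obs, rtol=1e-9)

    def test_seed_reproducibility_bit_identical(self, small_phantom_pair):
        spec, _, noisy = small_phantom_pair
        cfg = SRFConfig(layers=3, seed=42)
        a = denoise(noisy, spec.noise_params(), cfg)
        b = denoise(noisy, spec.noise_params(), cfg)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self, small_phantom_pair):
        spec, _, noisy = small_phantom_pair
        p = spec.noise_params()
        a = denoise(noisy, p, SRFConfig(layers=3, seed=1))
        b = denoise(noisy, p, SRFConfig(layers=3, seed=2))
        assert not np.array_equal(a, b)

    def test_nonfinite_observation_rejected(self):
        obs = np.full((8, 8), 10.0)
        obs[3, 3] = np.nan
        with pytest.raises(ValueError):
            denoise(obs, self.PARAMS, SRFConfig(seed=0))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SRFConfig(neighborhood_size=4)
        with pytest.raises(ValueError):
            SRFConfig(neighborhood_size=3, region_size=5)
        with pytest.raises(ValueError):
            SRFConfig(q=-1.0)
        with pytest.raises(ValueError):
            SRFConfig(layers=-1)

    def test_yaml_dict_round_trip(self):
        cfg = SRFConfig(neighborhood_size=9, region_size=5, q=2.0,
                        sigma=1.5, layers=7, lam=0.3, step=0.4, seed=99)
        assert SRFConfig.from_dict(cfg.to_dict()) == cfg
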