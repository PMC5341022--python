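"""Morris elementary-effects screening: design structure, EE oracle, TG ranking."""

import itertools

import numpy as np
import pytest

from tggpp.morris import (
    DEFAULT_RANGES,
    ParamRanges,
    elementary_effects,
    morris_design,
    screen_tg,
    summarize_effects,
)
from tggpp.synthdata import echo_preset, recovery_preset, simulate_site


def run_morris(f, n_params, r, p, seed):
    trajs = morris_design(n_params, r=r, p=p, seed=seed)
    outs = [np.array([f(pt) for pt in t]) for t in trajs]
    names = tuple(f"u{i}" for i in range(n_params))
    eff = elementary_effects(trajs, outs, names)
    return summarize_effects(eff, r=r, p=p, seed=seed), eff


def enumerate_effects(f, n_params, p):
    """Exhaustive EE population: every (base, sign, move-order) trajectory.

    Independent first-principles enumeration of the one-at-a-time design
    space at p levels, giving the exact finite population the sampled design
    draws from uniformly.
    """
    delta = p / (2.0 * (p - 1.0))
    base_levels = [i / (p - 1.0) for i in range(p // 2)]
    effects = {i: [] for i in range(n_params)}
    for base in itertools.product(base_levels, repeat=n_params):
        for signs in itertools.product([1.0, -1.0], repeat=n_params):
            start = [b if s > 0 else b + delta for b, s in zip(base, signs)]
            for order in itertools.permutations(range(n_params)):
                x = list(start)
                for i in order:
                    before = f(np.array(x))
                    x[i] += signs[i] * delta
                    after = f(np.array(x))
                    effects[i].append((after - before) / (signs[i] * delta))
    return effects


class TestDesign:
    def test_point_count(self):
        trajs = morris_design(3, r=4, p=4, seed=0)
        assert len(trajs) == 4 and all(t.shape == (4, 3) for t in trajs)

    def test_delta(self):
        trajs = morris_design(2, r=3, p=4, seed=1)
        for t in trajs:
            steps = np.abs(np.diff(t, axis=0))
            assert np.allclose(steps[steps > 1e-12], 2.0 / 3.0)

    def test_one_at_a_time_each_param_once(self):
        for t in morris_design(3, r=10, p=8, seed=2):
            moved = [int(np.nonzero(~np.isclose(t[i + 1], t[i]))[0][0])
                     for i in range(len(t) - 1)]
            assert sorted(moved) == [0, 1, 2]

    def test_points_on_grid_in_unit_cube(self):
        for t in morris_design(3, r=10, p=4, seed=3):
            assert np.all((t >= 0) & (t <= 1))
            np.testing.assert_allclose(t * 3.0, np.round(t * 3.0), atol=1e-12)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            morris_design(3, r=1, p=4)
        with pytest.raises(ValueError):
            morris_design(3, r=4, p=5)


class TestElementaryEffects:
    def test_constant_function(self):
        res, _ = run_morris(lambda u: 1.0, 3, r=6, p=4, seed=0)
        assert np.all(res.mu_star == 0) and np.all(res.sigma == 0)

    def test_linear_additive_exact(self):
        """For f = 3u₁, μ* equals the coefficient exactly and σ = 0 for any r, p, seed."""
        for seed, p in [(0, 4), (7, 8)]:
            res, _ = run_morris(lambda u: 3.0 * u[0], 3, r=12, p=p, seed=seed)
            np.testing.assert_allclose(res.mu_star, [3.0, 0.0, 0.0], atol=1e-12)
            np.testing.assert_allclose(res.sigma, 0.0, atol=1e-12)

    def test_interaction_gives_positive_sigma(self):
        res, _ = run_morris(lambda u: u[0] * u[1], 2, r=30, p=4, seed=4)
        assert res.sigma[0] > 0 and res.sigma[1] > 0

    def test_sampled_matches_enumeration_oracle(self):
        """Sampled μ*, σ for f = u₁·u₂ agree with the exhaustive population."""
        f = lambda u: u[0] * u[1]
        r = 200
        res, eff = run_morris(f, 2, r=r, p=4, seed=5)
        exact = enumerate_effects(f, 2, p=4)
        for i in range(2):
            pop = np.array(exact[i])
            mu_exact, sd_exact = np.mean(np.abs(pop)), np.std(pop, ddof=1)
            se_mu = np.std(np.abs(pop)) / np.sqrt(r)
            assert abs(res.mu_star[i] - mu_exact) < 3 * se_mu + 1e-12
            se_sd = sd_exact / np.sqrt(2 * r)
            assert abs(res.sigma[i] - sd_exact) < 3 * se_sd + 1e-12

    def test_ranking_invariant_to_affine_output_rescale(self):
        f = lambda u: u[0] + 0.3 * u[1] + 0.05 * u[2]
        g = lambda u: -4.0 * f(u) + 11.0
        r1, _ = run_morris(f, 3, r=20, p=8, seed=6)
        r2, _ = run_morris(g, 3, r=20, p=8, seed=6)
        np.testing.assert_array_equal(r1.rank, r2.rank)


class TestScreenTG:
    def test_tg_ranking_on_synthetic_data(self):
        """Defaults-generated data with LST −5…35 °C: x_m never most influential."""
        from tggpp.synthdata import PFTPreset
        preset = PFTPreset(pft="GRA", x_n=0.0, x_o=30.0, x_m=50.0, m=8.0,
                           lst_mean=15.0, lst_amp=20.0, evi_mean=0.45,
                           evi_amp=0.3, noise_frac=0.15)
        s = simulate_site(preset, 10, seed=42)
        res = screen_tg(s, r=20, p=8, seed=0)
        ranks = dict(zip(res.names, res.rank))
        assert ranks["x_m"] > 1          # never the most influential parameter
        assert ranks["x_o"] == 1

    def test_xm_ranks_last_when_lst_stays_low(self):
        s = simulate_site(echo_preset(), 10, seed=0)
        res = screen_tg(s, r=20, p=8, seed=1)
        assert dict(zip(res.names, res.rank))["x_m"] == 3

    def test_design_respects_parameter_ordering(self):
        s = simulate_site(recovery_preset(), 5, seed=3)
        res = screen_tg(s, r=10, p=8, seed=7)
        # every recorded effect came from a valid (ordered) parameter point
        assert all(len(v) == 10 for v in res.effects.values())

    def test_deterministic_under_seed(self):
        s = simulate_site(recovery_preset(), 5, seed=3)
        a = screen_tg(s, r=8, p=8, seed=11)
        b = screen_tg(s, r=8, p=8, seed=11)
        np.testing.assert_array_equal(a.mu_star, b.mu_star)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(a.rank, b.rank)

    def test_tied_all_zero_ranks_stable(self):
        res = summarize_effects({"x_n": [0.0] * 4, "x_o": [0.0] * 4, "x_m": [0.0] * 4},
                                r=4, p=4, seed=0)
        np.testing.assert_array_equal(res.rank, [1, 2, 3])

    def test_ranges_validate(self):
        with pytest.raises(ValueError):
            ParamRanges(x_o=(40.0, 10.0))
        assert DEFAULT_RANGES.contains([0.0, 30.0, 50.0])
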