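"""Synthetic-data generators: determinism, moments, encoded regime structure."""

import numpy as np
import pytest

from otterforage import (
    CensusConfig,
    GroundTruthConfig,
    IntertidalConfig,
    PreyProfile,
    RegimeShift,
    generate_ground_truth,
    simulate_census,
    simulate_intertidal,
    simulate_sofa_outputs,
)
from conftest import small_truth_config


def _many_prey(k):
    return [
        PreyProfile(f"p{i:03d}", 2.0 - 0.01 * i, 1.0, 50, 10, 1e-4)
        for i in range(k)
    ]


class TestGroundTruth:
    def test_same_seed_identical(self):
        cfg = small_truth_config()
        a = generate_ground_truth(cfg, seed=7)
        b = generate_ground_truth(cfg, seed=7)
        np.testing.assert_array_equal(a.Delta, b.Delta)

    def test_zero_noise_constant_paths(self):
        cfg = small_truth_config(sigma_D=0.0, regime_shifts=[])
        t = generate_ground_truth(cfg, seed=0)
        assert np.all(t.Delta == t.Delta[:, :1])

    def test_innovation_variance_matches_configured_scale(self):
        # 100 prey x 101 increments ~ 1e4 replicate innovations
        cfg = GroundTruthConfig(
            prey=_many_prey(100),
            base_delta={f"p{i:03d}": -1.5 for i in range(100)},
            year_start=2000, year_end=2101,
            sigma_D=0.3, regime_shifts=[],
        )
        t = generate_ground_truth(cfg, seed=1)
        v = np.diff(t.Delta, axis=1).var()
        assert abs(v - 0.09) / 0.09 < 0.05

    def test_step_shift_offset_exact_without_noise(self):
        cfg = small_truth_config(sigma_D=0.0)
        t = generate_ground_truth(cfg, seed=0)
        i = t.prey_ids.index("urchin")
        pre = t.Delta[i, t.years < 2014].mean()
        post = t.Delta[i, t.years >= 2014].mean()
        assert post - pre == pytest.approx(0.8, abs=1e-12)

    def test_ramp_shift_reaches_full_increase(self):
        cfg = small_truth_config(
            sigma_D=0.0, year_end=2020,
            regime_shifts=[RegimeShift("mussel", 2014, 4, 1.2)],
        )
        t = generate_ground_truth(cfg, seed=0)
        i = t.prey_ids.index("mussel")
        base = t.Delta[i, 0]
        assert t.Delta[i, t.years == 2013][0] == pytest.approx(base)
        assert t.Delta[i, t.years == 2017][0] == pytest.approx(base + 1.2)
        # linear ramp midpoint
        assert t.Delta[i, t.years == 2015][0] == pytest.approx(base + 0.6)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"prey": _many_prey(1), "base_delta": {"p000": -1.0}},
            {"sigma_D": -0.1},
            {"tau": 0.0},
            {"regime_shifts": [RegimeShift("urchin", 1990, 1, 0.5)]},
            {"regime_shifts": [RegimeShift("whale", 2010, 1, 0.5)]},
        ],
    )
    def test_invalid_configurations_rejected(self, overrides):
        with pytest.raises(ValueError):
            small_truth_config(**overrides)


class TestSofaOutputs:
    def test_same_seed_identical(self):
        t = generate_ground_truth(small_truth_config(), seed=3)
        a = simulate_sofa_outputs(t, n_draws=150, seed=9)
        b = simulate_sofa_outputs(t, n_draws=150, seed=9)
        np.testing.assert_array_equal(a.eta_draws, b.eta_draws)
        np.testing.assert_array_equal(a.mu_obs, b.mu_obs)

    def test_rows_on_simplex(self):
        t = generate_ground_truth(small_truth_config(), seed=3)
        obs = simulate_sofa_outputs(t, n_draws=200, seed=4)
        sums = obs.eta_draws.sum(axis=-1)
        assert np.all(np.abs(sums - 1) < 1e-9)
        assert np.all(obs.eta_draws >= 0)

    def test_large_precision_concentrates_on_truth(self):
        t = generate_ground_truth(small_truth_config(tau=1e8), seed=3)
        obs = simulate_sofa_outputs(t, n_draws=500, seed=4)
        eta_true = t.eta_matrix()
        assert np.max(np.abs(obs.eta_draws.mean(axis=1) - eta_true)) < 1e-3

    def test_zero_observation_noise_exact(self):
        t = generate_ground_truth(small_truth_config(sigma_E=0.0), seed=3)
        obs = simulate_sofa_outputs(t, n_draws=150, seed=4)
        np.testing.assert_allclose(
            obs.mu_obs, np.broadcast_to(t.mu[:, None], obs.mu_obs.shape)
        )

    def test_dirichlet_component_variance(self):
        t = generate_ground_truth(small_truth_config(tau=50.0, sigma_D=0.0),
                                  seed=3)
        obs = simulate_sofa_outputs(t, n_draws=10_000, seed=4)
        eta = t.eta_matrix()[0]
        expected = eta * (1 - eta) / 51.0
        observed = obs.eta_draws[0].var(axis=0)
        assert np.all(np.abs(observed - expected) / expected < 0.10)

    def test_missing_fraction_leaves_each_prey_observed(self):
        t = generate_ground_truth(small_truth_config(), seed=3)
        obs = simulate_sofa_outputs(t, n_draws=150, seed=4, missing_frac=0.6)
        assert np.isnan(obs.mu_obs).any()
        assert np.all(np.isfinite(obs.mu_obs).sum(axis=1) >= 1)

    def test_rejects_too_few_draws(self):
        t = generate_ground_truth(small_truth_config(), seed=3)
        with pytest.raises(ValueError):
            simulate_sofa_outputs(t, n_draws=50, seed=0)


class TestIntertidal:
    def test_collapse_below_pre_period_minima(self):
        surveys = simulate_intertidal(seed=5)
        import pandas as pd

        df = pd.DataFrame(
            [(s.site_id, s.year, s.pisaster_density) for s in surveys],
            columns=["site", "year", "dens"],
        ).dropna()
        for site, sub in df.groupby("site"):
            pre_min = sub.loc[sub.year < 2013, "dens"].min()
            post_max = sub.loc[sub.year >= 2013, "dens"].max()
            assert post_max < pre_min

    def test_post_period_mussels_larger(self):
        surveys = simulate_intertidal(seed=5)
        pre = np.concatenate(
            [s.mussel_sizes_mm for s in surveys if 2009 <= s.year <= 2012]
        )
        post = np.concatenate(
            [s.mussel_sizes_mm for s in surveys if s.year >= 2013]
        )
        assert post.mean() > pre.mean()

    def test_zero_variance_draws_hit_configured_means(self):
        cfg = IntertidalConfig(
            size_pre=(40.0, 0.0), size_post=(50.0, 0.0),
            cover_pre=(5.0, 0.0), cover_post=(18.0, 0.0),
        )
        surveys = simulate_intertidal(cfg, seed=1)
        for s in surveys:
            if 2009 <= s.year <= 2012:
                assert np.all(s.mussel_sizes_mm == 40.0)
                assert s.mussel_cover == 5.0
            if s.year >= 2013:
                assert np.all(s.mussel_sizes_mm == 50.0)
                assert s.mussel_cover == 18.0

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError):
            IntertidalConfig(pre_years=(2009, 2014), post_years=(2013, 2021))

    def test_same_seed_identical(self):
        a = simulate_intertidal(seed=2)
        b = simulate_intertidal(seed=2)
        assert all(
            np.array_equal(x.mussel_sizes_mm, y.mussel_sizes_mm)
            and x.grid_presence.equals(y.grid_presence)
            for x, y in zip(a, b)
        )


class TestCensus:
    def test_gap_years_absent(self):
        c = simulate_census(seed=0)
        assert 2011 not in c.years and 2020 not in c.years
        assert c.years.min() == 2000 and c.years.max() == 2024

    def test_zero_sd_gives_exact_pre_mean(self):
        cfg = CensusConfig(pre_sd=0.0, post_sd=0.0)
        c = simulate_census(cfg, seed=0)
        assert np.all(c.counts[c.years < 2013] == 373)
        assert np.all(c.counts[c.years >= 2013] == 535)

    def test_replicate_grand_mean_near_configured(self):
        post_means = [
            simulate_census(seed=s).counts[simulate_census(seed=s).years >= 2013].mean()
            for s in range(1000)
        ]
        grand = np.mean(post_means)
        assert abs(grand - 535) / 535 < 0.02

    def test_same_seed_identical(self):
        a = simulate_census(seed=11)
        b = simulate_census(seed=11)
        np.testing.assert_array_equal(a.counts, b.counts)
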