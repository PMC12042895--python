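"""Patch-choice primitives: encounter model, allocation, Dirichlet precision."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otterforage import (
    DegenerateAllocationError,
    allocation_probabilities,
    dirichlet_mle,
    dirichlet_precision,
    encounter_probability,
    simulate_dives,
)
from otterforage.foraging import DegenerateDrawsWarning


class TestEncounterProbability:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (0.0, 0.0),
            (np.log(2.0), 0.5),
            (2.0, 1.0 - np.exp(-2.0)),   # 0.864664...
        ],
    )
    def test_closed_form(self, delta, expected):
        assert encounter_probability(delta) == pytest.approx(expected, abs=1e-12)

    def test_matches_poisson_encounter_simulation(self, rng):
        # independent check: a patch is encountered iff a Poisson(delta)
        # count of patch arrivals during the dive is nonzero
        delta = 2.0
        n = 1_000_000
        hit = (rng.poisson(delta, n) > 0).mean()
        se = np.sqrt(hit * (1 - hit) / n)
        assert abs(encounter_probability(delta) - hit) < 3 * se

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 10, 200)
        lam = encounter_probability(d)
        assert np.all(np.diff(lam) > 0)
        assert np.all((lam >= 0) & (lam < 1))

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            encounter_probability(-0.1)


class TestAllocationProbabilities:
    def test_single_prey(self):
        av = allocation_probabilities(np.array([5.0]), np.array([0.3]))
        assert av.pi == pytest.approx([0.3])
        assert av.eta == pytest.approx([1.0])

    def test_two_prey_enumeration(self):
        # four encounter outcomes enumerated by hand: the better prey wins
        # whenever encountered, the worse only when alone
        av = allocation_probabilities(np.array([10.0, 5.0]), np.array([0.5, 0.5]))
        assert av.pi == pytest.approx([0.5, 0.25])
        assert av.eta == pytest.approx([2 / 3, 1 / 3])

    def test_exact_ties_exclude_neither(self):
        av = allocation_probabilities(np.array([7.0, 7.0]), np.array([0.4, 0.2]))
        assert av.pi == pytest.approx([0.4, 0.2])

    def test_tie_tolerance_widens_ties(self):
        E = np.array([7.0, 7.05])
        lam = np.array([0.4, 0.2])
        strict = allocation_probabilities(E, lam, tie_tol=0.0)
        loose = allocation_probabilities(E, lam, tie_tol=0.1)
        assert strict.pi[0] < lam[0]          # excluded by the slightly better prey
        assert loose.pi == pytest.approx(lam)  # within tolerance: a tie

    def test_all_zero_encounters_degenerate(self):
        with pytest.raises(DegenerateAllocationError):
            allocation_probabilities(np.array([2.0, 1.0]), np.zeros(2))

    @pytest.mark.parametrize("bad_lam", [[-0.1, 0.5], [0.5, 1.0]])
    def test_rejects_invalid_lambda(self, bad_lam):
        with pytest.raises(ValueError):
            allocation_probabilities(np.array([2.0, 1.0]), np.array(bad_lam))

    @given(st.integers(min_value=2, max_value=6), st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_total_equals_any_encounter_probability(self, k, seed):
        # with distinct profitabilities every dive with >= 1 encounter is
        # allocated somewhere: sum(pi) = 1 - prod(1 - lambda)
        r = np.random.default_rng(seed)
        E = r.permutation(np.linspace(1, 10, k))
        lam = r.uniform(0.05, 0.9, k)
        av = allocation_probabilities(E, lam)
        assert av.pi.sum() == pytest.approx(1 - np.prod(1 - lam), rel=1e-12)
        assert av.eta.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(av.pi <= lam + 1e-12)

    def test_expected_energy_monotone_in_each_lambda(self, rng):
        # raising any prey's encounter probability cannot lower the
        # unnormalized expected per-dive energy
        for _ in range(20):
            k = rng.integers(2, 6)
            E = rng.uniform(1, 10, k)
            lam = rng.uniform(0.05, 0.8, k)
            base = (allocation_probabilities(E, lam).pi * E).sum()
            for i in range(k):
                lam2 = lam.copy()
                lam2[i] = min(lam2[i] + 0.05, 0.95)
                bumped = (allocation_probabilities(E, lam2).pi * E).sum()
                assert bumped >= base - 1e-12

    def test_matches_dive_simulator(self, rng):
        # Monte-Carlo oracle: Bernoulli encounters, take the best prey
        for _ in range(3):
            k = int(rng.integers(2, 6))
            E = rng.permutation(np.linspace(1, 9, k))
            lam = rng.uniform(0.05, 0.7, k)
            av = allocation_probabilities(E, lam)
            sim = simulate_dives(E, lam, 200_000, rng)
            z = np.abs(av.eta - sim.eta_hat) / np.maximum(sim.eta_se, 1e-9)
            assert np.all(z < 4)


class TestDirichletPrecision:
    def test_recovers_generating_precision(self, rng):
        draws = rng.dirichlet(50 * np.array([0.2, 0.3, 0.5]), size=10_000)
        assert 45 <= dirichlet_precision(draws) <= 55

    def test_recovers_two_component_precision(self, rng):
        draws = rng.dirichlet(20 * np.array([0.5, 0.5]), size=10_000)
        assert 17 <= dirichlet_precision(draws) <= 23

    def test_monotone_in_concentration(self, rng):
        p = np.array([0.25, 0.35, 0.40])
        loose = dirichlet_precision(rng.dirichlet(5 * p, size=2000))
        tight = dirichlet_precision(rng.dirichlet(500 * p, size=2000))
        assert tight > loose

    def test_identical_rows_capped_with_warning(self):
        draws = np.tile([0.2, 0.3, 0.5], (100, 1))
        with pytest.warns(DegenerateDrawsWarning):
            tau = dirichlet_precision(draws, cap=1e8)
        assert tau == 1e8

    def test_requires_enough_simplex_rows(self, rng):
        with pytest.raises(ValueError):
            dirichlet_precision(rng.dirichlet([1, 1], size=10))
        bad = rng.dirichlet([1, 1, 1], size=100)
        bad[0] *= 2.0
        with pytest.raises(ValueError):
            dirichlet_precision(bad)

    def test_mle_concentrations_close_to_truth(self, rng):
        alpha = np.array([4.0, 10.0, 26.0])
        draws = rng.dirichlet(alpha, size=20_000)
        fit = dirichlet_mle(draws)
        assert np.all(np.abs(fit - alpha) / alpha < 0.1)
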