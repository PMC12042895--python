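"""Bioenergetic derived quantities and counterfactual prey-dynamics scenarios.

Given a fitted posterior, this module computes the mean overall rate of
energy intake for an optimally foraging otter,

    Ebar_t = sum_i eta_{i,t} * E_i       (kcal per minute of feeding effort)

and per-capita predation rates

    P_{i,t} = eta_{i,t} * E_i / G_i      (items of prey i per minute)

where ``G_i`` is the mean energy content of one consumed item. The headline
statistics use the normalized effort allocation ``eta``; the unnormalized
variant (``pi`` in place of ``eta``, which differs by the yearly factor
``sum_i pi_{i,t}``) is available via a flag.

Counterfactual scenarios freeze chosen prey at their pre-disturbance density
range: for every posterior draw, post-cutoff log densities of frozen prey
are replaced by i.i.d. normal draws whose mean and variance come from that
same draw's reference-window (default 2007-2012) estimates. The process
model is then re-resolved draw by draw, so encounter probabilities and
allocations reflect optimal foraging under the altered prey field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorSamples, allocation_from_draws
from .synthetic import ObservedForaging, PreyProfile

__all__ = [
    "PreyItemValue",
    "ScenarioSpec",
    "ScenarioResult",
    "item_values_from_profiles",
    "mean_energy_intake",
    "predation_rate",
    "counterfactual_densities",
    "resolve_scenario",
    "SCENARIO_FROZEN_PREY",
]

# canonical scenario names -> frozen prey
SCENARIO_FROZEN_PREY = {
    "baseline": (),
    "no_urchin_increase": ("urchin",),
    "no_mussel_increase": ("mussel",),
    "neither": ("urchin", "mussel"),
}


@dataclass
class PreyItemValue:
    """Mean kcal per consumed item of one prey type.

    ``G`` is caloric density times edible biomass at mean size; ``G_draws``
    (optional) carries item-value uncertainty propagated from size and
    caloric-density draws, one per posterior draw.
    """

    prey_id: str
    G: float
    G_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("item energy G must be positive")
        if self.G_draws is not None and np.any(self.G_draws <= 0):
            raise ValueError("all G draws must be positive")


def item_values_from_profiles(
    profiles: list[PreyProfile],
    obs: ObservedForaging | None = None,
    n_draws: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, PreyItemValue]:
    """Item energy values, optionally with propagated size/caloric draws.

    When ``obs`` and ``n_draws`` are given, each posterior draw is paired
    with one size draw and one caloric-density draw (resampled with ``rng``)
    so that item-value variance propagates into predation rates.
    """
    out: dict[str, PreyItemValue] = {}
    for p in profiles:
        G = float(p.item_energy_kcal())
        draws = None
        if obs is not None and n_draws is not None:
            if rng is None:
                rng = np.random.default_rng(0)
            i = obs.prey_ids.index(p.prey_id)
            pick = rng.integers(0, obs.size_draws.shape[1], size=n_draws)
            draws = np.maximum(
                obs.cal_draws[i, pick] * p.edible_biomass_g(obs.size_draws[i, pick]),
                1e-9,
            )
        out[p.prey_id] = PreyItemValue(prey_id=p.prey_id, G=G, G_draws=draws)
    return out


@dataclass
class ScenarioSpec:
    """A named counterfactual prey-dynamics scenario."""

    name: str
    frozen_prey: tuple[str, ...] = ()
    cutoff_year: int = 2012
    reference_years: tuple[int, int] = (2007, 2012)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_years[0] > self.reference_years[1]:
            raise ValueError("reference_years must be an increasing range")
        if self.reference_years[1] > self.cutoff_year:
            raise ValueError("reference years must precede the cutoff")

    @classmethod
    def named(cls, name: str, seed: int = 0, **kw) -> "ScenarioSpec":
        if name not in SCENARIO_FROZEN_PREY:
            raise ValueError(f"unknown scenario {name!r}")
        return cls(name=name, frozen_prey=SCENARIO_FROZEN_PREY[name],
                   seed=seed, **kw)


@dataclass
class ScenarioResult:
    """Per-year energy intake and predation rates under one scenario."""

    name: str
    years: np.ndarray
    energy_mean: np.ndarray      # (T,) point estimate of Ebar_t, kcal/min
    energy_lo: np.ndarray
    energy_hi: np.ndarray
    predation: pd.DataFrame      # prey_id, year, mean, lo95, hi95 (items/min)
    effort: pd.DataFrame         # prey_id, year, mean, lo95, hi95 (eta)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year energy table (year, statistic, mean, lo95, hi95)."""
        return pd.DataFrame({
            "scenario": self.name, "year": self.years,
            "statistic": "energy_intake_kcal_min",
            "mean": self.energy_mean, "lo95": self.energy_lo,
            "hi95": self.energy_hi,
        })


def mean_energy_intake(alloc, E, normalized: bool = True) -> float:
    """Mean overall rate of energy intake, ``sum_i a_i * E_i`` (kcal/min).

    Uses the normalized effort allocation ``eta`` by default; with
    ``normalized=False`` uses the unnormalized per-dive probabilities ``pi``
    (expected kcal per dive-minute including empty dives).
    """
    E = np.asarray(E, dtype=float)
    a = np.asarray(alloc.eta if normalized else alloc.pi, dtype=float)
    if a.shape != E.shape:
        raise ValueError("allocation and E must be aligned")
    return float(np.sum(a * E))


def predation_rate(eta_i: float, E_i: float, G_i: float) -> float:
    """Expected items of a prey type consumed per minute, ``eta*E/G``."""
    if G_i <= 0:
        raise ValueError("item energy G must be positive")
    return float(eta_i) * float(E_i) / float(G_i)


def counterfactual_densities(
    ps: PosteriorSamples, spec: ScenarioSpec
) -> np.ndarray:
    """Adjusted log-density draws under a freeze scenario.

    For every posterior draw, each frozen prey's post-cutoff ``Delta``
    values are replaced by i.i.d. normal draws whose mean and standard
    deviation are that draw's own reference-window estimates; unfrozen prey
    (and the baseline scenario, with no frozen prey) are returned untouched.
    Deterministic for a fixed ``spec.seed``.
    """
    unknown = set(spec.frozen_prey) - set(ps.prey_ids)
    if unknown:
        raise ValueError(f"scenario freezes unfitted prey: {sorted(unknown)}")
    Delta = ps.Delta
    if not spec.frozen_prey:
        return Delta
    years = ps.years
    ref = (years >= spec.reference_years[0]) & (years <= spec.reference_years[1])
    if not ref.any():
        raise ValueError("empty reference window")
    post = years > spec.cutoff_year
    if not post.any():
        return Delta

    rng = np.random.default_rng(spec.seed)
    out = Delta.copy()
    n = Delta.shape[0]
    for prey in spec.frozen_prey:
        i = ps.prey_ids.index(prey)
        refvals = Delta[:, i, ref]                      # (n_draws, n_ref)
        m = refvals.mean(axis=1)
        s = refvals.std(axis=1, ddof=0)
        out[:, i, post] = rng.normal(
            m[:, None], s[:, None], size=(n, int(post.sum()))
        )
    return out


def resolve_scenario(
    ps: PosteriorSamples,
    spec: ScenarioSpec,
    item_values: dict[str, PreyItemValue],
    normalized_energy: bool = True,
) -> ScenarioResult:
    """Resolve the process model under a scenario, draw by draw.

    Applies the counterfactual density adjustment, recomputes encounter
    probabilities and allocations for every posterior draw, then summarizes
    ``Ebar_t`` and ``P_{i,t}`` as posterior means with 95% credible
    intervals. The baseline scenario takes no resampling path and therefore
    reproduces the fitted model's values exactly.
    """
    missing = set(ps.prey_ids) - set(item_values)
    if missing:
        raise ValueError(f"item values missing for prey: {sorted(missing)}")
    Delta = counterfactual_densities(ps, spec)
    pi, eta = allocation_from_draws(ps.mu, Delta, ps.config.tie_tol)
    E = np.exp(ps.mu)                                   # (n_draws, K)
    alloc = eta if normalized_energy else pi
    energy = (alloc * E[:, :, None]).sum(axis=1)        # (n_draws, T)

    n, K, T = pi.shape
    G = np.empty((n, K))
    for i, p in enumerate(ps.prey_ids):
        iv = item_values[p]
        if iv.G_draws is not None:
            if len(iv.G_draws) != n:
                raise ValueError(
                    f"G draw count for {p} ({len(iv.G_draws)}) != posterior "
                    f"draw count ({n})"
                )
            G[:, i] = iv.G_draws
        else:
            G[:, i] = iv.G
    pred = alloc * E[:, :, None] / G[:, :, None]        # (n_draws, K, T)

    def _summ(draws, label):
        mean = draws.mean(axis=0)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        rows = []
        for i, p in enumerate(ps.prey_ids):
            for t, y in enumerate(ps.years):
                rows.append((spec.name, p, int(y), mean[i, t], lo[i, t], hi[i, t]))
        return pd.DataFrame(
            rows, columns=["scenario", "prey_id", "year", "mean", "lo95", "hi95"]
        )

    e_lo, e_hi = np.percentile(energy, [2.5, 97.5], axis=0)
    return ScenarioResult(
        name=spec.name, years=ps.years.copy(),
        energy_mean=energy.mean(axis=0), energy_lo=e_lo, energy_hi=e_hi,
        predation=_summ(pred, "predation"), effort=_summ(eta, "effort"),
    )
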