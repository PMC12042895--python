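import warnings

import numpy as np
import pytest

from otterforage import (
    GroundTruthConfig,
    ModelConfig,
    PosteriorSamples,
    PreyProfile,
    RegimeShift,
)

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_prey(k: int = 4) -> list[PreyProfile]:
    base = [
        PreyProfile("crab", 2.2, 1.1, 100, 20, 1.6e-4),
        PreyProfile("clam", 1.8, 0.9, 60, 12, 1.5e-4),
        PreyProfile("urchin", 1.5, 1.1, 55, 12, 1.8e-4),
        PreyProfile("mussel", 1.2, 0.85, 55, 15, 1.2e-4),
        PreyProfile("snail", 1.0, 0.95, 30, 8, 2.0e-4),
    ]
    return base[:k]


def small_truth_config(**overrides) -> GroundTruthConfig:
    kw = dict(
        prey=small_prey(4),
        base_delta={"crab": -2.2, "clam": -1.9, "urchin": -1.3, "mussel": -2.0},
        year_start=2007,
        year_end=2014,
        sigma_D=0.15,
        sigma_E=0.10,
        tau=300.0,
        regime_shifts=[RegimeShift("urchin", 2014, 1, 0.8)],
    )
    kw.update(overrides)
    return GroundTruthConfig(**kw)


def fake_posterior(
    rng: np.random.Generator,
    prey_ids=("crab", "urchin", "mussel"),
    mu=(2.2, 1.5, 1.2),
    years=np.arange(2007, 2017),
    n_draws: int = 400,
    delta_loc: float = -1.5,
    delta_scale: float = 0.2,
) -> PosteriorSamples:
    """Hand-built posterior draws for scenario-engine tests (no MCMC)."""
    K, T = len(prey_ids), len(years)
    import pandas as pd

    return PosteriorSamples(
        prey_ids=list(prey_ids),
        years=np.asarray(years),
        mu=np.asarray(mu)[None, :] + 0.05 * rng.standard_normal((n_draws, K)),
        Delta=delta_loc + delta_scale * rng.standard_normal((n_draws, K, T)),
        sigma_D=np.full((n_draws, K), 0.1),
        sigma_E=np.full((n_draws, K), 0.1),
        tau=np.full(T, 300.0),
        diagnostics=pd.DataFrame(columns=["parameter", "rhat", "ess"]),
        config=ModelConfig(),
    )
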