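"""Brute-force dive simulator.

Independent Monte-Carlo check of the closed-form allocation model: each dive
draws Bernoulli(lambda_i) encounters per prey type and the otter takes the
most profitable prey encountered. Used as a cross-validation oracle against
:func:`otterforage.foraging.allocation_probabilities`, never as the
implementation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiveSimulation", "simulate_dives"]


@dataclass
class DiveSimulation:
    """Empirical allocation from simulated feeding dives.

    eta_hat / eta_se : proportion (and binomial SE) of successful dives
        allocated to each prey, conditioned on at least one encounter.
    p_any : fraction of dives with at least one encounter (estimates
        ``1 - prod(1 - lambda_i)``).
    energy_per_dive : mean energy of the chosen patch over *all* dives
        (zero when nothing is encountered) — estimates ``sum(pi_i * E_i)``.
    energy_per_success : mean energy conditioned on >= 1 encounter —
        estimates ``sum(eta_i * E_i)``.
    """

    eta_hat: np.ndarray
    eta_se: np.ndarray
    p_any: float
    energy_per_dive: float
    energy_per_dive_se: float
    energy_per_success: float
    energy_per_success_se: float
    n_dives: int
    n_success: int


def simulate_dives(
    E, lam, n_dives: int, rng: np.random.Generator, batch: int = 1_000_000
) -> DiveSimulation:
    """Simulate ``n_dives`` independent feeding dives.

    Encounters are independent Bernoulli(lambda_i) per dive; the chosen prey
    is the encountered type with the highest profitability ``E_i`` (ties
    broken toward the lower index, which only matters for exactly equal E).
    """
    E = np.asarray(E, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if E.shape != lam.shape or E.ndim != 1:
        raise ValueError("E and lambda must be 1-D arrays of equal length")
    K = E.size
    order = np.argsort(-E, kind="stable")  # best first

    counts = np.zeros(K, dtype=np.int64)
    energy_sum = 0.0
    energy_sq = 0.0
    done = 0
    while done < n_dives:
        n = min(batch, n_dives - done)
        enc = rng.random((n, K)) < lam[None, :]
        enc_sorted = enc[:, order]
        any_enc = enc_sorted.any(axis=1)
        # index (in profitability order) of the best encountered prey
        best = np.argmax(enc_sorted, axis=1)
        chosen = order[best[any_enc]]
        counts += np.bincount(chosen, minlength=K)
        e = E[chosen]
        energy_sum += e.sum()
        energy_sq += (e**2).sum()
        done += n

    n_success = int(counts.sum())
    if n_success == 0:
        raise RuntimeError("no dive encountered any prey; cannot estimate eta")
    eta_hat = counts / n_success
    eta_se = np.sqrt(eta_hat * (1 - eta_hat) / n_success)

    # per-dive energy treats empty dives as zero energy
    mean_dive = energy_sum / n_dives
    var_dive = max(energy_sq / n_dives - mean_dive**2, 0.0)
    mean_succ = energy_sum / n_success
    var_succ = max(energy_sq / n_success - mean_succ**2, 0.0)
    return DiveSimulation(
        eta_hat=eta_hat,
        eta_se=eta_se,
        p_any=n_success / n_dives,
        energy_per_dive=mean_dive,
        energy_per_dive_se=float(np.sqrt(var_dive / n_dives)),
        energy_per_success=mean_succ,
        energy_per_success_se=float(np.sqrt(var_succ / n_success)),
        n_dives=n_dives,
        n_success=n_success,
    )
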