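"""Optimal-foraging patch-choice primitives.

The process model treats each prey type *i* as a Poisson field of suitable
patches with effective density ``delta_i`` (the instantaneous encounter rate
for a foraging otter). On a single feeding dive the otter encounters a patch
of type *i* with probability ``lambda_i = 1 - exp(-delta_i)``; assuming it
always chooses the most profitable patch encountered, the probability that a
dive is allocated to prey *i* is the joint probability ``pi_i`` of
encountering *i* and nothing more profitable. Effort allocation ``eta`` is
``pi`` renormalized onto the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi, polygamma

__all__ = [
    "AllocationVector",
    "DegenerateAllocationError",
    "DegenerateDrawsWarning",
    "encounter_probability",
    "allocation_probabilities",
    "dirichlet_mle",
    "dirichlet_precision",
]


class DegenerateAllocationError(ValueError):
    """All encounter probabilities are zero: effort allocation is undefined."""


class DegenerateDrawsWarning(UserWarning):
    """Dirichlet draw matrix is (near-)degenerate; precision was capped."""


@dataclass
class AllocationVector:
    """Per-dive allocation probabilities for one year.

    Attributes
    ----------
    pi : unnormalized joint probabilities (encounter prey *i* and nothing
        more profitable); ``0 <= pi_i <= lambda_i`` and ``sum(pi) <= 1``.
    eta : ``pi`` normalized to the simplex — the expected proportion of
        feeding dives allocated to each prey type.
    """

    pi: np.ndarray
    eta: np.ndarray
    year: int | None = None
    prey_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.pi.shape != self.eta.shape:
            raise ValueError("pi and eta must have the same shape")


def encounter_probability(delta):
    """Finite per-dive probability of encountering a patch.

    ``lambda = 1 - exp(-delta)`` for an instantaneous encounter rate
    ``delta >= 0``; strictly increasing, in [0, 1).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("effective density (encounter rate) must be >= 0")
    out = -np.expm1(-delta)
    return float(out) if out.ndim == 0 else out


def allocation_probabilities(
    E, lam, tie_tol: float = 0.0, year: int | None = None,
    prey_ids: list[str] | None = None,
) -> AllocationVector:
    """Joint encounter-and-no-better probabilities and effort allocation.

    ``pi_i = lambda_i * prod_{j != i} (1 - lambda_j * W_ij)`` where the switch
    ``W_ij`` is 1 iff prey *j* is strictly more profitable than prey *i*
    (``E_j > E_i + tie_tol``). Exactly tied profitabilities do not exclude
    each other. ``eta`` is ``pi`` normalized to the simplex.

    Raises
    ------
    DegenerateAllocationError
        If every ``lambda_i`` is zero (no prey is ever encountered).
    """
    E = np.asarray(E, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if E.shape != lam.shape or E.ndim != 1:
        raise ValueError("E and lambda must be 1-D arrays of equal length")
    if E.size < 1:
        raise ValueError("need at least one prey type")
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("encounter probabilities must lie in [0, 1)")
    if tie_tol < 0:
        raise ValueError("tie_tol must be >= 0")

    W = E[None, :] > E[:, None] + tie_tol  # W[i, j]: j strictly better than i
    np.fill_diagonal(W, False)
    pi = lam * np.prod(1.0 - lam[None, :] * W, axis=1)
    total = pi.sum()
    if total <= 0.0:
        raise DegenerateAllocationError(
            "all encounter probabilities are zero; eta is undefined"
        )
    return AllocationVector(pi=pi, eta=pi / total, year=year, prey_ids=prey_ids)


def _inv_psi(y: np.ndarray) -> np.ndarray:
    """Inverse digamma by Newton iteration (Minka's initialization)."""
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - psi(1.0)))
    for _ in range(6):
        x = x - (psi(x) - y) / polygamma(1, x)
    return x


def dirichlet_mle(
    draws: np.ndarray,
    floor: float = 1e-6,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Maximum-likelihood Dirichlet concentration vector for simplex rows.

    Uses Minka's fixed-point iteration,
    ``psi(alpha_k_new) = psi(sum alpha) + mean(log p_k)``.
    Components are floored at ``floor`` and rows renormalized first, since an
    exact zero has -inf log density under any Dirichlet.
    """
    p = np.asarray(draws, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("draws must be a 2-D matrix with >= 2 rows")
    if np.any(p < 0):
        raise ValueError("draws must be nonnegative")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("each row must lie on the probability simplex")
    p = np.clip(p, floor, None)
    p /= p.sum(axis=1, keepdims=True)

    mean_log = np.log(p).mean(axis=0)
    # moment-matched start (Ronning / Minka)
    m = p.mean(axis=0)
    v = p.var(axis=0).mean()
    s0 = max(m.mean() * (1 - m.mean()) / max(v, 1e-12) - 1.0, 1.0)
    alpha = m * s0
    for _ in range(max_iter):
        new = _inv_psi(psi(alpha.sum()) + mean_log)
        if np.max(np.abs(new - alpha)) < tol * (1.0 + np.max(np.abs(alpha))):
            alpha = new
            break
        alpha = new
    return alpha


def dirichlet_precision(
    draw_matrix: np.ndarray,
    floor: float = 1e-6,
    cap: float = 1e8,
) -> float:
    """ML Dirichlet precision (sum of concentrations) for a draw matrix.

    Precomputed per year from effort-allocation posterior draws and then held
    fixed while the state-space model is fitted. Draw matrices whose rows are
    (numerically) identical imply an unbounded precision; those return ``cap``
    with a :class:`DegenerateDrawsWarning`.
    """
    p = np.asarray(draw_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] < 50:
        raise ValueError("need at least 50 simplex rows to fit a precision")
    if np.max(p.var(axis=0)) < 1e-14:
        warnings.warn(
            "draw rows are numerically identical; precision is unbounded "
            "and has been capped",
            DegenerateDrawsWarning,
        )
        return float(cap)
    tau = float(dirichlet_mle(p, floor=floor).sum())
    if tau > cap:
        warnings.warn(
            "fitted precision exceeds cap; returning capped value",
            DegenerateDrawsWarning,
        )
        return float(cap)
    return tau
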