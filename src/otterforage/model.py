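"""Bayesian state-space model of foraging effort and prey density.

Latent log effective densities ``Delta[i, t]`` follow independent Gaussian
random walks (innovation scale ``sigma_D[i]``); patch profitabilities are
constant on the log scale (``mu[i]``). The observation model ties these to
the emulated foraging-analysis outputs:

* observed log intake rates are ``Normal(mu_i, sigma_E_i)`` per prey-year;
* the observed yearly effort allocation is ``Dirichlet(tau_t * eta_t)``,
  where ``eta_t`` is the model-implied allocation (normalized joint
  encounter-and-no-better probabilities) and ``tau_t`` is a per-year
  precision fixed in advance by maximum likelihood on the allocation draws.

Priors are weakly informative: Cauchy on the log profitabilities,
half-Cauchy on the innovation and observation scales (truncated at
``sigma_max``: an unbounded half-Cauchy leaves the posterior improper for
short series, because the effort likelihood is flat along a common per-year
density shift whose prior volume grows faster than the scale prior decays),
and a normal prior on
the initial log densities centred on ecologically plausible encounter
rates — the effort likelihood is invariant to the overall density scale, so
this prior is what identifies it.

Sampling uses a blocked adaptive Metropolis-within-Gibbs scheme written for
this model's geometry:

* per-year blocks of latent densities on a checkerboard (odd/even years
  are conditionally independent given their neighbours under the random
  walk), with Haario-style covariance adaptation;
* exact moves along the likelihood-flat manifold (any common per-year
  shift of log pi leaves the allocation likelihood invariant): a grid
  independence sampler for the constant mode, adapted random walks for
  low-frequency cosine modes and for the per-year flat-field levels;
* whole-path, tail (from a random breakpoint) and uniform global shifts of
  the log densities, which let regime-like transitions renegotiate;
* profitabilities as a joint block;
* the innovation scales both conditionally (centered) and through a
  centered/non-centered interweaving move that rescales each prey's latent
  path about a random anchor year — without which the scale parameters mix
  pathologically (the classic state-space funnel).

Proposal scales adapt toward target acceptance rates during warmup only.
Convergence is assessed with rank-normalized R-hat and bulk effective
sample size (arviz) over independent chains, and the fit fails loudly when
the configured thresholds are violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .foraging import dirichlet_precision
from .synthetic import ObservedForaging

__all__ = [
    "ModelConfig",
    "PosteriorSamples",
    "PosteriorAllocation",
    "ConvergenceError",
    "fit_model",
    "posterior_allocation",
    "allocation_from_draws",
]


class ConvergenceError(RuntimeError):
    """The sampler failed the configured convergence thresholds."""


@dataclass
class ModelConfig:
    """Priors, sampler controls, and convergence thresholds."""

    chains: int = 4
    n_warmup: int = 1500               # adaptation sweeps, discarded
    n_steps: int = 3000                # post-warmup sweeps per chain
    thin: int = 3
    seed: int = 0
    cauchy_scale: float = 2.5          # prior scale for mu
    sigma_scale: float = 2.5           # half-Cauchy scale for sigma_D, sigma_E
    sigma_max: float = 1.0             # truncation of the scale priors
    delta0_loc: float = -1.8           # prior centre for initial log density
    delta0_scale: float = 1.0          # prior scale for initial log density
    tie_tol: float = 0.0
    eta_floor: float = 1e-6
    max_rhat: float = 1.01
    min_ess: float = 400.0
    min_acceptance: float = 0.02
    enforce_convergence: bool = True

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        for name in ("max_rhat", "min_ess", "cauchy_scale", "sigma_scale",
                     "delta0_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# vectorized model math
# ---------------------------------------------------------------------------

def _log_allocation(mu: np.ndarray, Delta: np.ndarray, tie_tol: float):
    """log pi and log eta for batched parameters.

    mu: (..., K); Delta: (..., K, T). ``pi_i = lam_i * prod_{j better}
    (1 - lam_j)`` computed on the log scale; note ``log(1 - lam_j) =
    -delta_j`` exactly under the encounter model.
    """
    delta = np.exp(Delta)
    lam = -np.expm1(-delta)
    with np.errstate(divide="ignore"):
        log_lam = np.log(lam)
    log1m_lam = -delta
    W = (mu[..., None, :] > mu[..., :, None] + tie_tol).astype(float)
    excl = np.einsum("...ij,...jt->...it", W, log1m_lam)
    log_pi = log_lam + excl
    log_eta = log_pi - logsumexp(log_pi, axis=-2, keepdims=True)
    return log_pi, log_eta


def allocation_from_draws(
    mu: np.ndarray, Delta: np.ndarray, tie_tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (pi, eta) arrays of shape (n_draws, K, T)."""
    log_pi, log_eta = _log_allocation(
        np.asarray(mu, float), np.asarray(Delta, float), tie_tol
    )
    return np.exp(log_pi), np.exp(log_eta)


class _ModelData:
    """Observed data and fixed hyperparameters, with likelihood pieces."""

    def __init__(self, eta_obs, mu_obs, tau, config: ModelConfig):
        self.eta_obs = eta_obs                    # (T, K) floored simplex
        self.log_eta_obs_T = np.log(eta_obs).T    # (K, T)
        self.mu_obs = mu_obs                      # (K, T), NaN = missing
        self.obs_mask = np.isfinite(mu_obs)
        self.mu_obs_filled = np.where(self.obs_mask, mu_obs, 0.0)
        self.n_obs = self.obs_mask.sum(axis=1)    # per prey
        self.tau = tau                            # (T,)
        self.cfg = config
        self.K, self.T = mu_obs.shape

    def dirichlet_ll(self, W, Delta, t_idx=None) -> np.ndarray:
        """Per-year Dirichlet log likelihood, shape (C, S).

        ``W`` is the (C, K, K) profitability switch matrix; ``t_idx``
        selects a subset of years (checkerboard updates).
        """
        if t_idx is None:
            D = Delta
            tau = self.tau
            log_obs = self.log_eta_obs_T
        else:
            D = Delta[:, :, t_idx]
            tau = self.tau[t_idx]
            log_obs = self.log_eta_obs_T[:, t_idx]
        delta = np.exp(D)
        lam = -np.expm1(-delta)
        with np.errstate(divide="ignore"):
            log_lam = np.log(lam)
        excl = np.einsum("cij,cjs->cis", W, -delta)
        log_pi = log_lam + excl
        log_eta = log_pi - logsumexp(log_pi, axis=1, keepdims=True)
        alpha = tau[None, None, :] * np.exp(log_eta)
        ll = (
            gammaln(tau)[None, :]
            - gammaln(alpha).sum(axis=1)
            + ((alpha - 1.0) * log_obs[None, :, :]).sum(axis=1)
        )
        return np.where(np.isfinite(ll), ll, -np.inf)

    def intake_ll_per_prey(self, mu, log_sE) -> np.ndarray:
        """(C, K) Gaussian log likelihood of observed log intake rates."""
        sE = np.exp(log_sE)
        resid = (self.mu_obs_filled[None] - mu[:, :, None]) / sE[:, :, None]
        ll = np.where(self.obs_mask[None], -0.5 * resid**2, 0.0).sum(axis=2)
        return ll - self.n_obs[None, :] * log_sE

    def rw_ll_per_prey(self, Delta, log_sD) -> np.ndarray:
        """(C, K) random-walk log density of the latent paths."""
        sD = np.exp(log_sD)
        diff = np.diff(Delta, axis=2)
        return (
            -0.5 * (diff / sD[:, :, None]) ** 2
        ).sum(axis=2) - (self.T - 1) * log_sD

    def switch(self, mu) -> np.ndarray:
        W = (mu[:, None, :] > mu[:, :, None] + self.cfg.tie_tol).astype(float)
        for c in range(W.shape[0]):
            np.fill_diagonal(W[c], 0.0)
        return W

    def mu_prior(self, mu) -> np.ndarray:
        return -np.log1p((mu / self.cfg.cauchy_scale) ** 2).sum(axis=1)

    def sigma_prior(self, log_s) -> np.ndarray:
        """(C, K) half-Cauchy prior with the log-transform Jacobian."""
        s = np.exp(log_s)
        return -np.log1p((s / self.cfg.sigma_scale) ** 2) + log_s


# ---------------------------------------------------------------------------
# blocked adaptive Metropolis-within-Gibbs
# ---------------------------------------------------------------------------

class _GibbsSampler:
    """Blocked sampler over (mu, Delta, log sigma_D, log sigma_E)."""

    TARGET_BLOCK = 0.25
    TARGET_SCALAR = 0.44

    def __init__(self, data: _ModelData, x0: dict, config: ModelConfig,
                 rng: np.random.Generator):
        self.d = data
        self.cfg = config
        self.rng = rng
        C = config.chains
        K, T = data.K, data.T
        # dispersed initialization around the data-driven point
        self.mu = x0["mu"][None] + 0.1 * rng.standard_normal((C, K))
        self.Delta = x0["Delta"][None] + 0.2 * rng.standard_normal((C, K, T))
        self.log_sD = x0["log_sD"][None] + 0.3 * rng.standard_normal((C, K))
        self.log_sE = x0["log_sE"][None] + 0.3 * rng.standard_normal((C, K))
        self.W = data.switch(self.mu)
        # adaptive proposal scales
        self.s_year = np.full(T, 0.1)
        self.s_ridge = np.full(T, 0.5)
        self.s_mu = 0.02
        self.s_sd = np.full(K, 0.3)
        self.s_se = np.full(K, 0.3)
        self.s_nc = np.full(K, 0.15)
        self.s_glob = 0.3
        self.s_path = np.full(K, 0.3)
        self.s_flat_year = np.full(T, 0.1)
        self.s_flat_mode = np.full(8, 0.3)
        self.s_tail = np.full(K, 0.3)
        # Haario-style running covariance per year block: the per-year
        # posterior mixes tightly constrained directions with a weakly
        # identified overall-density ridge, so identity proposals mix
        # pathologically; covariance-shaped proposals track both.
        self._cov_n = 0
        self._cov_mean = np.zeros((T, K))
        self._cov_m2 = np.zeros((T, K, K))
        self._chol = np.broadcast_to(np.eye(K), (T, K, K)).copy()

    def _update_block_cov(self):
        """Welford update of per-year covariance, pooled across chains."""
        T, K = self.d.T, self.d.K
        for x in self.Delta.transpose(0, 2, 1):        # each chain: (T, K)
            self._cov_n += 1
            d = x - self._cov_mean
            self._cov_mean += d / self._cov_n
            self._cov_m2 += d[:, :, None] * (x - self._cov_mean)[:, None, :]
        if self._cov_n > 50 and self._cov_n % 10 == 0:
            cov = self._cov_m2 / (self._cov_n - 1)
            cov += 1e-6 * np.eye(K)[None]
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:   # pragma: no cover
                pass

    # -- update moves -------------------------------------------------------

    def _year_blocks(self, parity: int, adapt_gamma: float | None,
                     ridge: bool = False):
        """Checkerboard update of per-year latent-density columns.

        ``ridge=True`` proposes a common shift of all prey within a year —
        the weakly identified overall-density direction that the Dirichlet
        likelihood constrains only through curvature — with its own adapted
        scalar scale; the regular move proposes covariance-shaped jumps.
        """
        d, rng = self.d, self.rng
        C, K, T = self.mu.shape[0], d.K, d.T
        t_idx = np.arange(parity, T, 2)
        S = t_idx.size
        cur = self.Delta[:, :, t_idx]
        if ridge:
            step = np.broadcast_to(
                rng.standard_normal((C, 1, S)), (C, K, S)
            )
            prop = cur + self.s_ridge[t_idx][None, None, :] * step
        else:
            eps = rng.standard_normal((C, S, K))
            step = np.einsum("skj,csj->cks", self._chol[t_idx], eps)
            prop = cur + self.s_year[t_idx][None, None, :] * step

        ll_cur = d.dirichlet_ll(self.W, self.Delta, t_idx)
        Dp = self.Delta.copy()
        Dp[:, :, t_idx] = prop
        ll_new = d.dirichlet_ll(self.W, Dp, t_idx)

        # local random-walk prior terms (neighbours have opposite parity)
        sD = np.exp(self.log_sD)[:, :, None]

        def local_prior(D):
            out = np.zeros((C, K, S))
            left = t_idx - 1
            ok = left >= 0
            out[:, :, ok] += -0.5 * (
                (D[:, :, t_idx[ok]] - D[:, :, left[ok]]) / sD
            ) ** 2
            if not ok[0]:
                out[:, :, 0] += -0.5 * (
                    (D[:, :, 0] - self.cfg.delta0_loc) / self.cfg.delta0_scale
                ) ** 2
            right = t_idx + 1
            ok = right < T
            out[:, :, ok] += -0.5 * (
                (D[:, :, right[ok]] - D[:, :, t_idx[ok]]) / sD
            ) ** 2
            return out.sum(axis=1)      # (C, S)

        log_r = (ll_new - ll_cur) + local_prior(Dp) - local_prior(self.Delta)
        accept = np.log(rng.random((C, S))) < log_r
        for s, t in enumerate(t_idx):
            self.Delta[accept[:, s], :, t] = prop[accept[:, s], :, s]
        if adapt_gamma is not None:
            rate = accept.mean(axis=0)
            if ridge:
                self.s_ridge[t_idx] *= np.exp(
                    adapt_gamma * (rate - self.TARGET_SCALAR)
                )
            else:
                self.s_year[t_idx] *= np.exp(
                    adapt_gamma * (rate - self.TARGET_BLOCK)
                )

    # -- flat-manifold machinery -------------------------------------------
    #
    # The Dirichlet effort likelihood depends on the latent densities only
    # through the normalized allocation, so shifting every ``log pi`` within
    # a year by a common constant leaves it exactly invariant: the overall
    # allocation scale is identified only by the priors, and generic moves
    # crawl along this curved valley. The moves below travel the valley
    # exactly: shift ``log pi``, invert back to ``Delta`` (sequentially in
    # profitability order), and weight by the random-walk/initial priors and
    # the triangular Jacobian of the ``log pi -> Delta`` map; the likelihood
    # cancels identically.

    def _current_xi(self):
        delta = np.exp(self.Delta)
        lam = -np.expm1(-delta)
        with np.errstate(divide="ignore"):
            xi = np.log(lam) + np.einsum("cij,cjt->cit", self.W, -delta)
        return xi

    def _fiber_logf(self, xi, shifts):
        """Evaluate points on each chain's flat fiber.

        xi: (C, K, T) current log pi; shifts: (C, G, T) per-year log-pi
        shifts. Returns (Delta_new (C,G,K,T), ok (C,G), logf (C,G)) where
        logf is the within-fiber density: latent priors plus the log
        Jacobian determinant of the coordinate map.
        """
        C, K, T = xi.shape
        G = shifts.shape[1]
        order = np.argsort(-self.mu, axis=1, kind="stable")      # (C, K)
        xi_g = xi[:, None, :, :] + shifts[:, :, None, :]         # (C,G,K,T)
        pi_s = np.exp(
            np.take_along_axis(xi_g, order[:, None, :, None], axis=2)
        )
        lam_s = np.empty_like(pi_s)
        P = np.ones((C, G, T))
        ok = np.ones((C, G), dtype=bool)
        for k in range(K):
            lk = pi_s[:, :, k, :] / np.maximum(P, 1e-300)
            lam_s[:, :, k, :] = lk
            ok &= np.all((lk > 0) & (lk < 1.0 - 1e-9), axis=-1)
            P = P * (1.0 - lk)
        lam_s = np.clip(lam_s, 1e-300, 1.0 - 1e-15)
        inv = np.argsort(order, axis=1)
        lam_new = np.take_along_axis(lam_s, inv[:, None, :, None], axis=2)
        delta_new = -np.log1p(-lam_new)
        Delta_new = np.log(delta_new)

        # diag of the triangular Jacobian d Delta / d log pi
        log_det = (
            np.log(lam_new) - np.log1p(-lam_new) - np.log(delta_new)
        ).sum(axis=(2, 3))
        sD = np.exp(self.log_sD)
        rw = (
            -0.5 * (np.diff(Delta_new, axis=3) / sD[:, None, :, None]) ** 2
        ).sum(axis=(2, 3))
        d0 = (
            -0.5 * (((Delta_new[:, :, :, 0] - self.cfg.delta0_loc)
                     / self.cfg.delta0_scale) ** 2)
        ).sum(axis=2)
        logf = np.where(ok, rw + d0 + log_det, -np.inf)
        return Delta_new, ok, np.where(np.isfinite(logf), logf, -np.inf)

    _FLAT_GRID = np.linspace(-4.0, 4.0, 49)

    def _fiber_logf_per_year(self, xi, shifts):
        """Per-year fiber evaluation for checkerboard flat-field updates.

        Like :meth:`_fiber_logf` but returns per-year components
        (Delta_new (C,G,K,T), ok (C,G,T), logf (C,G,T)) where the
        random-walk terms couple each shifted year to the *current* values
        of its neighbours — the correct conditional when the opposite
        parity is held fixed.
        """
        C, K, T = xi.shape
        G = shifts.shape[1]
        order = np.argsort(-self.mu, axis=1, kind="stable")
        xi_g = xi[:, None, :, :] + shifts[:, :, None, :]
        pi_s = np.exp(
            np.take_along_axis(xi_g, order[:, None, :, None], axis=2)
        )
        lam_s = np.empty_like(pi_s)
        P = np.ones((C, G, T))
        ok = np.ones((C, G, T), dtype=bool)
        for k in range(K):
            lk = pi_s[:, :, k, :] / np.maximum(P, 1e-300)
            lam_s[:, :, k, :] = lk
            ok &= (lk > 0) & (lk < 1.0 - 1e-9)
            P = P * (1.0 - lk)
        lam_s = np.clip(lam_s, 1e-300, 1.0 - 1e-15)
        inv = np.argsort(order, axis=1)
        lam_new = np.take_along_axis(lam_s, inv[:, None, :, None], axis=2)
        delta_new = -np.log1p(-lam_new)
        Delta_new = np.log(delta_new)

        log_det = (
            np.log(lam_new) - np.log1p(-lam_new) - np.log(delta_new)
        ).sum(axis=2)                                       # (C,G,T)
        sD = np.exp(self.log_sD)[:, None, :, None]          # (C,1,K,1)
        cur = self.Delta[:, None, :, :]
        rw = np.zeros((C, G, T))
        rw[:, :, 1:] += (
            -0.5 * ((Delta_new[:, :, :, 1:] - cur[:, :, :, :-1]) / sD) ** 2
        ).sum(axis=2)
        rw[:, :, :-1] += (
            -0.5 * ((cur[:, :, :, 1:] - Delta_new[:, :, :, :-1]) / sD) ** 2
        ).sum(axis=2)
        rw[:, :, 0] += (
            -0.5 * (((Delta_new[:, :, :, 0] - self.cfg.delta0_loc)
                     / self.cfg.delta0_scale) ** 2)
        ).sum(axis=2)
        logf = np.where(ok, log_det + rw, -np.inf)
        return Delta_new, ok, np.where(np.isfinite(logf), logf, -np.inf)

    def _flat_year_rw(self, parity: int, adapt_gamma: float | None):
        """Checkerboard random-walk update of the per-year flat-field levels.

        Every year's common log-pi shift is likelihood-flat; given the
        opposite parity the per-year conditionals are independent, so all
        years of one parity move at once with per-year adapted scales. The
        conditionals are much narrower than the mode-0 marginal (the
        random-walk prior couples neighbouring years), which is why these
        use adapted random walks rather than the coarse proposal grid.
        """
        d, rng = self.d, self.rng
        C, T = self.mu.shape[0], d.T
        t_idx = np.arange(parity, T, 2)
        xi = self._current_xi()
        a_full = np.zeros((C, T))
        a_full[:, t_idx] = self.s_flat_year[t_idx][None, :] * \
            rng.standard_normal((C, t_idx.size))
        _, _, logf0 = self._fiber_logf_per_year(xi, np.zeros((C, 1, T)))
        Delta_p, ok_p, logf_p = self._fiber_logf_per_year(xi, a_full[:, None, :])
        with np.errstate(invalid="ignore"):
            log_r = np.where(
                ok_p[:, 0, :], logf_p[:, 0, :] - logf0[:, 0, :], -np.inf
            )
        accept = np.log(rng.random((C, T))) < log_r
        for t in t_idx:
            sel = accept[:, t]
            self.Delta[sel, :, t] = Delta_p[sel, 0, :, t]
        if adapt_gamma is not None:
            rate = accept[:, t_idx].mean(axis=0)
            self.s_flat_year[t_idx] *= np.exp(
                adapt_gamma * (rate - self.TARGET_SCALAR)
            )

    def _flat_mode_rw(self, m: int, adapt_gamma: float | None):
        """Adapted random walk along one low-frequency flat-manifold mode."""
        d, rng = self.d, self.rng
        C, T = self.mu.shape[0], d.T
        profile = np.cos(np.pi * m * np.arange(T) / max(T - 1, 1))
        xi = self._current_xi()
        a = self.s_flat_mode[m] * rng.standard_normal(C)
        _, _, logf0 = self._fiber_logf(xi, np.zeros((C, 1, T)))
        Delta_p, ok, logf = self._fiber_logf(
            xi, a[:, None, None] * profile[None, None, :]
        )
        with np.errstate(invalid="ignore"):
            log_r = np.where(ok[:, 0], logf[:, 0] - logf0[:, 0], -np.inf)
        accept = np.log(rng.random(C)) < log_r
        self.Delta[accept] = Delta_p[accept, 0]
        if adapt_gamma is not None:
            self.s_flat_mode[m] *= np.exp(
                adapt_gamma * (accept.mean() - self.TARGET_SCALAR)
            )

    def _flat_mode_gibbs(self, profile: np.ndarray):
        """Independence sampler along one flat-manifold mode.

        Any per-year common shift of ``log pi`` is likelihood-flat, so for a
        shift profile over years (low-frequency cosine modes) the exact 1-D
        conditional along the fiber (priors times Jacobian) can be evaluated
        on a grid; proposing from the piecewise-constant approximation and
        correcting with a Metropolis-Hastings step decorrelates the mode in
        one hit.
        """
        d, rng = self.d, self.rng
        C, T = self.mu.shape[0], d.T
        grid = self._FLAT_GRID
        G = grid.size
        h = grid[1] - grid[0]
        i0 = G // 2                                 # grid point at shift 0
        xi = self._current_xi()
        shifts = np.broadcast_to(
            grid[None, :, None] * profile[None, None, :], (C, G, T)
        )
        Delta_g, ok, logf = self._fiber_logf(xi, shifts)

        wmax = logf.max(axis=1, keepdims=True)
        w = np.exp(logf - wmax)
        w /= w.sum(axis=1, keepdims=True)
        cdf = np.cumsum(w, axis=1)
        u = rng.random(C)
        cell = (u[:, None] > cdf).sum(axis=1)
        a_prop = grid[cell] + h * (rng.random(C) - 0.5)

        Delta_p, ok_p, logf_p = self._fiber_logf(
            xi, a_prop[:, None, None] * profile[None, None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            log_r = (
                logf_p[:, 0] - logf[np.arange(C), i0]
                + np.log(w[np.arange(C), i0]) - np.log(w[np.arange(C), cell])
            )
        accept = ok_p[:, 0] & (np.log(rng.random(C)) < log_r)
        self.Delta[accept] = Delta_p[accept, 0]

    def _global_level(self, adapt_gamma: float | None):
        """Uniform shift of every log density (all prey and years).

        Complementary to the fiber moves: a uniform Delta shift keeps the
        random-walk prior exactly invariant and pays only the second-order
        (curvature) likelihood cost, so composing it with the fiber moves
        lets chains traverse the weakly identified overall level.
        """
        d, rng = self.d, self.rng
        C = self.mu.shape[0]
        c = self.s_glob * rng.standard_normal(C)
        Dp = self.Delta + c[:, None, None]
        loc, scale = self.cfg.delta0_loc, self.cfg.delta0_scale
        log_r = (
            d.dirichlet_ll(self.W, Dp).sum(axis=1)
            - d.dirichlet_ll(self.W, self.Delta).sum(axis=1)
            - 0.5 * (((Dp[:, :, 0] - loc) / scale) ** 2).sum(axis=1)
            + 0.5 * (((self.Delta[:, :, 0] - loc) / scale) ** 2).sum(axis=1)
        )
        accept = np.log(rng.random(C)) < log_r
        self.Delta[accept] = Dp[accept]
        if adapt_gamma is not None:
            self.s_glob *= np.exp(
                adapt_gamma * (accept.mean() - self.TARGET_SCALAR)
            )

    def _path_shifts(self, adapt_gamma: float | None):
        """Whole-path shift of one prey's log densities at a time.

        Moves each prey's overall level against the effort likelihood
        directly; the random-walk prior is invariant, only the initial-state
        prior and the Dirichlet terms enter.
        """
        d, rng = self.d, self.rng
        C, K = self.mu.shape
        loc, scale = self.cfg.delta0_loc, self.cfg.delta0_scale
        rates = np.zeros(K)
        for i in rng.permutation(K):
            c = self.s_path[i] * rng.standard_normal(C)
            Dp = self.Delta.copy()
            Dp[:, i, :] += c[:, None]
            log_r = (
                d.dirichlet_ll(self.W, Dp).sum(axis=1)
                - d.dirichlet_ll(self.W, self.Delta).sum(axis=1)
                - 0.5 * ((Dp[:, i, 0] - loc) / scale) ** 2
                + 0.5 * ((self.Delta[:, i, 0] - loc) / scale) ** 2
            )
            accept = np.log(rng.random(C)) < log_r
            self.Delta[accept] = Dp[accept]
            rates[i] = accept.mean()
        if adapt_gamma is not None:
            self.s_path *= np.exp(adapt_gamma * (rates - self.TARGET_SCALAR))

    def _tail_shifts(self, adapt_gamma: float | None):
        """Shift one prey's log densities from a random breakpoint onward.

        Regime-like paths (abrupt collapses or outbreaks) concentrate a
        large increment at one transition; moving the whole tail as a block
        lets the sampler renegotiate where and how large that step is
        without fighting the random-walk prior year by year.
        """
        d, rng = self.d, self.rng
        C, K = self.mu.shape
        T = d.T
        rates = np.zeros(K)
        for i in rng.permutation(K):
            tb = int(rng.integers(1, T))
            c = self.s_tail[i] * rng.standard_normal(C)
            Dp = self.Delta.copy()
            Dp[:, i, tb:] += c[:, None]
            sD = np.exp(self.log_sD[:, i])
            log_r = (
                d.dirichlet_ll(self.W, Dp).sum(axis=1)
                - d.dirichlet_ll(self.W, self.Delta).sum(axis=1)
                - 0.5 * ((Dp[:, i, tb] - Dp[:, i, tb - 1]) / sD) ** 2
                + 0.5 * ((self.Delta[:, i, tb] - self.Delta[:, i, tb - 1]) / sD) ** 2
            )
            accept = np.log(rng.random(C)) < log_r
            self.Delta[accept] = Dp[accept]
            rates[i] = accept.mean()
        if adapt_gamma is not None:
            self.s_tail *= np.exp(adapt_gamma * (rates - self.TARGET_SCALAR))

    def _mu_block(self, adapt_gamma: float | None):
        d, rng = self.d, self.rng
        C, K = self.mu.shape
        prop = self.mu + self.s_mu * rng.standard_normal((C, K))
        Wp = d.switch(prop)
        log_r = (
            d.dirichlet_ll(Wp, self.Delta).sum(axis=1)
            - d.dirichlet_ll(self.W, self.Delta).sum(axis=1)
            + d.intake_ll_per_prey(prop, self.log_sE).sum(axis=1)
            - d.intake_ll_per_prey(self.mu, self.log_sE).sum(axis=1)
            + d.mu_prior(prop) - d.mu_prior(self.mu)
        )
        accept = np.log(rng.random(C)) < log_r
        self.mu[accept] = prop[accept]
        self.W[accept] = Wp[accept]
        if adapt_gamma is not None:
            self.s_mu *= np.exp(adapt_gamma * (accept.mean() - self.TARGET_BLOCK))

    def _scale_updates(self, adapt_gamma: float | None):
        d, rng = self.d, self.rng
        C, K = self.mu.shape
        log_smax = np.log(self.cfg.sigma_max)
        # centered sigma_D | Delta (per prey)
        prop = self.log_sD + self.s_sd[None, :] * rng.standard_normal((C, K))
        log_r = (
            d.rw_ll_per_prey(self.Delta, prop)
            - d.rw_ll_per_prey(self.Delta, self.log_sD)
            + d.sigma_prior(prop) - d.sigma_prior(self.log_sD)
        )
        log_r = np.where(prop > log_smax, -np.inf, log_r)
        accept = np.log(rng.random((C, K))) < log_r
        self.log_sD = np.where(accept, prop, self.log_sD)
        if adapt_gamma is not None:
            self.s_sd *= np.exp(
                adapt_gamma * (accept.mean(axis=0) - self.TARGET_SCALAR)
            )
        # sigma_E | mu (per prey)
        prop = self.log_sE + self.s_se[None, :] * rng.standard_normal((C, K))
        log_r = (
            d.intake_ll_per_prey(self.mu, prop)
            - d.intake_ll_per_prey(self.mu, self.log_sE)
            + d.sigma_prior(prop) - d.sigma_prior(self.log_sE)
        )
        log_r = np.where(prop > log_smax, -np.inf, log_r)
        accept = np.log(rng.random((C, K))) < log_r
        self.log_sE = np.where(accept, prop, self.log_sE)
        if adapt_gamma is not None:
            self.s_se *= np.exp(
                adapt_gamma * (accept.mean(axis=0) - self.TARGET_SCALAR)
            )

    def _interweave_sigma_d(self, adapt_gamma: float | None):
        """Non-centered rescaling move for each prey's latent path.

        Holding the standardized increments fixed, a change of sigma_D
        rescales the whole path about a randomly chosen anchor year:
        ``Delta' = Delta_a + (sigma'/sigma) * (Delta - Delta_a)``. In the
        non-centered parameterization the increment prior cancels, so the
        acceptance ratio involves only the Dirichlet likelihood, the
        initial-state prior (when the anchor is not the first year) and the
        scale prior. This is the ancillarity-sufficiency interweaving that
        lets the innovation scales cross the funnel; varying the anchor
        serves paths whose dominant changes happen mid-series.
        """
        d, rng = self.d, self.rng
        C, K = self.mu.shape
        T = d.T
        loc, scale = self.cfg.delta0_loc, self.cfg.delta0_scale
        rates = np.zeros(K)
        for i in rng.permutation(K):
            t_anchor = int(rng.integers(T))
            prop_ls = self.log_sD[:, i] + self.s_nc[i] * rng.standard_normal(C)
            ratio = np.exp(prop_ls - self.log_sD[:, i])
            Dp = self.Delta.copy()
            base = self.Delta[:, i, t_anchor][:, None]
            Dp[:, i, :] = base + ratio[:, None] * (self.Delta[:, i, :] - base)
            log_r = (
                d.dirichlet_ll(self.W, Dp).sum(axis=1)
                - d.dirichlet_ll(self.W, self.Delta).sum(axis=1)
                + d.sigma_prior(prop_ls[:, None])[:, 0]
                - d.sigma_prior(self.log_sD[:, i][:, None])[:, 0]
                - 0.5 * ((Dp[:, i, 0] - loc) / scale) ** 2
                + 0.5 * ((self.Delta[:, i, 0] - loc) / scale) ** 2
            )
            log_r = np.where(
                prop_ls > np.log(self.cfg.sigma_max), -np.inf, log_r
            )
            accept = np.log(rng.random(C)) < log_r
            self.Delta[accept] = Dp[accept]
            self.log_sD[accept, i] = prop_ls[accept]
            rates[i] = accept.mean()
        if adapt_gamma is not None:
            self.s_nc *= np.exp(adapt_gamma * (rates - self.TARGET_SCALAR))

    # -- driver -------------------------------------------------------------

    def sweep(self, adapt_gamma: float | None):
        self._year_blocks(0, adapt_gamma)
        self._year_blocks(1, adapt_gamma)
        self._flat_year_rw(0, adapt_gamma)
        self._flat_year_rw(1, adapt_gamma)
        T = self.d.T
        t_axis = np.arange(T) / max(T - 1, 1)
        self._flat_mode_gibbs(np.ones(T))
        for m in range(1, min(8, T)):
            self._flat_mode_rw(m, adapt_gamma)
        self._global_level(adapt_gamma)
        self._path_shifts(adapt_gamma)
        self._tail_shifts(adapt_gamma)
        self._mu_block(adapt_gamma)
        self._scale_updates(adapt_gamma)
        # the innovation-scale funnel is the slowest direction; cross it
        # twice more per sweep (cheap relative to the block updates)
        for _ in range(2):
            self._interweave_sigma_d(adapt_gamma)
            self._scale_updates(adapt_gamma)

    def run(self):
        cfg = self.cfg
        for n in range(cfg.n_warmup):
            self.sweep(adapt_gamma=2.0 * (n + 20.0) ** -0.6)
            self._update_block_cov()
        kept = cfg.n_steps // cfg.thin
        C, K, T = self.mu.shape[0], self.d.K, self.d.T
        mu = np.empty((C, kept, K))
        Delta = np.empty((C, kept, K, T))
        log_sD = np.empty((C, kept, K))
        log_sE = np.empty((C, kept, K))
        j = 0
        for n in range(cfg.n_steps):
            self.sweep(adapt_gamma=None)
            if (n + 1) % cfg.thin == 0 and j < kept:
                mu[:, j] = self.mu
                Delta[:, j] = self.Delta
                log_sD[:, j] = self.log_sD
                log_sE[:, j] = self.log_sE
                j += 1
        return {"mu": mu, "Delta": Delta, "log_sD": log_sD, "log_sE": log_sE}


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorAllocation:
    """Posterior effort allocation for a single year."""

    year: int
    prey_ids: list[str]
    eta_draws: np.ndarray        # (n_draws, K)
    pi_draws: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.eta_draws.mean(axis=0)

    @property
    def ci95(self) -> np.ndarray:
        """(2, K) array of 2.5 / 97.5 percentiles of eta."""
        return np.percentile(self.eta_draws, [2.5, 97.5], axis=0)


@dataclass
class PosteriorSamples:
    """Flattened posterior draws and diagnostics from a fitted model."""

    prey_ids: list[str]
    years: np.ndarray
    mu: np.ndarray               # (n_draws, K)
    Delta: np.ndarray            # (n_draws, K, T)
    sigma_D: np.ndarray          # (n_draws, K)
    sigma_E: np.ndarray          # (n_draws, K)
    tau: np.ndarray              # (T,)
    diagnostics: pd.DataFrame    # per parameter: rhat, ess
    config: ModelConfig

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def allocation_draws(self) -> tuple[np.ndarray, np.ndarray]:
        """(pi, eta) draws, each (n_draws, K, T)."""
        return allocation_from_draws(self.mu, self.Delta, self.config.tie_tol)

    def summary(self) -> pd.DataFrame:
        """Posterior mean and 95% credible interval per scalar parameter."""
        rows = []

        def add(name, draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append((name, float(np.mean(draws)), lo, hi))

        for i, p in enumerate(self.prey_ids):
            add(f"mu[{p}]", self.mu[:, i])
            add(f"sigma_D[{p}]", self.sigma_D[:, i])
            add(f"sigma_E[{p}]", self.sigma_E[:, i])
            for t, y in enumerate(self.years):
                add(f"Delta[{p},{y}]", self.Delta[:, i, t])
        return pd.DataFrame(rows, columns=["parameter", "mean", "lo95", "hi95"])


def posterior_allocation(ps: PosteriorSamples, year: int) -> PosteriorAllocation:
    """Per-draw effort allocation for one fitted year, with 95% intervals."""
    where = np.flatnonzero(ps.years == year)
    if where.size == 0:
        raise ValueError(f"year {year} outside fitted range "
                         f"{ps.years[0]}-{ps.years[-1]}")
    t = int(where[0])
    pi, eta = ps.allocation_draws()
    return PosteriorAllocation(
        year=year, prey_ids=list(ps.prey_ids),
        eta_draws=eta[:, :, t], pi_draws=pi[:, :, t],
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_point(data: _ModelData) -> dict:
    """Data-driven central initialization.

    mu starts at the per-prey mean observed log intake; Delta is backed out
    from the observed allocation by sequential inversion in profitability
    order, assuming a total per-dive allocation probability of 0.8.
    """
    K, T = data.K, data.T
    with np.errstate(invalid="ignore"):
        mu0 = np.nanmean(np.where(data.obs_mask, data.mu_obs, np.nan), axis=1)
    mu0 = np.where(np.isfinite(mu0), mu0, 1.0)
    order = np.argsort(-mu0, kind="stable")
    Delta0 = np.empty((K, T))
    for t in range(T):
        pi_target = 0.8 * data.eta_obs[t]
        lam = np.empty(K)
        prod = 1.0
        for i in order:
            lam[i] = min(max(pi_target[i] / max(prod, 1e-12), 1e-4), 0.95)
            prod *= 1.0 - lam[i]
        Delta0[:, t] = np.log(-np.log1p(-lam))
    sE0 = np.nanstd(
        np.where(data.obs_mask, data.mu_obs - mu0[:, None], np.nan), axis=1
    )
    sE0 = np.where(np.isfinite(sE0) & (sE0 > 0.02), sE0, 0.1)
    sD0 = np.clip(np.std(np.diff(Delta0, axis=1), axis=1), 0.05, 1.0)
    return {"mu": mu0, "Delta": Delta0,
            "log_sD": np.log(sD0), "log_sE": np.log(sE0)}


def _param_names(prey_ids, years) -> list[str]:
    names = [f"mu[{p}]" for p in prey_ids]
    names += [f"Delta[{p},{y}]" for p in prey_ids for y in years]
    names += [f"sigma_D[{p}]" for p in prey_ids]
    names += [f"sigma_E[{p}]" for p in prey_ids]
    return names


def _diagnostics(draws: dict, prey_ids, years) -> pd.DataFrame:
    import arviz as az

    C, n, K = draws["mu"].shape
    T = draws["Delta"].shape[-1]
    arr = np.concatenate(
        [
            draws["mu"],
            draws["Delta"].reshape(C, n, K * T),
            draws["log_sD"],
            draws["log_sE"],
        ],
        axis=-1,
    )
    ds = az.convert_to_dataset({"theta": arr})
    return pd.DataFrame({
        "parameter": _param_names(prey_ids, years),
        "rhat": az.rhat(ds)["theta"].values,
        "ess": az.ess(ds)["theta"].values,
    })


def fit_model(
    obs: ObservedForaging,
    config: ModelConfig | None = None,
    tau: np.ndarray | None = None,
) -> PosteriorSamples:
    """Fit the state-space foraging model to emulated observations.

    The per-year Dirichlet precision ``tau_t`` is computed up front from the
    effort-allocation draw matrices (maximum likelihood) unless supplied.
    Missing intake observations (NaN in ``mu_obs``) simply drop out of the
    likelihood. Raises :class:`ConvergenceError` if rank-normalized R-hat
    or bulk ESS violate the configured thresholds (unless
    ``enforce_convergence=False``). Deterministic for a fixed config seed.
    """
    cfg = config if config is not None else ModelConfig()
    K = len(obs.prey_ids)
    T = len(obs.years)
    if K < 2 or T < 2:
        raise ValueError("need at least 2 prey types and 2 years")

    if tau is None:
        tau = np.array(
            [dirichlet_precision(obs.eta_draws[t]) for t in range(T)]
        )
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (T,) or np.any(~np.isfinite(tau)) or np.any(tau <= 0):
        raise ValueError("tau must be a positive, finite per-year vector")

    eta_obs = obs.eta_obs(cfg.eta_floor)
    data = _ModelData(eta_obs, obs.mu_obs, tau, cfg)
    rng = np.random.default_rng(cfg.seed)
    sampler = _GibbsSampler(data, _initial_point(data), cfg, rng)
    draws = sampler.run()
    diag = _diagnostics(draws, obs.prey_ids, obs.years)

    if cfg.enforce_convergence:
        bad = diag[(diag.rhat > cfg.max_rhat) | (diag.ess < cfg.min_ess)]
        if len(bad):
            worst = bad.sort_values("rhat", ascending=False).head(5)
            raise ConvergenceError(
                f"{len(bad)} parameters fail convergence thresholds "
                f"(R-hat <= {cfg.max_rhat}, ESS >= {cfg.min_ess}); worst:\n"
                f"{worst.to_string(index=False)}"
            )

    C, n = draws["mu"].shape[:2]
    return PosteriorSamples(
        prey_ids=list(obs.prey_ids), years=obs.years.copy(),
        mu=draws["mu"].reshape(C * n, K),
        Delta=draws["Delta"].reshape(C * n, K, T),
        sigma_D=np.exp(draws["log_sD"].reshape(C * n, K)),
        sigma_E=np.exp(draws["log_sE"].reshape(C * n, K)),
        tau=tau, diagnostics=diag, config=cfg,
    )
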