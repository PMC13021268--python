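"""Posterior sampling engine.

A general-purpose sampler for the smooth, low-dimensional (5-15
parameter) posteriors arising from the regression models in this package
(random effects are integrated out of the likelihoods before sampling).
The strategy:

1. find the posterior mode with BFGS and form a Laplace (inverse-Hessian)
   covariance estimate;
2. warm up many chains *in lockstep* — the log-posterior is evaluated in
   one batched call per iteration across all chains, so extra chains are
   nearly free — and refit the proposal to the pooled warmup draws
   (twice);
3. draw from the frozen kernel.

Each chain runs a Metropolis-Hastings mixture kernel: an *independence*
proposal — a defensive two-component multivariate-t mixture (a snug
component plus a wide one, so the proposal density stays non-negligible
in skewed posterior tails) — mixed with a *random-walk* proposal scaled
by the classic 2.38^2/d rule whose step size adapts per chain toward 23%
acceptance during warmup.  The walk keeps every chain locally mobile
where the independence proposal is mismatched; the independence jumps
decorrelate chains where it is good.

Split-R-hat and bulk effective sample size are computed with ArviZ.
Divergence counts are reported as 0: the notion is specific to
Hamiltonian samplers and does not arise for Metropolis kernels;
convergence trouble shows up in R-hat/ESS instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import arviz as az
import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp

__all__ = ["SamplerSettings", "PosteriorDraws", "find_map", "sample_posterior"]

# BatchLogPost: maps (B, dim) parameter rows to (B,) log-posterior values
BatchLogPost = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``draws`` is the number of retained draws per chain after ``warmup``
    adaptation iterations (which are discarded).  Chains run in lockstep
    with batched likelihood evaluations, so more chains cost little.
    """

    chains: int = 12
    draws: int = 3000
    warmup: int = 800
    seed: int = 0
    independence_weight: float = 0.4  # post-warmup mixture weight of the independence kernel
    t_df: float = 5.0  # tail heaviness of the independence proposal


@dataclass
class PosteriorDraws:
    """Draws plus convergence diagnostics for one fitted model."""

    draws: np.ndarray  # (chains, draws, dim)
    names: tuple[str, ...]
    rhat: np.ndarray  # per parameter
    ess_bulk: np.ndarray  # per parameter
    accept_rate: float
    divergences: int = 0
    mode: np.ndarray | None = None

    @property
    def flat(self) -> np.ndarray:
        """All chains pooled, shape (chains * draws, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def parameter(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    hess = np.empty((d, d))
    step = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step[i]
            ej[j] = step[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step[i] * step[j])
    return hess


def find_map(
    log_post: BatchLogPost,
    x0: np.ndarray,
    maxiter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and Laplace covariance (inverse negative Hessian)."""
    def neg(x: np.ndarray) -> float:
        val = float(log_post(x[None])[0])
        # large finite penalty keeps BFGS line searches off the boundary
        return -val if np.isfinite(val) else 1e10
    res = optimize.minimize(neg, x0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-5})
    xmap = res.x
    hess = _numeric_hessian(neg, xmap)
    d = xmap.size
    jitter = 0.0
    eye = np.eye(d)
    for _ in range(12):
        try:
            cov = np.linalg.inv(hess + jitter * eye)
            np.linalg.cholesky((cov + cov.T) / 2.0)
            return xmap, (cov + cov.T) / 2.0
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-6)
    return xmap, 0.1 * eye


def _safe_cholesky(cov: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    jitter = 1e-10 * max(float(np.trace(cov)) / cov.shape[0], 1e-10)
    for _ in range(10):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    return fallback


class _DefensiveT:
    """Two-component multivariate-t mixture proposal (snug + wide), batched."""

    WIDE = 3.0
    WIDE_WEIGHT = 0.2

    def __init__(self, mean: np.ndarray, chol: np.ndarray, df: float):
        self.mean = mean
        self.chols = (1.1 * chol, self.WIDE * chol)
        self.log_w = (np.log1p(-self.WIDE_WEIGHT), np.log(self.WIDE_WEIGHT))
        self.df = df
        d = mean.size
        self._consts = []
        for ch in self.chols:
            logdet = float(np.sum(np.log(np.diag(ch))))
            self._consts.append(
                gammaln((df + d) / 2.0)
                - gammaln(df / 2.0)
                - 0.5 * d * np.log(df * np.pi)
                - logdet
            )

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        d = self.mean.size
        parts = []
        for ch, lw, const in zip(self.chols, self.log_w, self._consts):
            dev = np.linalg.solve(ch, (x - self.mean).T)  # (d, B)
            quad = np.sum(dev * dev, axis=0)
            parts.append(lw + const - 0.5 * (self.df + d) * np.log1p(quad / self.df))
        return logsumexp(np.stack(parts), axis=0)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        d = self.mean.size
        z = rng.standard_normal((size, d))
        w = rng.chisquare(self.df, size) / self.df
        wide = rng.random(size) < self.WIDE_WEIGHT
        step = np.where(wide[:, None], z @ self.chols[1].T, z @ self.chols[0].T)
        return self.mean + step / np.sqrt(w)[:, None]


def _run_chains(
    log_post: BatchLogPost,
    states: np.ndarray,  # (B, d)
    n_iter: int,
    rng: np.random.Generator,
    proposal: _DefensiveT,
    rw_chol: np.ndarray,
    ind_weight: float,
    adapt: bool,
    rw_scales: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """All chains in lockstep; returns (draws, states, scales, accepts)."""
    B, d = states.shape
    lp = log_post(states)
    lq = proposal.logpdf(states)
    out = np.empty((B, n_iter, d))
    n_accept = 0
    for it in range(n_iter):
        ind = rng.random(B) < ind_weight
        prop = np.where(
            ind[:, None],
            proposal.draw(rng, B),
            states + rw_scales[:, None] * (rng.standard_normal((B, d)) @ rw_chol.T),
        )
        lp_prop = log_post(prop)
        lq_prop = proposal.logpdf(prop)
        with np.errstate(invalid="ignore"):
            log_alpha = lp_prop - lp + np.where(ind, lq - lq_prop, 0.0)
        accept = np.log(rng.random(B)) < log_alpha
        states = np.where(accept[:, None], prop, states)
        lp = np.where(accept, lp_prop, lp)
        lq = np.where(accept, lq_prop, lq)
        n_accept += int(accept.sum())
        if adapt:
            rw = ~ind
            # Robbins-Monro drift of each walk scale toward 23% acceptance
            rw_scales = np.where(
                rw,
                rw_scales * np.exp((accept.astype(float) - 0.234) / np.sqrt(1.0 + it)),
                rw_scales,
            )
            rw_scales = np.clip(rw_scales, 0.05, 20.0)
        out[:, it, :] = states
    return out, states, rw_scales, n_accept


def sample_posterior(
    log_post: BatchLogPost,
    x0: np.ndarray,
    names: Sequence[str],
    settings: SamplerSettings,
) -> PosteriorDraws:
    """Sample a posterior with the adaptive batched mixture MH kernel."""
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    B = settings.chains
    xmap, cov = find_map(log_post, x0)
    chol = _safe_cholesky(cov, 0.1 * np.eye(d))

    rng = np.random.default_rng((settings.seed, 0x4D43))
    states = xmap + 0.3 * (rng.standard_normal((B, d)) @ chol.T)

    # warmup in two rounds: the Laplace proposal seeds the first; the
    # proposal and walk covariance are refit from pooled draws after each
    proposal = _DefensiveT(xmap, chol, settings.t_df)
    rw_chol = (2.38 / np.sqrt(d)) * chol
    scales = np.ones(B)
    half = max(settings.warmup // 2, 1)
    for round_len in (half, settings.warmup - half):
        if round_len <= 0:
            continue
        warm, states, scales, _ = _run_chains(
            log_post, states, round_len, rng, proposal, rw_chol,
            ind_weight=0.4, adapt=True, rw_scales=scales,
        )
        pooled = warm[:, round_len // 2 :, :].reshape(-1, d)
        pooled_chol = _safe_cholesky(np.cov(pooled.T).reshape(d, d), chol)
        proposal = _DefensiveT(pooled.mean(axis=0), pooled_chol, settings.t_df)
        rw_chol = (2.38 / np.sqrt(d)) * pooled_chol

    all_draws, _, _, n_accept = _run_chains(
        log_post, states, settings.draws, rng, proposal, rw_chol,
        ind_weight=settings.independence_weight, adapt=False, rw_scales=scales,
    )

    rhat = np.empty(d)
    ess = np.empty(d)
    for j in range(d):
        chains_j = all_draws[:, :, j]
        rhat[j] = float(az.rhat(chains_j)) if B > 1 else np.nan
        ess[j] = float(az.ess(chains_j))
    return PosteriorDraws(
        draws=all_draws,
        names=tuple(names),
        rhat=rhat,
        ess_bulk=ess,
        accept_rate=n_accept / max(B * settings.draws, 1),
        divergences=0,
        mode=xmap,
    )
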