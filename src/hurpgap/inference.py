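"""Bayesian fitting of the HURP model: likelihood, proposal, sampler.

The observation model treats each measured intensity y_k(x_i, t_j) on side
k (trailing +, leading -) as Gaussian around the PDE solution H_k(x_i, t_j)
with known standard deviation sigma, so the log likelihood is a sum of
independent normal terms over both sides and the full space-time grid.

Sampling is Random Walk Metropolis on the log scale of the positive
parameters: a proposal perturbs eta = log(delta + theta) by a draw from
N(0, Sigma), with Sigma tuned from a short pilot run.  The map back to
the natural scale is asymmetric, so the exact Metropolis-Hastings
correction (change-of-variables Jacobian plus the delta-shift asymmetry)
is applied by default; it can be disabled for a plain-Metropolis protocol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ObservedProfileDataset
from .exceptions import (DegenerateProposalError, HurpGapError,
                         InsufficientSamplesError, InvalidParameterError)
from .parameters import HurpProfile, ModelParameters, SpatialGrid
from .pde import alternating_run
from .priors import PriorSpec

__all__ = ["McmcConfig", "PosteriorSamples", "log_likelihood", "propose",
           "run_mcmc", "summarize_posterior", "make_loglik"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


def log_likelihood(params: ModelParameters, data: ObservedProfileDataset,
                   model_runs: tuple[HurpProfile, HurpProfile]) -> float:
    """Gaussian log likelihood of the data given simulated profiles.

    ``model_runs`` is the (leading, trailing) pair; each is interpolated
    onto the observation grid (x_obs, t_obs).  The leading run is compared
    to y_minus, the trailing run to y_plus, with standard deviation
    ``data.sigma`` on every point.
    """
    lead, trail = model_runs
    sigma = data.sigma
    total = 0.0
    n = 0
    for profile, y in ((lead, data.y_minus), (trail, data.y_plus)):
        H = profile.evaluate_at(data.x_obs, data.t_obs)
        if H.shape != y.shape:
            raise InvalidParameterError(
                f"model evaluation shape {H.shape} does not match data {y.shape}")
        z = (y - H) / sigma
        total += -0.5 * float(np.sum(z * z))
        n += y.size
    total += -n * (0.5 * _LOG_2PI + math.log(sigma))
    return total


def _validate_cov(Sigma: np.ndarray) -> np.ndarray:
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Sigma.shape[0] != Sigma.shape[1]:
        raise InvalidParameterError("proposal covariance must be square")
    if not np.allclose(Sigma, Sigma.T, atol=1e-12):
        raise InvalidParameterError("proposal covariance must be symmetric")
    w = np.linalg.eigvalsh(Sigma)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise InvalidParameterError("proposal covariance is not positive semi-definite")
    return Sigma


def _cov_factor(Sigma: np.ndarray) -> np.ndarray:
    """Square-root factor C with C C^T = Sigma (PSD-safe)."""
    w, V = np.linalg.eigh(Sigma)
    return V * np.sqrt(np.clip(w, 0.0, None))


def propose(theta: np.ndarray, Sigma: np.ndarray, delta, rng: np.random.Generator,
            xi: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Log-space random-walk proposal with exact Hastings correction.

    theta'_i = sign(theta_i) * exp(log(delta_i + |theta_i|) + xi_i) with
    xi ~ N(0, Sigma) drawn jointly.  Returns (theta', log Hastings
    correction), the correction being log q(theta | theta') - log
    q(theta' | theta) for the asymmetric map.  ``xi`` may be supplied to
    make the draw deterministic (testing).
    """
    theta = np.asarray(theta, dtype=float)
    d = theta.size
    Sigma = _validate_cov(Sigma)
    if Sigma.shape != (d, d):
        raise InvalidParameterError(
            f"covariance shape {Sigma.shape} does not match theta ({d})")
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (d,))
    if np.any(delta < 0):
        raise InvalidParameterError("delta entries must be >= 0")
    if xi is None:
        xi = _cov_factor(Sigma) @ rng.standard_normal(d)
    else:
        xi = np.asarray(xi, dtype=float)

    sign = np.where(theta < 0, -1.0, 1.0)
    theta_new = sign * np.exp(np.log(delta + np.abs(theta)) + xi)

    # exact MH correction: Gaussian asymmetry in eta plus Jacobian of the
    # eta -> theta map (proposal density carries a factor 1/|theta'_i|)
    xi_rev = np.log(np.abs(theta)) - np.log(delta + np.abs(theta_new))
    Sigma_pinv = np.linalg.pinv(Sigma)
    quad_fwd = float(xi @ Sigma_pinv @ xi)
    quad_rev = float(xi_rev @ Sigma_pinv @ xi_rev)
    log_hastings = -0.5 * (quad_rev - quad_fwd) \
        + float(np.sum(np.log(np.abs(theta_new)) - np.log(np.abs(theta))))
    return theta_new, log_hastings


@dataclass
class McmcConfig:
    """Protocol settings for the Random Walk Metropolis sampler."""

    n_iter: int = 10_000
    n_chains: int = 4
    pilot_iter: int = 1_000
    proposal_cov: np.ndarray | None = None
    delta: float = 1e-8
    burn_in_fraction: float = 0.5
    seed: int = 0
    hastings: bool = True
    pilot_step: float = 0.1       # initial per-parameter log-scale step

    def __post_init__(self) -> None:
        if not self.n_iter > self.pilot_iter >= 0:
            raise InvalidParameterError("need n_iter > pilot_iter >= 0")
        if not 0 <= self.burn_in_fraction < 1:
            raise InvalidParameterError("burn_in_fraction must be in [0, 1)")
        if np.any(np.asarray(self.delta) < 0):
            raise InvalidParameterError("delta must be >= 0")
        if self.n_chains < 1:
            raise InvalidParameterError("n_chains must be >= 1")
        if self.proposal_cov is not None:
            self.proposal_cov = _validate_cov(self.proposal_cov)


@dataclass
class PosteriorSamples:
    """MCMC draws with burn-in bookkeeping."""

    draws: np.ndarray              # (n_chains, n_iter, n_params), natural scale
    log_posterior: np.ndarray      # (n_chains, n_iter)
    acceptance_rates: np.ndarray   # (n_chains,)
    burn_in: int
    param_names: tuple
    fixed: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def post_burn_in(self) -> np.ndarray:
        """Per-chain draws after burn-in: (n_chains, n_kept, n_params)."""
        return self.draws[:, self.burn_in:, :]

    def pooled(self) -> np.ndarray:
        """Post-burn-in draws pooled across chains: (n, n_params)."""
        kept = self.post_burn_in()
        return kept.reshape(-1, kept.shape[-1])


def make_loglik(data: ObservedProfileDataset, base: ModelParameters,
                priors: PriorSpec, grid: SpatialGrid,
                eq_tol: float = 1e-6):
    """Forward-model log-likelihood as a function of the free vector.

    Builds the leading/trailing alternation (trailing equilibrium ->
    leading run -> trailing run) at each theta, sampled at the data's
    frame interval, and scores it under the Gaussian observation model.
    Solver failures return -inf (the proposal is rejected) with a warning.
    """
    if data.t_obs.size < 2:
        raise InvalidParameterError("need at least 2 observation frames")
    dt_obs = float(data.t_obs[1] - data.t_obs[0])
    duration = float(data.t_obs[-1] - data.t_obs[0])
    free = priors.free_names

    def loglik(theta_free: np.ndarray) -> float:
        try:
            params = base.replace(**dict(zip(free, map(float, theta_free))))
            runs = alternating_run(params, grid, duration, duration, dt_obs,
                                   eq_tol=eq_tol)
            return log_likelihood(params, data, runs)
        except (HurpGapError, ValueError) as exc:
            logger.warning("forward solve failed at theta=%s: %s",
                           np.array2string(np.asarray(theta_free), precision=4), exc)
            return -np.inf

    return loglik


def _run_chain(log_target, theta0: np.ndarray, Sigma: np.ndarray, delta,
               n_iter: int, rng: np.random.Generator, hastings: bool,
               adapt_until: int = 0, adapt_every: int = 50,
               history_window: int = 300, Sigma_floor: np.ndarray | None = None):
    """One Metropolis chain.

    If ``adapt_until`` > 0 the proposal is adapted every ``adapt_every``
    iterations up to that point and then frozen (so later draws come from
    a fixed kernel): the covariance shape is re-estimated from the last
    ``history_window`` draws with the optimal-RWM scaling 2.38^2/d, and a
    global scale factor follows a Robbins-Monro recursion toward the
    optimal high-dimensional acceptance rate of about 0.234.
    """
    d = theta0.size
    draws = np.empty((n_iter, d))
    log_post = np.empty(n_iter)
    theta = np.asarray(theta0, dtype=float)
    lp = log_target(theta)
    Sigma_shape = _validate_cov(Sigma)
    log_scale = 0.0
    C = _cov_factor(Sigma_shape)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (d,))
    Sigma_pinv = np.linalg.pinv(np.atleast_2d(Sigma_shape))
    accepted = 0
    accepted_window = 0
    for it in range(n_iter):
        if 0 < it <= adapt_until and it % adapt_every == 0:
            acc_window = accepted_window / adapt_every
            accepted_window = 0
            log_scale += 1.5 * (acc_window - 0.234)
            eta_hist = np.log(delta + draws[max(0, it - history_window):it])
            cov = np.atleast_2d(np.cov(eta_hist, rowvar=False))
            if np.all(np.isfinite(cov)) and np.trace(cov) > 0:
                base = Sigma_floor if Sigma_floor is not None \
                    else 1e-9 * np.eye(d)
                Sigma_shape = (2.38 ** 2 / d) * cov + base
            Sigma_cur = np.exp(2.0 * log_scale) * Sigma_shape
            C = _cov_factor(Sigma_cur)
            Sigma_pinv = np.linalg.pinv(Sigma_cur)
        xi = C @ rng.standard_normal(d)
        theta_new = np.exp(np.log(delta + np.abs(theta)) + xi)
        if hastings:
            xi_rev = np.log(np.abs(theta)) - np.log(delta + theta_new)
            corr = -0.5 * (float(xi_rev @ Sigma_pinv @ xi_rev)
                           - float(xi @ Sigma_pinv @ xi)) \
                + float(np.sum(np.log(theta_new) - np.log(np.abs(theta))))
        else:
            corr = 0.0
        lp_new = log_target(theta_new)
        log_ratio = lp_new - lp + corr
        if np.isnan(log_ratio):       # -inf vs -inf: stay put
            accept = False
        else:
            accept = np.log(rng.uniform()) < log_ratio
        if accept:
            theta, lp = theta_new, lp_new
            accepted += 1
            accepted_window += 1
        draws[it] = theta
        log_post[it] = lp
    return draws, log_post, accepted / max(n_iter, 1)


def run_mcmc(data: ObservedProfileDataset, priors: PriorSpec,
             config: McmcConfig, fixed: dict | ModelParameters | None = None,
             grid: SpatialGrid | None = None, eq_tol: float = 1e-6,
             loglik_fn=None) -> PosteriorSamples:
    """Pilot-tuned Random Walk Metropolis over the free parameters.

    A short pilot run (``config.pilot_iter`` iterations, started at the
    prior medians with an isotropic log-scale step) provides an empirical
    covariance of the transformed samples; the main proposal uses the
    standard optimal-RWM scaling (2.38^2/d) of that estimate.  The main
    chains are initialised from independent prior draws and run for
    ``config.n_iter`` iterations each; the first ``burn_in_fraction`` of
    every chain is marked as burn-in.  Fully reproducible given
    ``config.seed``.

    ``fixed`` supplies values for parameters named in ``priors.fixed``
    (and sigma/L); ``loglik_fn`` overrides the forward-model likelihood
    (e.g. a constant for prior-only sampling).
    """
    if isinstance(fixed, ModelParameters):
        base = fixed
    else:
        fixed = dict(fixed or {})
        if "sigma" not in fixed:
            fixed["sigma"] = data.sigma if data is not None else 1.0
        base = ModelParameters().replace(**fixed)
    free = priors.free_names
    d = len(free)
    if d == 0:
        raise InvalidParameterError("no free parameters to infer")
    if grid is None:
        grid = SpatialGrid(L=base.L, n_cells=90)

    if loglik_fn is None:
        loglik_fn = make_loglik(data, base, priors, grid, eq_tol=eq_tol)

    def log_target(theta):
        lp = priors.log_prior(theta)
        if lp == -np.inf:
            return -np.inf
        return lp + loglik_fn(theta)

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chains + 1)
    delta = config.delta

    if config.proposal_cov is not None:
        Sigma = _validate_cov(config.proposal_cov)
        if Sigma.shape != (d, d):
            raise InvalidParameterError("proposal_cov does not match free dimension")
    elif config.pilot_iter > 0:
        pilot_rng = np.random.default_rng(child_seeds[0])
        Sigma0 = np.eye(d) * config.pilot_step ** 2
        pilot_draws, _, pilot_acc = _run_chain(
            log_target, priors.medians(), Sigma0, delta,
            config.pilot_iter, pilot_rng, config.hastings,
            adapt_until=config.pilot_iter)
        if pilot_acc == 0:
            raise DegenerateProposalError(
                "pilot run accepted no proposals; rescale pilot_step or "
                "check that the prior medians are inside the model's support")
        eta = np.log(delta + pilot_draws[config.pilot_iter // 2:])
        Sigma = (2.38 ** 2 / d) * np.atleast_2d(np.cov(eta, rowvar=False)) \
            + 1e-10 * np.eye(d)
    else:
        Sigma = np.eye(d) * config.pilot_step ** 2

    n = config.n_iter
    burn_in = int(config.burn_in_fraction * n)
    draws = np.empty((config.n_chains, n, d))
    log_post = np.empty((config.n_chains, n))
    acc = np.empty(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(child_seeds[c + 1])
        theta0 = priors.sample(rng)
        for _ in range(50):      # prior draws in unsolvable regions retried
            if log_target(theta0) > -np.inf:
                break
            theta0 = priors.sample(rng)
        draws[c], log_post[c], acc[c] = _run_chain(
            log_target, theta0, Sigma, delta, n, rng, config.hastings,
            adapt_until=burn_in, Sigma_floor=Sigma)
    return PosteriorSamples(draws=draws, log_posterior=log_post,
                            acceptance_rates=acc, burn_in=burn_in,
                            param_names=free,
                            fixed={k: getattr(base, k) for k in
                                   ("sigma", "L", *priors.fixed)})


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Delegates to arviz.
    """
    import arviz as az

    with np.errstate(invalid="ignore"):
        return float(az.rhat(az.convert_to_dataset(chains))["x"].values)


def summarize_posterior(samples: PosteriorSamples):
    """Per-parameter posterior summary table.

    Medians and central 95% intervals on the pooled post-burn-in draws,
    the mean acceptance rate, and the split-chain R-hat diagnostic.
    Returns a pandas DataFrame indexed by parameter name.
    """
    import pandas as pd

    kept = samples.post_burn_in()
    if kept.shape[1] == 0:
        raise InsufficientSamplesError("no post-burn-in draws to summarise")
    if samples.n_chains < 2:
        raise InsufficientSamplesError("need >= 2 chains for split-chain diagnostics")
    pooled = samples.pooled()
    rows = []
    for j, name in enumerate(samples.param_names):
        chains_j = kept[:, :, j]
        if np.allclose(chains_j, chains_j.flat[0]):
            rhat = np.nan      # degenerate constant chain: flagged
        else:
            rhat = split_rhat(chains_j)
        rows.append({
            "parameter": name,
            "median": float(np.median(pooled[:, j])),
            "q2.5": float(np.quantile(pooled[:, j], 0.025)),
            "q97.5": float(np.quantile(pooled[:, j], 0.975)),
            "acceptance": float(np.mean(samples.acceptance_rates)),
            "rhat": rhat,
        })
    return pd.DataFrame(rows).set_index("parameter")
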