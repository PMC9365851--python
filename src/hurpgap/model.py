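"""Model/Results interface to the HURP fibre model.

:class:`KFiberHurpModel` wraps an observed line-profile dataset together
with priors and fixed parameters; ``fit()`` runs the pilot-tuned Random
Walk Metropolis sampler and returns a :class:`KFiberHurpResults` carrying
the posterior draws, credible intervals, convergence diagnostics and a
``summary()`` table.  Forward simulation, simulated FRAP, sensitivity
sweeps and plotting hang off these two objects.
"""

from __future__ import annotations

import numpy as np

from .datasets import ObservedProfileDataset, estimate_sigma
from .exceptions import InvalidParameterError
from .inference import (McmcConfig, PosteriorSamples, log_likelihood,
                        make_loglik, run_mcmc, summarize_posterior)
from .parameters import ModelParameters, SpatialGrid
from .pde import alternating_run
from .priors import PriorSpec
from .sensitivity import sensitivity_sweep

__all__ = ["KFiberHurpModel", "KFiberHurpResults"]


class KFiberHurpModel:
    """HURP advection-diffusion-reaction model bound to observed profiles.

    Parameters
    ----------
    data : ObservedProfileDataset
        Leading/trailing intensity profiles on the observation grid.
    priors : PriorSpec, optional
        Defaults to the package's weakly informative log-normal priors
        with a tight prior on the binding ratio r.
    fixed : dict, optional
        Values for parameters excluded from inference (names listed in
        ``priors.fixed``) plus optionally ``sigma`` and ``L``.  If sigma
        is absent it is taken from the dataset.
    grid : SpatialGrid, optional
        Internal solver grid; defaults to 90 cells over L (finer than the
        104 nm observation spacing).
    """

    def __init__(self, data: ObservedProfileDataset,
                 priors: PriorSpec | None = None,
                 fixed: dict | None = None,
                 grid: SpatialGrid | None = None,
                 eq_tol: float = 1e-6):
        self.data = data
        self.priors = priors if priors is not None else PriorSpec.default()
        fixed = dict(fixed or {})
        fixed.setdefault("sigma", data.sigma)
        missing = [n for n in self.priors.fixed if n not in fixed]
        if missing:
            raise InvalidParameterError(
                f"priors fix {missing} but no values were supplied")
        self.fixed = fixed
        self.base_params = ModelParameters().replace(**fixed)
        self.grid = grid if grid is not None else SpatialGrid(
            L=self.base_params.L, n_cells=90)
        self.eq_tol = eq_tol
        self._loglik = make_loglik(data, self.base_params, self.priors,
                                   self.grid, eq_tol=eq_tol)

    @classmethod
    def from_table(cls, path, sigma: float | None = None, **kwargs
                   ) -> "KFiberHurpModel":
        """Build the model from a tab-separated profile table.

        If ``sigma`` is not given it is estimated from the data as the
        standard deviation of spatial first differences divided by
        sqrt(2).
        """
        from .io import read_profile_table

        data = read_profile_table(path, sigma=sigma)
        if not isinstance(data, ObservedProfileDataset):
            raise InvalidParameterError(
                "profile table must contain both leading and trailing sides")
        return cls(data, **kwargs)

    # -- likelihood surface -------------------------------------------------

    def loglike(self, params) -> float:
        """Log likelihood at a ModelParameters or free-parameter vector."""
        if isinstance(params, ModelParameters):
            theta = np.array([getattr(params, n) for n in self.priors.free_names])
        else:
            theta = np.asarray(params, dtype=float)
        return self._loglik(theta)

    def simulate(self, params: ModelParameters, t_lead: float | None = None,
                 t_trail: float | None = None, dt_out: float | None = None):
        """(leading, trailing) profile pair at ``params``."""
        duration = float(self.data.t_obs[-1] - self.data.t_obs[0])
        dt = float(self.data.t_obs[1] - self.data.t_obs[0])
        return alternating_run(params, self.grid,
                               t_lead if t_lead is not None else duration,
                               t_trail if t_trail is not None else duration,
                               dt_out if dt_out is not None else dt,
                               eq_tol=self.eq_tol)

    # -- fitting ------------------------------------------------------------

    def fit(self, config: McmcConfig | None = None, seed: int | None = None,
            **config_overrides) -> "KFiberHurpResults":
        """Sample the posterior; returns a results object."""
        if config is None:
            config = McmcConfig(**config_overrides)
        elif config_overrides:
            raise InvalidParameterError(
                "pass either a config object or keyword overrides, not both")
        if seed is not None:
            config = McmcConfig(**{**config.__dict__, "seed": seed})
        posterior = run_mcmc(self.data, self.priors, config,
                             fixed=self.base_params, grid=self.grid,
                             eq_tol=self.eq_tol)
        return KFiberHurpResults(self, posterior, config)


class KFiberHurpResults:
    """Posterior summaries and downstream analyses of a fitted model."""

    def __init__(self, model: KFiberHurpModel, posterior: PosteriorSamples,
                 config: McmcConfig):
        self.model = model
        self.posterior = posterior
        self.config = config
        self._summary = None

    @property
    def summary_frame(self):
        """Pandas DataFrame: median, 95% interval, acceptance, R-hat."""
        if self._summary is None:
            self._summary = summarize_posterior(self.posterior)
        return self._summary

    @property
    def params(self):
        """Posterior medians as a pandas Series."""
        return self.summary_frame["median"]

    def conf_int(self, alpha: float = 0.05):
        """Central (1 - alpha) credible intervals on pooled draws."""
        import pandas as pd

        pooled = self.posterior.pooled()
        lo = np.quantile(pooled, alpha / 2, axis=0)
        hi = np.quantile(pooled, 1 - alpha / 2, axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi},
                            index=list(self.posterior.param_names))

    @property
    def rhat(self):
        return self.summary_frame["rhat"]

    @property
    def acceptance_rates(self) -> np.ndarray:
        return self.posterior.acceptance_rates

    @property
    def fitted_params(self) -> ModelParameters:
        """ModelParameters at the posterior medians (fixed values kept)."""
        return self.model.base_params.replace(
            **{n: float(v) for n, v in self.params.items()})

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.summary_frame
        lines = ["K-fibre HURP model - posterior summary",
                 "=" * 54,
                 f"chains: {self.posterior.n_chains}   "
                 f"iterations: {self.posterior.draws.shape[1]}   "
                 f"burn-in: {self.posterior.burn_in}",
                 f"mean acceptance: {np.mean(self.acceptance_rates):.3f}",
                 "-" * 54,
                 df.to_string(float_format=lambda v: f"{v:.4g}"),
                 "=" * 54]
        return "\n".join(lines)

    # -- downstream analyses at the fitted parameters ------------------------

    def simulate_fitted(self, **kwargs):
        """Forward alternation run at the posterior medians."""
        return self.model.simulate(self.fitted_params, **kwargs)

    def loglike_at_median(self) -> float:
        runs = self.simulate_fitted()
        return log_likelihood(self.fitted_params, self.model.data, runs)

    def simulate_frap(self, bleach_from: float = 1.5, **kwargs):
        from .frap import simulate_frap

        return simulate_frap(self.fitted_params, self.model.grid,
                             bleach_from=bleach_from, **kwargs)

    def sensitivity(self, param: str, values, **kwargs):
        return sensitivity_sweep(self.fitted_params, param, values,
                                 grid=self.model.grid, **kwargs)

    # -- plotting (decoration) ----------------------------------------------

    def plot_posterior(self, axes=None):
        """Histograms of the posterior marginals, one panel per parameter."""
        import matplotlib.pyplot as plt

        pooled = self.posterior.pooled()
        names = self.posterior.param_names
        if axes is None:
            _, axes = plt.subplots(2, (len(names) + 1) // 2,
                                   figsize=(3 * ((len(names) + 1) // 2), 6))
        axes = np.ravel(axes)
        for ax, j in zip(axes, range(len(names))):
            ax.hist(pooled[:, j], bins=40, density=True, color="steelblue")
            ax.set_title(names[j])
        return axes

    def plot_traces(self, axes=None):
        """Per-chain trace plots (convergence check)."""
        import matplotlib.pyplot as plt

        names = self.posterior.param_names
        if axes is None:
            _, axes = plt.subplots(len(names), 1,
                                   figsize=(6, 1.5 * len(names)), sharex=True)
        axes = np.ravel(axes)
        for ax, j in zip(axes, range(len(names))):
            for c in range(self.posterior.n_chains):
                ax.plot(self.posterior.draws[c, :, j], lw=0.5)
            ax.axvline(self.posterior.burn_in, color="k", ls="--", lw=0.8)
            ax.set_ylabel(names[j])
        return axes
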