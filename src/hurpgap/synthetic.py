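"""Synthetic data emulating the study's inputs.

Three generators cover every input the pipeline consumes:

* spatiotemporal line-profile datasets on the kinetochore-tracking
  observation grid (one sample per 104 nm pixel, one per 4.1 s frame,
  profiles spanning 3 um from the kinetochore) with additive Gaussian
  noise of fixed sigma;
* 1-D Brownian particle traces for MSD analysis;
* raw FRAP channel series (bleach ROI / whole-spindle reference /
  background) with a mono-exponential recovery of known timescale and
  mobile fraction.

Each generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import numpy as np

from .datasets import FrapRawSeries, ObservedProfileDataset, ParticleTraceSet
from .exceptions import InvalidParameterError
from .parameters import ModelParameters, SpatialGrid
from .pde import alternating_run, default_grid, equilibrium_profile

__all__ = ["default_true_params", "generate_profile_dataset",
           "generate_particle_traces", "generate_frap_series"]


def default_true_params() -> ModelParameters:
    """Ground-truth fixture for recovery experiments.

    Orders of magnitude anchored to measured scales: a mixed-nucleotide
    zone of ~1.5 um, lattice diffusion ~0.024 um^2/s, turnover ~0.1/s,
    kinetochore speeds ~0.02 um/s, a RanGTP scale of a few microns and a
    fourfold GDP/GTP binding preference.  These are test fixtures, not
    fitted values.
    """
    return ModelParameters(l=1.5, D=0.024, lam=0.1, mu=0.1,
                           v_plus=0.02, v_minus=0.02,
                           gamma1=0.01, gamma2=0.01, s=3.0, r=4.0,
                           sigma=0.05, L=3.0)


def generate_profile_dataset(true_params: ModelParameters | None = None,
                             t_lead: float = 60.0, t_trail: float = 60.0,
                             sigma: float | None = None, seed: int = 0,
                             grid: SpatialGrid | None = None,
                             ) -> ObservedProfileDataset:
    """Noisy leading/trailing profile dataset from a known parameter set.

    Runs the trailing-equilibrium -> leading -> trailing alternation,
    samples both runs on the observation grid, and adds i.i.d. Gaussian
    noise with standard deviation ``sigma`` (default: 5% of the
    trailing-equilibrium maximum).  Negative noisy values are kept:
    observation noise may undershoot zero.
    """
    if true_params is None:
        true_params = default_true_params()
    if grid is None:
        grid = default_grid(L=true_params.L)
    if sigma is not None and sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")

    x_obs = ObservedProfileDataset.default_x_obs(true_params.L)
    t_obs = ObservedProfileDataset.default_t_obs(min(t_lead, t_trail))
    lead, trail = alternating_run(true_params, grid, t_lead, t_trail,
                                  dt_out=float(t_obs[1] - t_obs[0]))
    H_minus = lead.evaluate_at(x_obs, t_obs)
    H_plus = trail.evaluate_at(x_obs, t_obs)

    if sigma is None:
        eq = equilibrium_profile(true_params, grid, "trailing")
        sigma = 0.05 * float(eq.max())

    rng = np.random.default_rng(seed)
    y_plus = H_plus + sigma * rng.standard_normal(H_plus.shape)
    y_minus = H_minus + sigma * rng.standard_normal(H_minus.shape)
    return ObservedProfileDataset(x_obs=x_obs, t_obs=t_obs,
                                  y_plus=y_plus, y_minus=y_minus,
                                  sigma=max(sigma, 1e-12))


def generate_particle_traces(D: float, n_traces: int, dt: float,
                             n_steps: int, seed: int = 0,
                             x0: float = 0.0) -> ParticleTraceSet:
    """1-D Brownian traces: increments ~ N(0, 2 D dt) per step."""
    if D < 0:
        raise InvalidParameterError("D must be >= 0")
    if n_traces < 1 or n_steps < 1:
        raise InvalidParameterError("need n_traces >= 1 and n_steps >= 1")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    rng = np.random.default_rng(seed)
    incr = np.sqrt(2.0 * D * dt) * rng.standard_normal((n_traces, n_steps))
    pos = np.concatenate([np.full((n_traces, 1), x0), x0 + np.cumsum(incr, axis=1)],
                         axis=1)
    return ParticleTraceSet(traces=list(pos), dt=dt)


def generate_frap_series(tau: float = 10.0, mobile_fraction: float = 0.9,
                         pre_frames: int = 5, n_frames: int = 60,
                         dt: float = 2.0, noise: float = 0.0, seed: int = 0,
                         plateau: float = 1000.0, background: float = 100.0,
                         reference: float = 2000.0, bleach_depth: float = 0.7,
                         ) -> FrapRawSeries:
    """Raw FRAP channels with a known mono-exponential recovery.

    The bleach ROI sits at ``plateau`` before the bleach, drops by
    ``bleach_depth`` of its background-subtracted level at the bleach
    frame, then recovers as mobile_fraction * (1 - exp(-t/tau)) of the
    bleached depth.  Reference and background are constant; optional
    Gaussian noise (sd = ``noise``) is added to every channel.
    """
    if not 0 <= mobile_fraction <= 1:
        raise InvalidParameterError("mobile_fraction must be in [0, 1]")
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    if not 0 < bleach_depth <= 1:
        raise InvalidParameterError("bleach_depth must be in (0, 1]")
    if pre_frames < 1 or n_frames <= pre_frames:
        raise InvalidParameterError("need 1 <= pre_frames < n_frames")

    times = np.arange(n_frames) * dt
    signal_pre = plateau - background
    floor = signal_pre * (1.0 - bleach_depth)
    depth = signal_pre - floor
    bleach = np.empty(n_frames)
    bleach[:pre_frames] = plateau
    t_post = times[pre_frames:] - times[pre_frames]
    bleach[pre_frames:] = background + floor \
        + mobile_fraction * depth * (1.0 - np.exp(-t_post / tau))

    ref = np.full(n_frames, reference)
    back = np.full(n_frames, background)
    if noise > 0:
        rng = np.random.default_rng(seed)
        bleach = bleach + noise * rng.standard_normal(n_frames)
        ref = ref + noise * rng.standard_normal(n_frames)
        back = back + noise * rng.standard_normal(n_frames)
    return FrapRawSeries(times=times, bleach_roi=np.clip(bleach, 0, None),
                         reference=np.clip(ref, 0, None),
                         background=np.clip(back, 0, None),
                         pre_bleach_count=pre_frames)
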