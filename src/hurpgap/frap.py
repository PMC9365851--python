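"""FRAP analysis: double normalisation, mono-exponential fitting, and
simulated photobleaching of the fitted PDE model.

The double normalisation divides the background-subtracted bleach-ROI
signal by its pre-bleach mean and multiplies by the inverse evolution of
the background-subtracted whole-structure reference, which corrects for
acquisition photobleaching:

    FRAP(t) = (Bleach(t) - Back(t)) / (Bleach_pre - Back_pre)
            * (Ref_pre - Back_pre) / (Ref(t) - Back(t))

Pre-bleach means are taken over the pre-bleach frames, so normalised
pre-bleach values average to 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datasets import FrapRawSeries
from .exceptions import FitError, InvalidParameterError, NormalisationError
from .parameters import ModelParameters, SpatialGrid
from .pde import equilibrium_profile, simulate

__all__ = ["FrapRecoveryCurve", "frap_double_normalise",
           "fit_monoexponential", "simulate_frap"]


@dataclass
class FrapRecoveryCurve:
    """Normalised FRAP signal, optionally with mono-exponential fit results.

    ``tau`` is the recovery timescale (s) and ``mobile_fraction`` the
    recovered fraction of the bleached depth relative to the pre-bleach
    level; both are None until fitted.
    """

    times: np.ndarray
    signal: np.ndarray
    t_bleach: float
    tau: float | None = None
    mobile_fraction: float | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise InvalidParameterError("times and signal must have equal length")
        if self.mobile_fraction is not None and self.mobile_fraction > 1.05:
            raise InvalidParameterError(
                f"mobile_fraction {self.mobile_fraction:.3f} far above 1: bad fit")


def frap_double_normalise(raw: FrapRawSeries) -> FrapRecoveryCurve:
    """Double-normalised FRAP curve from raw channel series."""
    pre = slice(0, raw.pre_bleach_count)
    bleach_pre = float(np.mean(raw.bleach_roi[pre]))
    ref_pre = float(np.mean(raw.reference[pre]))
    back_pre = float(np.mean(raw.background[pre]))

    if bleach_pre == back_pre:
        raise NormalisationError("pre-bleach bleach-ROI equals background")
    denom = raw.reference - raw.background
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise NormalisationError(
            f"reference equals background at frame {int(bad[0])}")

    signal = ((raw.bleach_roi - raw.background) / (bleach_pre - back_pre)
              * (ref_pre - back_pre) / denom)
    t_bleach = float(raw.times[raw.pre_bleach_count])
    return FrapRecoveryCurve(times=raw.times.copy(), signal=signal,
                             t_bleach=t_bleach)


def fit_monoexponential(curve: FrapRecoveryCurve,
                        t_bleach: float | None = None) -> FrapRecoveryCurve:
    """Least-squares mono-exponential recovery fit.

    Fits f(t) = F0 + A (1 - exp(-(t - t_bleach)/tau)) to the post-bleach
    points.  The mobile fraction is the recovered share of the bleached
    depth, A / (1 - F0), where F0 is the fitted post-bleach floor of the
    (pre-bleach-normalised) signal.  Returns a new curve carrying the fit.
    """
    if t_bleach is None:
        t_bleach = curve.t_bleach
    post = curve.times >= t_bleach
    t = curve.times[post] - t_bleach
    y = curve.signal[post]
    if t.size < 4:
        raise InvalidParameterError("need >= 4 post-bleach points to fit")

    def f(t, F0, A, tau):
        return F0 + A * (1.0 - np.exp(-t / tau))

    span = float(t[-1] - t[0]) or 1.0
    p0 = (float(y[0]), float(y[-1] - y[0]), span / 5.0)
    try:
        popt, _ = curve_fit(f, t, y, p0=p0,
                            bounds=([-np.inf, -np.inf, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20_000)
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    F0, A, tau = map(float, popt)
    resid = float(np.linalg.norm(y - f(t, *popt)))
    if A <= 0 or abs(A) < 1e-12:
        mobile = 0.0
        tau = float(tau)
    else:
        depth = 1.0 - F0
        mobile = A / depth if depth > 1e-12 else 0.0
    return FrapRecoveryCurve(times=curve.times.copy(),
                             signal=curve.signal.copy(),
                             t_bleach=t_bleach, tau=tau,
                             mobile_fraction=mobile, fit_residual=resid)


def simulate_frap(params: ModelParameters, grid: SpatialGrid,
                  bleach_from: float = 1.5, duration: float = 60.0,
                  dt_out: float = 0.5) -> FrapRecoveryCurve:
    """Simulated photobleaching of the trailing-side steady state.

    Starts from the trailing equilibrium, zeroes H for x > ``bleach_from``
    (the bleached region), evolves the model, and reports the mean
    intensity over the bleached region normalised to its pre-bleach
    equilibrium mean.  A mono-exponential fit supplies the recovery
    timescale.
    """
    if not 0 < bleach_from < params.L:
        raise InvalidParameterError("bleach_from must lie inside (0, L)")
    eq = equilibrium_profile(params, grid, "trailing")
    region = grid.x > bleach_from
    if not region.any():
        raise InvalidParameterError("bleached region contains no grid cells")
    pre_mean = float(eq[region].mean())
    if pre_mean <= 0:
        raise InvalidParameterError("equilibrium vanishes in the bleached region")

    bleached = eq.copy()
    bleached[region] = 0.0
    run = simulate(params, grid, bleached, duration, dt_out, "trailing")
    signal = run.H[:, region].mean(axis=1) / pre_mean
    curve = FrapRecoveryCurve(times=run.times, signal=signal, t_bleach=0.0)
    return fit_monoexponential(curve)
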