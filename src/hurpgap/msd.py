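"""Mean-squared-displacement analysis of 1-D particle traces.

For lattice diffusion in one dimension MSD(lag) = 2 D lag, so the
diffusion coefficient is half the slope of the short-lag MSD line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import ParticleTraceSet
from .exceptions import InvalidParameterError

__all__ = ["MsdCurve", "compute_msd", "estimate_diffusion"]


@dataclass
class MsdCurve:
    """Time- and ensemble-averaged MSD with pair counts per lag."""

    lags: np.ndarray       # s, starting at 0
    msd: np.ndarray        # um^2
    n_pairs: np.ndarray    # displacement pairs entering each lag
    D: float | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lags.shape == self.msd.shape == self.n_pairs.shape):
            raise InvalidParameterError("lags, msd and n_pairs must align")
        if np.any(self.msd < 0):
            raise InvalidParameterError("msd must be non-negative")


def compute_msd(traces: ParticleTraceSet, max_lag: float) -> MsdCurve:
    """Time- and ensemble-averaged MSD up to ``max_lag`` seconds.

    For each lag k*dt, averages (x(t + lag) - x(t))^2 over all traces and
    all valid (overlapping) start points.
    """
    dt = traces.dt
    shortest = min(tr.size for tr in traces.traces)
    max_k = int(np.floor(max_lag / dt + 1e-9))
    if max_k < 1:
        raise InvalidParameterError("max_lag must cover at least one step")
    if max_k > shortest - 1:
        raise InvalidParameterError(
            f"max_lag {max_lag} s exceeds the shortest trace span "
            f"({(shortest - 1) * dt} s)")

    lags = np.arange(max_k + 1) * dt
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1, dtype=int)
    counts[0] = sum(tr.size for tr in traces.traces)
    for tr in traces.traces:
        for k in range(1, max_k + 1):
            d = tr[k:] - tr[:-k]
            sums[k] += float(np.dot(d, d))
            counts[k] += d.size
    msd = np.zeros(max_k + 1)
    msd[1:] = sums[1:] / counts[1:]
    return MsdCurve(lags=lags, msd=msd, n_pairs=counts)


def estimate_diffusion(msd: MsdCurve, fit_lags: int = 5) -> float:
    """Diffusion coefficient from the short-lag MSD slope.

    Ordinary least squares of MSD against lag over the first ``fit_lags``
    non-zero lags, intercept free; D = slope / 2.  A constant MSD yields
    0 with a warning.
    """
    if fit_lags < 2:
        raise InvalidParameterError("fit_lags must be >= 2")
    if fit_lags > msd.lags.size - 1:
        raise InvalidParameterError("fit_lags exceeds available lags")
    x = msd.lags[1:fit_lags + 1]
    y = msd.msd[1:fit_lags + 1]
    if np.allclose(y, y[0]):
        warnings.warn("MSD is constant over the fit range; returning D = 0",
                      stacklevel=2)
        msd.D = 0.0
        return 0.0
    slope, _ = np.polyfit(x, y, 1)
    D = float(slope / 2.0)
    msd.D = D
    return D
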