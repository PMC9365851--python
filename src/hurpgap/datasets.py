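"""Observed-data containers: line profiles, particle traces, FRAP series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["ObservedProfileDataset", "ParticleTraceSet", "FrapRawSeries",
           "OBS_DX_UM", "OBS_DT_S"]

#: Observation grid of the kinetochore-tracking assay: one sample per
#: pixel in space and per frame in time.
OBS_DX_UM = 0.104
OBS_DT_S = 4.1


@dataclass
class ObservedProfileDataset:
    """Noisy HURP line profiles for a sister pair around one switch.

    ``y_plus`` holds the trailing-side intensities, ``y_minus`` the
    leading-side intensities, both of shape (len(t_obs), len(x_obs)).
    ``sigma`` is the fixed Gaussian measurement error.
    """

    x_obs: np.ndarray
    t_obs: np.ndarray
    y_plus: np.ndarray
    y_minus: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        self.t_obs = np.asarray(self.t_obs, dtype=float)
        self.y_plus = np.asarray(self.y_plus, dtype=float)
        self.y_minus = np.asarray(self.y_minus, dtype=float)
        shape = (self.t_obs.size, self.x_obs.size)
        for name, y in (("y_plus", self.y_plus), ("y_minus", self.y_minus)):
            if y.shape != shape:
                raise InvalidParameterError(
                    f"{name} has shape {y.shape}, expected {shape}")
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")

    @property
    def n_points(self) -> int:
        """Total number of observations across both sides."""
        return 2 * self.t_obs.size * self.x_obs.size

    @staticmethod
    def default_x_obs(L: float = 3.0) -> np.ndarray:
        """Pixel positions: every 104 nm over [0, L]."""
        return np.arange(0.0, L + 1e-9, OBS_DX_UM)

    @staticmethod
    def default_t_obs(duration: float) -> np.ndarray:
        """Frame times: every 4.1 s over [0, duration]."""
        return np.arange(0.0, duration + 1e-9, OBS_DT_S)


def estimate_sigma(y: np.ndarray) -> float:
    """Noise scale from the data itself.

    Standard deviation of first differences along the spatial axis divided
    by sqrt(2): differencing cancels the smooth signal component and doubles
    the noise variance.
    """
    y = np.asarray(y, dtype=float)
    return float(np.std(np.diff(y, axis=-1)) / np.sqrt(2.0))


@dataclass
class ParticleTraceSet:
    """1-D particle positions sampled at a uniform interval ``dt``."""

    traces: list
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        self.traces = [np.asarray(tr, dtype=float) for tr in self.traces]
        if not self.traces:
            raise InvalidParameterError("trace set must not be empty")
        for k, tr in enumerate(self.traces):
            if tr.size < 2:
                raise InvalidParameterError(f"trace {k} has fewer than 2 points")


@dataclass
class FrapRawSeries:
    """Raw FRAP channels: bleach ROI, whole-spindle reference, background.

    The first ``pre_bleach_count`` frames precede the bleach pulse.
    """

    times: np.ndarray
    bleach_roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    pre_bleach_count: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        for name in ("bleach_roi", "reference", "background"):
            if getattr(self, name).size != n:
                raise InvalidParameterError(
                    f"{name} length differs from times ({n})")
        if self.pre_bleach_count < 1:
            raise InvalidParameterError("pre_bleach_count must be >= 1")
        if self.pre_bleach_count >= n:
            raise InvalidParameterError("no post-bleach frames present")
        for name in ("bleach_roi", "reference", "background"):
            if np.any(getattr(self, name) < 0):
                raise InvalidParameterError(f"{name} has negative intensities")
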