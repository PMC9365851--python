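"""Domain types for the kinetochore-fibre HURP model.

The model lives on a 1-D coordinate x measured in micrometres from the
kinetochore (x = 0) toward the spindle pole, over a fibre segment of length
``L``.  HURP intensity H(x, t) obeys an advection-diffusion-reaction
equation whose parameters are collected in :class:`ModelParameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = ["ModelParameters", "SpatialGrid", "HurpProfile", "PARAM_NAMES"]

#: Order of the dynamic parameter vector theta used throughout inference.
PARAM_NAMES = ("l", "D", "lam", "mu", "v_plus", "v_minus",
               "gamma1", "gamma2", "s", "r")


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the HURP reaction-diffusion-advection model.

    Attributes
    ----------
    l : float
        Length of the GTP-cap plus mixed-nucleotide zone (um).  On the
        leading (depolymerising) side this zone is effectively absent and
        the binding profile uses l = 0.
    D : float
        HURP diffusion coefficient on the lattice (um^2/s).
    lam : float
        Maximal binding rate of HURP to the GDP lattice (intensity/s).
    mu : float
        Unbinding rate (1/s).
    v_plus : float
        Advection speed magnitude on the trailing (polymerising) fibre
        (um/s).  New lattice is added at the kinetochore, so bound material
        recedes toward +x.
    v_minus : float
        Advection speed magnitude on the leading (depolymerising) fibre
        (um/s); material flows toward the kinetochore (-x).
    gamma1, gamma2 : float
        Robin boundary interaction strengths at the kinetochore (x = 0) and
        at the far end (x = L) respectively (um/s).  Zero is reflecting
        (no flux); large values approach an absorbing boundary.
    s : float
        Length scale of the chromosome-centred RanGTP gradient
        g(x) = exp(-x/s) (um).
    r : float
        Ratio of GDP-lattice to GTP-cap binding rates (dimensionless,
        > 0); the binding rate ramps linearly from lam/r at x = 0 to lam
        at x = l.
    sigma : float
        Fixed Gaussian observation noise (intensity units).
    L : float
        Length of the modelled fibre segment (um).
    """

    l: float = 1.5
    D: float = 0.024
    lam: float = 0.1
    mu: float = 0.1
    v_plus: float = 0.02
    v_minus: float = 0.02
    gamma1: float = 0.01
    gamma2: float = 0.01
    s: float = 3.0
    r: float = 4.0
    sigma: float = 0.05
    L: float = 3.0

    def __post_init__(self) -> None:
        for name in ("l", "D", "lam", "mu", "v_plus", "v_minus",
                     "gamma1", "gamma2", "sigma", "L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.l > self.L:
            raise ValueError(f"l = {self.l} exceeds domain length L = {self.L}")

    def theta(self) -> np.ndarray:
        """Dynamic parameter vector in the canonical order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def with_theta(self, theta: np.ndarray) -> "ModelParameters":
        """New parameter set with the dynamic vector replaced."""
        return replace(self, **dict(zip(PARAM_NAMES, map(float, theta))))

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class SpatialGrid:
    """Cell-centred finite-volume grid on [0, L].

    Cell centres sit at x_k = (k + 1/2) dx with dx = L / n_cells; x is the
    distance from the kinetochore along the fibre.
    """

    L: float
    n_cells: int
    dx: float = field(init=False)
    x: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        dx = self.L / self.n_cells
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "x", (np.arange(self.n_cells) + 0.5) * dx)


@dataclass
class HurpProfile:
    """HURP intensity field H(x, t) on one fibre side.

    ``H`` has one row per entry of ``times`` and one column per grid cell.
    ``side`` is ``"leading"`` or ``"trailing"``.
    """

    grid: SpatialGrid
    times: np.ndarray
    H: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.side not in ("leading", "trailing"):
            raise ValueError(f"side must be 'leading' or 'trailing', got {self.side!r}")
        if self.H.shape != (self.times.size, self.grid.n_cells):
            raise ValueError(
                f"H shape {self.H.shape} does not match "
                f"(n_times={self.times.size}, n_cells={self.grid.n_cells})")
        if self.H.min(initial=0.0) < -1e-9:
            raise ValueError(f"H has negative entries below tolerance: min={self.H.min()}")

    @property
    def final(self) -> np.ndarray:
        """Profile at the last sampled time."""
        return self.H[-1]

    def evaluate_at(self, x_obs: np.ndarray, t_obs: np.ndarray) -> np.ndarray:
        """Linear interpolation of H onto observation points.

        Space is interpolated linearly between cell centres (constant
        extrapolation within the boundary half-cells); time linearly
        between stored frames.  Returns shape (len(t_obs), len(x_obs)).
        """
        x_obs = np.asarray(x_obs, dtype=float)
        t_obs = np.asarray(t_obs, dtype=float)
        if t_obs.min() < self.times[0] - 1e-9 or t_obs.max() > self.times[-1] + 1e-9:
            raise ValueError("t_obs outside simulated time range")
        # interpolate in time first (rows), then in space
        out_t = np.empty((t_obs.size, self.grid.n_cells))
        for j in range(self.grid.n_cells):
            out_t[:, j] = np.interp(t_obs, self.times, self.H[:, j])
        out = np.empty((t_obs.size, x_obs.size))
        for i in range(t_obs.size):
            out[i] = np.interp(x_obs, self.grid.x, out_t[i])
        return out
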