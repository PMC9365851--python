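"""Prior specification for the model parameters.

All dynamic parameters are positive, so priors default to independent
log-normals.  They are weakly informative (unit spread on the log scale)
around order-of-magnitude-plausible centres, except for the binding ratio
``r`` which carries a tight prior around 4: in vitro, HURP binds the GDP
lattice about fourfold more strongly than a GTP-analogue lattice, and the
line-profile data alone constrain ``r`` poorly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .parameters import PARAM_NAMES

__all__ = ["LogNormalPrior", "PriorSpec"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior: log(value) ~ N(log(median), log_sd^2)."""

    median: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.log_sd <= 0:
            raise InvalidParameterError(
                "log-normal prior needs median > 0 and log_sd > 0")

    def logpdf(self, v: float) -> float:
        if v <= 0 or not np.isfinite(v):
            return -np.inf
        z = (math.log(v) - math.log(self.median)) / self.log_sd
        return -math.log(v * self.log_sd) - 0.5 * (_LOG_2PI + z * z)

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * np.exp(self.log_sd * rng.standard_normal()))


#: Order-of-magnitude defaults for the weakly informative priors (package
#: defaults, overridable; units as in ModelParameters).
_DEFAULT_MEDIANS = {
    "l": 1.0, "D": 0.02, "lam": 0.1, "mu": 0.1,
    "v_plus": 0.02, "v_minus": 0.02,
    "gamma1": 0.01, "gamma2": 0.01, "s": 3.0, "r": 4.0,
}


@dataclass
class PriorSpec:
    """Per-parameter priors plus the set of parameters held fixed.

    ``priors`` maps every dynamic parameter name to a distribution with
    ``logpdf``/``sample``; names in ``fixed`` are excluded from inference
    (their values come from the model's fixed-parameter template).
    """

    priors: dict = field(default_factory=dict)
    fixed: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.fixed = frozenset(self.fixed)
        unknown = set(self.priors) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"priors for unknown parameters: {sorted(unknown)}")
        unknown = self.fixed - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"fixed names not parameters: {sorted(unknown)}")
        missing = [n for n in self.free_names if n not in self.priors]
        if missing:
            raise InvalidParameterError(f"inferred parameters lack priors: {missing}")

    @property
    def free_names(self) -> tuple:
        """Inferred parameters, in canonical order."""
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    @classmethod
    def default(cls, fixed=(), log_sd: float = 1.0,
                r_log_sd: float = 0.1) -> "PriorSpec":
        """Weakly informative log-normal priors; tight prior on r."""
        priors = {name: LogNormalPrior(_DEFAULT_MEDIANS[name],
                                       r_log_sd if name == "r" else log_sd)
                  for name in PARAM_NAMES}
        return cls(priors=priors, fixed=frozenset(fixed))

    def log_prior(self, theta: np.ndarray) -> float:
        """Joint log prior density of the free-parameter vector."""
        theta = np.asarray(theta, dtype=float)
        names = self.free_names
        if theta.shape != (len(names),):
            raise InvalidParameterError(
                f"theta has shape {theta.shape}, expected ({len(names)},)")
        total = 0.0
        for name, v in zip(names, theta):
            lp = self.priors[name].logpdf(float(v))
            if lp == -np.inf:
                return -np.inf
            total += lp
        return total

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the free-parameter vector from the prior."""
        return np.array([self.priors[n].sample(rng) for n in self.free_names])

    def medians(self) -> np.ndarray:
        return np.array([self.priors[n].median for n in self.free_names])
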