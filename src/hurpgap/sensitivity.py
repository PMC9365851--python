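"""Sensitivity of the HURP-gap to the mixed-nucleotide zone length and the
trailing-side polymerisation speed."""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError
from .parameters import ModelParameters, SpatialGrid
from .pde import default_grid, equilibrium_profile, measure_gap, simulate

__all__ = ["sensitivity_sweep"]

_SWEEPABLE = ("l", "v_plus")


def sensitivity_sweep(base: ModelParameters, param: str, values,
                      grid: SpatialGrid | None = None,
                      t_settle: float = 300.0,
                      frac: float = 0.5) -> list[tuple[float, float]]:
    """Gap size of the trailing-side long-time state across a parameter sweep.

    For each value of ``param`` (the zone length ``l`` or the polymerisation
    speed ``v_plus``) the trailing side is run for ``t_settle`` seconds
    starting from the trailing equilibrium of ``base`` (all other
    parameters untouched), and the half-maximum gap of the final profile
    is measured.  Returns a list of (value, gap_um) pairs.
    """
    if param not in _SWEEPABLE:
        raise InvalidParameterError(
            f"sweep parameter must be one of {_SWEEPABLE}, got {param!r}")
    if t_settle <= 0:
        raise InvalidParameterError("t_settle must be > 0")
    if grid is None:
        grid = default_grid(L=base.L)

    init = equilibrium_profile(base, grid, "trailing")
    out = []
    for v in np.asarray(values, dtype=float):
        params = base.replace(**{param: float(v)})
        run = simulate(params, grid, init, t_settle, t_settle, "trailing")
        out.append((float(v), measure_gap(run.final, grid.x, frac=frac)))
    return out
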