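"""Deterministic forward machinery for HURP dynamics on a kinetochore-fibre.

The model is the linear advection-diffusion-reaction equation

    dH/dt + v dH/dx = D d2H/dx2 + lambda(x) g(x) - mu H,   x in (0, L),

with g(x) = exp(-x/s) the stationary RanGTP gradient, lambda(x) the
piecewise-linear binding profile rising from lam/r at the kinetochore to
lam at the end of the mixed-nucleotide zone (x = l), and partially
absorbing Robin boundaries at both ends: the outward diffusive flux at
boundary i equals gamma_i * H(boundary).  gamma = 0 recovers a reflecting
(no-flux) wall; gamma -> infinity an absorbing one.

Discretisation is a cell-centred finite-volume scheme: second-order
central differences for diffusion, first-order upwinding for advection
(direction chosen by the sign of v), and ghost-value elimination of the
Robin relations at the boundary faces; the advective flux at an inflow
face uses the boundary value implied by the Robin relation.  The
semi-discrete system dH/dt = A H + b is linear, so time integration is an
exact matrix-exponential step: unconditionally stable, with no temporal
truncation error, and non-negativity preserving (A is a Metzler matrix).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .exceptions import (ConvergenceError, InvalidParameterError,
                         SolverDivergenceError, UndefinedGapError)
from .parameters import HurpProfile, ModelParameters, SpatialGrid

__all__ = ["ran_gradient", "binding_profile", "build_operator", "simulate",
           "equilibrium_profile", "alternating_run", "measure_gap",
           "default_grid"]

#: Default internal resolution: dx = L / 300.
DEFAULT_N_CELLS = 300


def default_grid(L: float = 3.0, n_cells: int = DEFAULT_N_CELLS) -> SpatialGrid:
    """Internal solver grid, finer than the 104 nm observation grid."""
    return SpatialGrid(L=L, n_cells=n_cells)


def ran_gradient(x, s: float):
    """RanGTP gradient factor g(x) = exp(-x/s), in (0, 1].

    Parameters
    ----------
    x : array_like
        Distance from the kinetochore (um), >= 0.
    s : float
        Gradient length scale (um), > 0.
    """
    if s <= 0:
        raise InvalidParameterError(f"gradient scale s must be > 0, got {s}")
    return np.exp(-np.asarray(x, dtype=float) / s)


def binding_profile(x, lam: float, r: float, l: float):
    """Spatial binding rate lambda(x).

    Ramps linearly from lam/r at the kinetochore to lam at the end of the
    GTP-cap/mixed-nucleotide zone (x = l); equals lam on the GDP lattice
    beyond.  l = 0 (leading side) gives the constant rate lam.
    """
    if r <= 0:
        raise InvalidParameterError(f"binding ratio r must be > 0, got {r}")
    if lam < 0 or l < 0:
        raise InvalidParameterError("lam and l must be >= 0")
    x = np.asarray(x, dtype=float)
    if l == 0:
        return np.full_like(x, lam, dtype=float)
    low = lam / r
    return np.where(x < l, low + (lam - low) * x / l, lam)


def _side_velocity(params: ModelParameters, side: str) -> float:
    """Signed advection speed: +v_plus on trailing, -v_minus on leading."""
    if side == "trailing":
        return params.v_plus
    if side == "leading":
        return -params.v_minus
    raise InvalidParameterError(f"side must be 'leading' or 'trailing', got {side!r}")


def build_operator(params: ModelParameters, grid: SpatialGrid, side: str,
                   boundary: str = "robin"):
    """Semi-discrete operator: dH/dt = A H + b.

    Returns the dense matrix ``A`` (n_cells x n_cells) and the source
    vector ``b`` = lambda(x) g(x).  ``boundary='periodic'`` wraps the
    domain (test harness for pure transport); the default applies the
    Robin closures described in the module docstring.
    """
    n, dx = grid.n_cells, grid.dx
    D, mu = params.D, params.mu
    v = _side_velocity(params, side)
    l_eff = params.l if side == "trailing" else 0.0

    b = binding_profile(grid.x, params.lam, params.r, l_eff) \
        * ran_gradient(grid.x, params.s)

    A = np.zeros((n, n))
    idx = np.arange(n)

    # diffusion: interior central differences in flux form
    if D > 0:
        A[idx[:-1], idx[:-1] + 1] += D / dx ** 2
        A[idx[:-1], idx[:-1]] -= D / dx ** 2
        A[idx[1:], idx[1:] - 1] += D / dx ** 2
        A[idx[1:], idx[1:]] -= D / dx ** 2

    if boundary == "periodic":
        if D > 0:
            A[0, -1] += D / dx ** 2
            A[0, 0] -= D / dx ** 2
            A[-1, 0] += D / dx ** 2
            A[-1, -1] -= D / dx ** 2
        if v > 0:
            A[idx[1:], idx[1:] - 1] += v / dx
            A[idx, idx] -= v / dx
            A[0, -1] += v / dx
        elif v < 0:
            A[idx[:-1], idx[:-1] + 1] += -v / dx
            A[idx, idx] -= -v / dx
            A[-1, 0] += -v / dx
    elif boundary == "robin":
        # Robin ghost closure: boundary value H(face) = alpha * H(adjacent cell)
        if D > 0:
            alpha1 = 1.0 / (1.0 + params.gamma1 * dx / (2.0 * D))
            alpha2 = 1.0 / (1.0 + params.gamma2 * dx / (2.0 * D))
        else:
            # no diffusion: gamma H(face) = 0 pins the boundary value to 0
            alpha1 = alpha2 = 0.0
        # outward diffusive flux gamma_i * H(face) at each end
        A[0, 0] -= params.gamma1 * alpha1 / dx
        A[-1, -1] -= params.gamma2 * alpha2 / dx
        # upwind advection
        if v > 0:
            A[idx[1:], idx[1:] - 1] += v / dx
            A[idx, idx] -= v / dx
            A[0, 0] += v * alpha1 / dx          # inflow at x=0 face
        elif v < 0:
            A[idx[:-1], idx[:-1] + 1] += -v / dx
            A[idx, idx] -= -v / dx
            A[-1, -1] += -v * alpha2 / dx       # inflow at x=L face
    else:
        raise InvalidParameterError(f"unknown boundary type {boundary!r}")

    A[idx, idx] -= mu
    return A, b


def _step_matrices(A: np.ndarray, b: np.ndarray, dt: float):
    """Exact one-step propagator: H(t+dt) = E H(t) + c.

    Computed from the exponential of the augmented matrix [[A, b], [0, 0]],
    which handles singular A (e.g. a zero right-hand side) without special
    cases.
    """
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A * dt
    M[:n, n] = b * dt
    P = expm(M)
    return P[:n, :n], P[:n, n]


def simulate(params: ModelParameters, grid: SpatialGrid, initial,
             duration: float, dt_out: float, side: str,
             boundary: str = "robin") -> HurpProfile:
    """Integrate the model forward and sample at multiples of ``dt_out``.

    ``initial`` is the intensity vector on ``grid`` at t = 0.  Output
    times are 0, dt_out, 2*dt_out, ..., up to and including ``duration``
    (with a final partial step if duration is not a multiple of dt_out).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if dt_out <= 0:
        raise InvalidParameterError("dt_out must be > 0")
    H0 = np.asarray(initial, dtype=float)
    if H0.shape != (grid.n_cells,):
        raise InvalidParameterError(
            f"initial has shape {H0.shape}, expected ({grid.n_cells},)")
    if H0.min() < 0:
        raise InvalidParameterError("initial profile must be non-negative")

    A, b = build_operator(params, grid, side, boundary=boundary)
    n_full = int(np.floor(duration / dt_out + 1e-9))
    times = [0.0] + [k * dt_out for k in range(1, n_full + 1)]
    remainder = duration - n_full * dt_out
    if remainder > 1e-9 * max(duration, dt_out):
        times.append(duration)

    E, c = _step_matrices(A, b, dt_out)
    states = np.empty((len(times), grid.n_cells))
    states[0] = H0
    H = H0
    for k in range(1, n_full + 1):
        H = E @ H + c
        states[k] = H
    if len(times) > n_full + 1:
        Er, cr = _step_matrices(A, b, remainder)
        states[-1] = Er @ H + cr

    if not np.all(np.isfinite(states)):
        raise SolverDivergenceError(
            "non-finite state encountered during integration")
    # exponential stepping is positivity preserving; clear roundoff only
    np.clip(states, 0.0, None, out=states)
    return HurpProfile(grid=grid, times=np.array(times), H=states, side=side)


def equilibrium_profile(params: ModelParameters, grid: SpatialGrid, side: str,
                        tol: float = 1e-6, max_time: float = 2000.0,
                        chunk: float = 25.0) -> np.ndarray:
    """Long-time profile, reached by integrating from an empty fibre.

    Convergence is declared when the maximum change per unit time drops
    below ``tol`` relative to the current profile maximum.  Raises
    :class:`ConvergenceError` (carrying the last residual) if the horizon
    ``max_time`` is exhausted first.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    A, b = build_operator(params, grid, side)
    E, c = _step_matrices(A, b, chunk)
    H = np.zeros(grid.n_cells)
    t = 0.0
    residual = np.inf
    while t < max_time:
        H_new = E @ H + c
        if not np.all(np.isfinite(H_new)):
            raise SolverDivergenceError("non-finite state during equilibration")
        t += chunk
        scale = max(float(np.max(np.abs(H_new))), 1e-300)
        residual = float(np.max(np.abs(H_new - H))) / (scale * chunk)
        H = H_new
        if residual < tol:
            return np.clip(H, 0.0, None)
    raise ConvergenceError(
        f"equilibrium not reached within {max_time} s "
        f"(last residual {residual:.3e}/s, tol {tol:.1e}/s)", residual=residual)


def alternating_run(params: ModelParameters, grid: SpatialGrid,
                    t_lead: float, t_trail: float, dt_out: float,
                    eq_tol: float = 1e-6) -> tuple[HurpProfile, HurpProfile]:
    """One leading/trailing alternation cycle around a directional switch.

    The trailing-side equilibrium provides the initial condition of a
    leading-side run of length ``t_lead``; that run's final state seeds a
    trailing-side run of length ``t_trail``.  This is the initial-condition
    chain used when comparing the model against profiles aligned to a
    directional switch.
    """
    if t_lead <= 0 or t_trail <= 0:
        raise InvalidParameterError("t_lead and t_trail must be > 0")
    eq = equilibrium_profile(params, grid, "trailing", tol=eq_tol)
    lead = simulate(params, grid, eq, t_lead, dt_out, "leading")
    trail = simulate(params, grid, lead.final, t_trail, dt_out, "trailing")
    return lead, trail


def measure_gap(profile, x, frac: float = 0.5) -> float:
    """Gap length: smallest x where the profile reaches frac * max.

    Linear interpolation between cell centres locates the crossing; 0.0 if
    the first cell already meets the threshold.  ``profile`` may be a
    :class:`HurpProfile` (its final frame is used) or an intensity vector
    paired with positions ``x``.
    """
    if isinstance(profile, HurpProfile):
        x = profile.grid.x
        profile = profile.final
    p = np.asarray(profile, dtype=float)
    x = np.asarray(x, dtype=float)
    if not 0 < frac < 1:
        raise InvalidParameterError(f"frac must be in (0, 1), got {frac}")
    if p.shape != x.shape:
        raise InvalidParameterError("profile and x must have the same shape")
    m = p.max()
    if m <= 0:
        raise UndefinedGapError("gap undefined for an all-zero profile")
    thr = frac * m
    if p[0] >= thr:
        return 0.0
    k = int(np.argmax(p >= thr))
    # linear interpolation between the straddling cell centres
    return float(x[k - 1] + (thr - p[k - 1]) / (p[k] - p[k - 1]) * (x[k] - x[k - 1]))
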