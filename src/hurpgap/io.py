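"""Readers and writers for the package's tabular dialects.

All files are tab-separated UTF-8 with '.' decimals, one header line of
column names (units embedded in the names), and optional leading comment
lines starting with '#'.  Positions are micrometres from the kinetochore
(x = 0), increasing poleward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .datasets import FrapRawSeries, ObservedProfileDataset, ParticleTraceSet, \
    estimate_sigma
from .exceptions import FormatError, InvalidParameterError
from .inference import PosteriorSamples
from .parameters import HurpProfile, ModelParameters, SpatialGrid

__all__ = ["write_profile_table", "read_profile_table",
           "write_posterior", "read_posterior",
           "write_traces", "read_traces",
           "write_frap_series", "read_frap_series",
           "write_table", "load_config", "save_config"]

_PROFILE_COLUMNS = ["side", "time_s", "position_um", "intensity"]
_POSITION_HEADER = ("# positions are um from the kinetochore (x=0), "
                    "increasing poleward, cell centres\n")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing columns {missing}; "
                          f"found {list(df.columns)}")
    return df


def write_profile_table(path, data) -> None:
    """Write profiles as side / time_s / position_um / intensity rows.

    ``data`` may be an :class:`ObservedProfileDataset`, a single
    :class:`HurpProfile`, or a (leading, trailing) pair of profiles.
    """
    rows = []
    if isinstance(data, ObservedProfileDataset):
        for side, y in (("trailing", data.y_plus), ("leading", data.y_minus)):
            for i, t in enumerate(data.t_obs):
                for j, x in enumerate(data.x_obs):
                    rows.append((side, t, x, y[i, j]))
    else:
        profiles = [data] if isinstance(data, HurpProfile) else list(data)
        for p in profiles:
            for i, t in enumerate(p.times):
                for j, x in enumerate(p.grid.x):
                    rows.append((p.side, t, x, p.H[i, j]))
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_POSITION_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def _side_matrix(df: pd.DataFrame, side: str):
    sub = df[df["side"] == side]
    times = np.sort(sub["time_s"].unique())
    positions = np.sort(sub["position_um"].unique())
    mat = np.full((times.size, positions.size), np.nan)
    pos_index = {p: j for j, p in enumerate(positions)}
    t_index = {t: i for i, t in enumerate(times)}
    for t, x, v in zip(sub["time_s"], sub["position_um"], sub["intensity"]):
        mat[t_index[t], pos_index[x]] = v
    bad = np.argwhere(np.isnan(mat))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"ragged grid: side={side!r}, time={times[i]} s is missing "
            f"position {positions[j]} um")
    return times, positions, mat


def read_profile_table(path, sigma: float | None = None):
    """Parse a profile table.

    Returns an :class:`ObservedProfileDataset` when both sides are
    present (``sigma`` estimated from spatial first differences if not
    supplied), or a :class:`HurpProfile` for a single side whose
    positions form a cell-centred grid.
    """
    df = _read_tsv(path, _PROFILE_COLUMNS)
    sides = set(df["side"].unique())
    unknown = sides - {"leading", "trailing"}
    if unknown:
        raise FormatError(f"unknown side labels {sorted(unknown)} in {path}")

    if sides == {"leading", "trailing"}:
        t_minus, x_minus, y_minus = _side_matrix(df, "leading")
        t_plus, x_plus, y_plus = _side_matrix(df, "trailing")
        if not (np.array_equal(t_minus, t_plus)
                and np.array_equal(x_minus, x_plus)):
            raise FormatError("leading and trailing grids differ")
        if sigma is None:
            sigma = estimate_sigma(np.vstack([y_plus, y_minus]))
        return ObservedProfileDataset(x_obs=x_plus, t_obs=t_plus,
                                      y_plus=y_plus, y_minus=y_minus,
                                      sigma=sigma)

    side = sides.pop()
    times, positions, mat = _side_matrix(df, side)
    dx = np.diff(positions)
    if positions.size < 2 or not np.allclose(dx, dx[0], rtol=1e-6):
        raise FormatError("single-side table has non-uniform positions")
    if not np.isclose(positions[0], dx[0] / 2, rtol=1e-6):
        raise FormatError("single-side positions are not cell centres "
                          "(x[0] must equal dx/2)")
    grid = SpatialGrid(L=float(positions[-1] + dx[0] / 2),
                       n_cells=positions.size)
    return HurpProfile(grid=grid, times=times, H=mat, side=side)


def write_posterior(path, samples: PosteriorSamples) -> None:
    """Long-format posterior draws: chain / iteration / parameter / value."""
    n_chains, n_iter, d = samples.draws.shape
    chain = np.repeat(np.arange(n_chains), n_iter * d)
    iteration = np.tile(np.repeat(np.arange(n_iter), d), n_chains)
    parameter = np.tile(list(samples.param_names), n_chains * n_iter)
    df = pd.DataFrame({"chain": chain, "iteration": iteration,
                       "parameter": parameter,
                       "value": samples.draws.reshape(-1)})
    with open(path, "w") as fh:
        fh.write(f"# burn_in = {samples.burn_in}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_posterior(path) -> pd.DataFrame:
    return _read_tsv(path, ["chain", "iteration", "parameter", "value"])


def write_traces(path, traces: ParticleTraceSet) -> None:
    """Particle traces: trace_id / time_s / position_um."""
    rows = []
    for k, tr in enumerate(traces.traces):
        for i, x in enumerate(tr):
            rows.append((k, i * traces.dt, x))
    df = pd.DataFrame(rows, columns=["trace_id", "time_s", "position_um"])
    with open(path, "w") as fh:
        fh.write(_POSITION_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_traces(path) -> ParticleTraceSet:
    df = _read_tsv(path, ["trace_id", "time_s", "position_um"])
    traces, dts = [], []
    for _, sub in df.groupby("trace_id"):
        sub = sub.sort_values("time_s")
        traces.append(sub["position_um"].to_numpy())
        t = sub["time_s"].to_numpy()
        if t.size >= 2:
            dts.append(t[1] - t[0])
    if not dts:
        raise FormatError(f"{path} contains no usable traces")
    return ParticleTraceSet(traces=traces, dt=float(np.median(dts)))


def write_frap_series(path, raw: FrapRawSeries) -> None:
    """FRAP channels with the pre-bleach frame count as a header key."""
    df = pd.DataFrame({"time_s": raw.times, "bleach": raw.bleach_roi,
                       "reference": raw.reference,
                       "background": raw.background})
    with open(path, "w") as fh:
        fh.write(f"# pre_bleach_frames = {raw.pre_bleach_count}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_frap_series(path) -> FrapRawSeries:
    pre = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "pre_bleach_frames" in line:
                pre = int(line.split("=")[1])
            if not line.startswith("#"):
                break
    if pre is None:
        raise FormatError(f"{path} lacks the '# pre_bleach_frames = N' header")
    df = _read_tsv(path, ["time_s", "bleach", "reference", "background"])
    return FrapRawSeries(times=df["time_s"].to_numpy(),
                         bleach_roi=df["bleach"].to_numpy(),
                         reference=df["reference"].to_numpy(),
                         background=df["background"].to_numpy(),
                         pre_bleach_count=pre)


def write_table(path, columns: dict, comment: str | None = None) -> None:
    """Generic curve/sweep writer: column name (with units) -> values."""
    df = pd.DataFrame(columns)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


_CONFIG_KEYS = {"model", "grid", "priors", "mcmc", "synth", "analyses",
                "seed", "out_dir", "verbosity"}


def load_config(path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path} must contain a mapping at top level")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}; "
                          f"allowed: {sorted(_CONFIG_KEYS)}")
    if "model" in cfg:
        ModelParameters.from_dict(cfg["model"])   # fail fast on bad keys
    return cfg


def save_config(path, cfg: dict) -> None:
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
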