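"""CSV/JSON serialization of trajectories, equilibrium tables and manifests.

Floats are written with 17 significant digits so that round-trips are exact
to the last representable bit.  Trajectory CSVs carry the derived columns
(service supply, species-area equilibrium, extinction and service debts,
speed) alongside the raw state so every figure can be regenerated from the
CSV alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import model
from .equilibria import EquilibriumRecord, equilibrium_table
from .params import ModelParams
from .transients import Trajectory, speed_profile

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_equilibria",
    "manifest",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
_STATE_COLUMNS = ("time", "R", "P", "S")


def trajectory_frame(traj: Trajectory, include_derived: bool = True) -> pd.DataFrame:
    """Tidy per-sample table of a trajectory (see :func:`write_trajectory`)."""
    df = pd.DataFrame({"time": traj.times, "R": traj.states[:, 0], "P": traj.states[:, 1]})
    three_var = traj.states.shape[1] == 3
    if three_var:
        df["S"] = traj.states[:, 2]
    if include_derived and len(df):
        p = traj.params
        R = np.maximum(df["R"].to_numpy(), 0.0)
        seq = np.asarray(model.seq_of_resource(R, p), dtype=float)
        S = df["S"].to_numpy() if three_var else seq
        df["ES"] = np.asarray(model.es_supply(np.maximum(S, 0.0), p), dtype=float)
        df["Seq"] = seq
        df["extinction_debt"] = S - seq
        df["service_debt"] = df["ES"] - np.asarray(
            model.es_supply(seq, p), dtype=float
        )
        if traj.speed is None:
            try:
                speed_profile(traj)
            except ValueError:
                pass
        if traj.speed is not None:
            df["speed"] = np.concatenate([[np.nan], traj.speed])
    return df


def write_trajectory(traj: Trajectory, path: str | Path, include_derived: bool = True) -> Path:
    """Write a trajectory as CSV (lossless float round-trip)."""
    path = Path(path)
    trajectory_frame(traj, include_derived).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectory(path: str | Path, params: ModelParams, variant: str | None = None) -> Trajectory:
    """Read a trajectory CSV back into a :class:`Trajectory`.

    The variant is inferred from the columns (an ``S`` column means the
    extended model) unless given.  Malformed files raise with the offending
    line/column; non-finite state values are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing = [c for c in ("time", "R", "P") if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks required columns {missing}")
    three_var = "S" in df.columns
    state_cols = ["R", "P", "S"] if three_var else ["R", "P"]
    for col in ["time"] + state_cols:
        bad = ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            line = int(np.nonzero(bad)[0][0]) + 2  # header is line 1
            raise ValueError(
                f"non-finite value in trajectory CSV {path} at line {line}, column {col!r}"
            )
    if variant is None:
        variant = "extended" if three_var else "quasistatic"
    times = df["time"].to_numpy(dtype=float)
    states = df[state_cols].to_numpy(dtype=float)
    if len(df) == 0:
        y_end = np.full(len(state_cols), np.nan)
        t_end = float("nan")
    else:
        y_end = states[-1].copy()
        t_end = float(times[-1])
    traj = Trajectory(
        variant=variant,
        params=params,
        times=times,
        states=states,
        solver={"source": str(path)},
        t_end=t_end,
        y_end=y_end,
        termination="horizon",
    )
    if "speed" in df.columns and len(df) > 1:
        traj.speed = df["speed"].to_numpy(dtype=float)[1:]
    return traj


def write_equilibria(records: list[EquilibriumRecord], path: str | Path) -> Path:
    """Write an equilibrium table (one row per equilibrium) as CSV."""
    path = Path(path)
    equilibrium_table(records).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def manifest(paths: Iterable[str | Path]) -> list[dict[str, str]]:
    """Checksummed artifact manifest for a set of written files."""
    return [{"path": str(p), "sha256": _sha256(Path(p))} for p in paths]


def write_manifest(paths: Iterable[str | Path], out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        json.dump(manifest(paths), fh, indent=2)
        fh.write("\n")
    return out
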