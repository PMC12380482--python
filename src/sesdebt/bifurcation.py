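"""Fold-bifurcation loci and equilibrium branch diagrams.

The extended model's sustainable (interior-high) equilibrium disappears in a
fold: as productivity ``c0`` drops (or harvest ``h`` rises) the stable and
unstable interior roots of the equilibrium quadratic collide and vanish.
Because the eliminated condition is ``c0*(1-R/K_max)*(C+D*R) = B`` with
``B = h*q*ES_max*S_max`` linear in ``h``, the fold locus is the straight line

    h_fold(c0) = c0 * (1 - R_m/K_max) * (C + D*R_m) / (q*ES_max*S_max),

where ``R_m = K_max/2 - C/(2D)`` is the fold's resource coordinate —
independent of both ``c0`` and ``h``.  The unstable interior root exits the
feasible region through ``R = 0`` at ``c0_exit(h) = B/C``; between fold and
exit the system is bistable (a collapsed and a sustainable attractor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import equilibria
from .equilibria import EquilibriumRecord
from .model import es_supply, seq_of_resource
from .params import ModelParams

__all__ = [
    "fold_point",
    "fold_slope",
    "fold_locus",
    "ghost_state",
    "unstable_exit_locus",
    "branch_diagram",
    "BifurcationDiagram",
]

_BRANCHES = ("interior-high", "interior-low", "human-free")


def _CDB(params: ModelParams) -> tuple[float, float, float]:
    C = params.c1 * params.c2 * params.K_max
    D = params.c1 + params.S_max
    B = params.h * params.q * params.ES_max * params.S_max
    return C, D, B


def fold_point(params: ModelParams) -> float:
    """Resource coordinate R_m of the fold (argmax of the supply curve).

    For the default forms R_m = K_max/2 - C/(2D); when that lies outside
    (0, K_max] a numeric grid maximization is used instead.
    """
    C, D, _ = _CDB(params)
    Rm = params.K_max / 2.0 - C / (2.0 * D)
    if 0.0 < Rm <= params.K_max:
        return Rm
    # Degenerate parameters: maximize numerically.
    grid = np.linspace(params.K_max * 1e-6, params.K_max, 200_001)
    vals = (1.0 - grid / params.K_max) * (C + D * grid)
    return float(grid[np.argmax(vals)])


def fold_slope(params: ModelParams) -> float:
    """Slope of the fold locus in the (c0, h) plane: h_fold = slope * c0."""
    C, D, _ = _CDB(params)
    Rm = fold_point(params)
    return (1.0 - Rm / params.K_max) * (C + D * Rm) / (params.q * params.ES_max * params.S_max)


def fold_locus(params: ModelParams, axis: str = "h_of_c0") -> Callable[[float], float]:
    """Closed-form fold locus as a callable.

    ``axis="h_of_c0"`` returns ``h_fold(c0)`` — the largest sustainable
    harvest at productivity ``c0``; ``axis="c0_of_h"`` returns ``c0_fold(h)``
    — the tipping-point productivity at harvest ``h``.
    """
    slope = fold_slope(params)
    if axis == "h_of_c0":
        return lambda c0: slope * c0
    if axis == "c0_of_h":
        return lambda h: h / slope
    raise ValueError(f"unknown axis {axis!r}; use 'h_of_c0' or 'c0_of_h'")


def ghost_state(params: ModelParams) -> np.ndarray:
    """State (R, P, S) of the interior equilibrium at the fold.

    For productivity just below ``c0_fold(h)`` this former equilibrium acts
    as a ghost attractor around which trajectories slow down.
    """
    Rm = fold_point(params)
    S = float(seq_of_resource(Rm, params))
    P = float(params.q * es_supply(S, params))
    return np.array([Rm, P, S])


def unstable_exit_locus(params: ModelParams) -> Callable[[float], float]:
    """Productivity c0_exit(h) where the unstable interior root exits at R=0.

    ``c0_exit = h*q*ES_max*S_max / (c1*c2*K_max)`` — linear in ``h`` (50*h for
    the default parameter values).  Between ``c0_fold(h)`` and ``c0_exit(h)``
    two interior equilibria coexist (bistability); above the exit only the
    sustainable branch remains.  Returns 0 at ``h = 0`` (no unstable interior
    branch at any productivity).
    """
    C, _, _ = _CDB(params)
    scale = params.q * params.ES_max * params.S_max / C

    return lambda h: scale * h


@dataclass(frozen=True)
class BifurcationDiagram:
    """Equilibrium branches over a productivity scan at fixed harvest.

    Branch arrays are aligned with ``c0`` and contain NaN where the branch is
    infeasible (sentinel gaps, not zeros).  ``c0_over_r`` reports the scan in
    multiples of the population growth rate ``r``.
    """

    params: ModelParams
    c0: np.ndarray
    # branches[variant][branch] -> dict with keys R, P, S, stability
    branches: dict[str, dict[str, dict[str, np.ndarray]]]
    fold: tuple[float, float] | None  # (c0_fold, R_fold) if inside the scan
    exit: float | None  # c0_exit if inside the scan

    @property
    def c0_over_r(self) -> np.ndarray:
        return self.c0 / self.params.r

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variant, branches in self.branches.items():
            for branch, arrs in branches.items():
                for i, c0 in enumerate(self.c0):
                    rows.append(
                        {
                            "c0": c0,
                            "c0_over_r": c0 / self.params.r,
                            "variant": variant,
                            "branch": branch,
                            "R": arrs["R"][i],
                            "P": arrs["P"][i],
                            "S": arrs["S"][i],
                            "stability": arrs["stability"][i],
                        }
                    )
        return pd.DataFrame(rows)


def _empty_branch(n: int) -> dict[str, np.ndarray]:
    return {
        "R": np.full(n, np.nan),
        "P": np.full(n, np.nan),
        "S": np.full(n, np.nan),
        "stability": np.full(n, None, dtype=object),
    }


def _fill(branch: dict[str, np.ndarray], i: int, rec: EquilibriumRecord) -> None:
    branch["R"][i] = rec.R
    branch["P"][i] = rec.P
    branch["S"][i] = rec.S if rec.state.shape[0] == 3 else np.nan
    branch["stability"][i] = rec.stability


def branch_diagram(
    params: ModelParams,
    c0_grid: np.ndarray,
    variants: tuple[str, ...] = ("extended", "baseline"),
) -> BifurcationDiagram:
    """Trace equilibrium branches over ``c0`` at the harvest rate ``params.h``.

    The baseline model is traced alongside the extended model by default: its
    interior branch ``R* = K_max*(1 - h*q/c0)`` varies continuously with no
    fold, the contrast that makes the extended model's tipping point visible.
    """
    c0_grid = np.asarray(c0_grid, dtype=float)
    if c0_grid.ndim != 1 or np.any(np.diff(c0_grid) <= 0):
        raise ValueError("c0_grid must be a strictly increasing 1-D array")
    n = c0_grid.size
    branches = {v: {b: _empty_branch(n) for b in _BRANCHES} for v in variants}
    for i, c0 in enumerate(c0_grid):
        p = params.replace(c0=float(c0))
        for variant in variants:
            for rec in equilibria.interior_equilibria(p, variant):
                _fill(branches[variant][rec.kind], i, rec)
            for rec in equilibria.boundary_equilibria(p, variant):
                if rec.kind == "human-free":
                    _fill(branches[variant][rec.kind], i, rec)

    fold = None
    exit_c0 = None
    if params.h > 0:
        c0_fold = fold_locus(params, "c0_of_h")(params.h)
        if c0_grid[0] <= c0_fold <= c0_grid[-1]:
            fold = (c0_fold, fold_point(params))
        ce = unstable_exit_locus(params)(params.h)
        if c0_grid[0] <= ce <= c0_grid[-1]:
            exit_c0 = ce
    return BifurcationDiagram(
        params=params, c0=c0_grid, branches=branches, fold=fold, exit=exit_c0
    )
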