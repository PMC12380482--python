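"""Safe-operating-space mapping over (productivity, harvest) combinations.

Each (c0, h) cell is classified into one of three outcome regions:

* ``III`` — no sustainable outcome: no feasible stable interior equilibrium
  exists (decided analytically; basin fraction 0).
* ``II``  — conditional: a sustainable equilibrium exists and a strict subset
  of sampled initial states converges to it (basin fraction in (0, 1)).
* ``I``   — unconditional: every sampled initial state converges to the
  sustainable equilibrium (basin fraction 1).

Basin fractions are estimated by forward integration from a deterministic
grid of initial states, with richness initialized on the debt-free manifold
``S = Seq(R)`` by default (an optional third axis samples S directly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import equilibria, model
from .params import ModelParams
from .transients import (
    COLLAPSE_THRESHOLD,
    DEFAULT_HORIZON,
    IntegrateOptions,
    classify_outcome,
    integrate,
)

__all__ = ["SamplingSpec", "SOSMap", "classify_regime", "sos_map", "compare_sos", "SOSComparison"]


@dataclass(frozen=True)
class SamplingSpec:
    """Initial-state sampling and integration settings for basin estimates.

    The default grid spans R in [0.01*K_max, K_max] and P in [1, q*ES_max];
    with ``n_S = 0`` (default) richness starts on the debt-free manifold,
    otherwise S is sampled uniformly in [0, S_max].  ``seed`` only matters
    when ``latin_hypercube`` sampling is enabled; the grid itself is
    deterministic.
    """

    n_R: int = 21
    n_P: int = 21
    n_S: int = 0
    horizon: float = DEFAULT_HORIZON
    rtol: float = 1e-6
    atol: float = 1e-8
    latin_hypercube: bool = False
    n_samples: int = 441  # only for Latin-hypercube sampling
    seed: int | None = None
    converge_tol: float = 0.005  # early-stop ball radius (relative) around the target

    def initial_states(self, params: ModelParams, dim: int) -> np.ndarray:
        R_lo, R_hi = 0.01 * params.K_max, params.K_max
        P_lo, P_hi = 1.0, params.q * params.ES_max
        if self.latin_hypercube:
            from scipy.stats import qmc

            ndim = 3 if (dim == 3 and self.n_S > 0) else 2
            sampler = qmc.LatinHypercube(d=ndim, seed=self.seed)
            u = sampler.random(self.n_samples)
            R = R_lo + u[:, 0] * (R_hi - R_lo)
            P = P_lo + u[:, 1] * (P_hi - P_lo)
            if dim == 2:
                return np.column_stack([R, P])
            if ndim == 3:
                S = u[:, 2] * params.S_max
            else:
                S = np.asarray(model.seq_of_resource(R, params))
            return np.column_stack([R, P, S])
        R = np.linspace(R_lo, R_hi, self.n_R)
        P = np.linspace(P_lo, P_hi, self.n_P)
        if dim == 2:
            RR, PP = np.meshgrid(R, P, indexing="ij")
            return np.column_stack([RR.ravel(), PP.ravel()])
        if self.n_S > 0:
            S = np.linspace(0.0, params.S_max, self.n_S)
            RR, PP, SS = np.meshgrid(R, P, S, indexing="ij")
            return np.column_stack([RR.ravel(), PP.ravel(), SS.ravel()])
        RR, PP = np.meshgrid(R, P, indexing="ij")
        states = np.column_stack([RR.ravel(), PP.ravel()])
        S = np.asarray(model.seq_of_resource(states[:, 0], params))
        return np.column_stack([states, S])

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_R": self.n_R,
            "n_P": self.n_P,
            "n_S": self.n_S,
            "horizon": self.horizon,
            "rtol": self.rtol,
            "atol": self.atol,
            "latin_hypercube": self.latin_hypercube,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "converge_tol": self.converge_tol,
        }


def _basin_fraction(
    variant: str,
    params: ModelParams,
    stable: list[equilibria.EquilibriumRecord],
    sampling: SamplingSpec,
) -> tuple[float, float]:
    """Fraction of sampled initial states converging to a stable equilibrium."""
    dim = model.state_dim(variant)
    states0 = sampling.initial_states(params, dim)
    opts = IntegrateOptions(
        rtol=sampling.rtol, atol=sampling.atol, max_step=None, dt=None
    )
    targets = [rec.state for rec in stable]
    refs = [np.linalg.norm(t) for t in targets]

    def near_target(t, y):
        return min(
            float(np.linalg.norm(y - tgt) / ref) for tgt, ref in zip(targets, refs)
        ) - sampling.converge_tol

    near_target.terminal = True
    near_target.direction = -1.0

    n_sust = n_undecided = 0
    for y0 in states0:
        traj = integrate(
            variant, y0, params, (0.0, sampling.horizon), opts, extra_events=[near_target]
        )
        if traj.termination == "event":
            outcome = "sustainable"
            traj.outcome = outcome
        else:
            outcome = classify_outcome(traj, params, stable)
        if outcome == "sustainable":
            n_sust += 1
        elif outcome == "undecided":
            n_undecided += 1
    n = states0.shape[0]
    return n_sust / n, n_undecided / n


def classify_regime(
    c0: float,
    h: float,
    params: ModelParams,
    sampling: SamplingSpec | None = None,
    variant: str = "extended",
) -> tuple[str, float, float]:
    """Region label, basin fraction and undecided fraction for one (c0, h).

    Existence/stability of the sustainable equilibrium is decided
    analytically; the basin fraction by forward integration from the sampled
    initial states.  A warning is emitted if more than 5% of trajectories are
    undecided at the horizon.
    """
    sampling = sampling or SamplingSpec()
    p = params.replace(c0=float(c0), h=float(h))
    stable = [r for r in equilibria.interior_equilibria(p, variant) if r.stability == "stable"]
    if not stable:
        return "III", 0.0, 0.0
    frac, undecided = _basin_fraction(variant, p, stable, sampling)
    if undecided > 0.05:
        warnings.warn(
            f"{undecided:.1%} of trajectories undecided at (c0={c0}, h={h}); "
            "consider a longer horizon",
            stacklevel=2,
        )
    label = "I" if frac == 1.0 else "II"
    return label, frac, undecided


@dataclass(frozen=True)
class SOSMap:
    """Gridded region classification over (c0, h) for one model variant."""

    variant: str
    c0: np.ndarray
    h: np.ndarray
    labels: np.ndarray  # object array, shape (len(c0), len(h))
    basin_fraction: np.ndarray
    undecided_fraction: np.ndarray
    params: ModelParams
    sampling: SamplingSpec

    def sustainable_mask(self) -> np.ndarray:
        """Cells with any sustainable outcome (regions I and II)."""
        return self.labels != "III"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c0 in enumerate(self.c0):
            for j, h in enumerate(self.h):
                rows.append(
                    {
                        "c0": c0,
                        "h": h,
                        "label": self.labels[i, j],
                        "basin_fraction": self.basin_fraction[i, j],
                        "undecided_fraction": self.undecided_fraction[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _default_grids(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    # The degenerate c0 = 0 and h = 0 boundary lines are excluded: with no
    # production every cell collapses, and with no harvest the classification
    # is trivially unconditional in every variant.
    c0 = np.linspace(0.044 / 45.0, 0.044, 45)
    h = np.arange(1, 34) * 0.0004
    return c0, h


def sos_map(
    variant: str,
    params: ModelParams,
    c0_grid: np.ndarray | None = None,
    h_grid: np.ndarray | None = None,
    sampling: SamplingSpec | None = None,
) -> SOSMap:
    """Classify every (c0, h) grid cell for one model variant.

    Deterministic given the sampling spec (and its seed when Latin-hypercube
    sampling is enabled).
    """
    sampling = sampling or SamplingSpec()
    d_c0, d_h = _default_grids(params)
    c0_grid = np.asarray(c0_grid, dtype=float) if c0_grid is not None else d_c0
    h_grid = np.asarray(h_grid, dtype=float) if h_grid is not None else d_h
    labels = np.empty((c0_grid.size, h_grid.size), dtype=object)
    frac = np.zeros_like(labels, dtype=float)
    und = np.zeros_like(frac)
    for i, c0 in enumerate(c0_grid):
        for j, h in enumerate(h_grid):
            labels[i, j], frac[i, j], und[i, j] = classify_regime(
                c0, h, params, sampling, variant
            )
    return SOSMap(
        variant=variant,
        c0=c0_grid,
        h=h_grid,
        labels=labels,
        basin_fraction=frac,
        undecided_fraction=und,
        params=params,
        sampling=sampling,
    )


@dataclass(frozen=True)
class SOSComparison:
    """Cell-wise comparison of two safe-operating-space maps."""

    reduction_mask: np.ndarray  # sustainable in A but not in B
    basin_shrunk_mask: np.ndarray  # basin fraction strictly smaller in B
    fraction_lost: float
    fraction_basin_shrunk: float


def compare_sos(map_a: SOSMap, map_b: SOSMap) -> SOSComparison:
    """Quantify the safe-operating-space reduction from map A to map B.

    Typically A is the baseline and B the extended model; the reduction mask
    marks cells sustainable in A but not in B, mirroring the grey regions of
    a baseline-vs-extended comparison map.
    """
    if map_a.c0.shape != map_b.c0.shape or map_a.h.shape != map_b.h.shape:
        raise ValueError("maps must share identical grids")
    if not (np.allclose(map_a.c0, map_b.c0) and np.allclose(map_a.h, map_b.h)):
        raise ValueError("maps must share identical grids")
    sus_a, sus_b = map_a.sustainable_mask(), map_b.sustainable_mask()
    reduction = sus_a & ~sus_b
    shrunk = map_b.basin_fraction < map_a.basin_fraction
    return SOSComparison(
        reduction_mask=reduction,
        basin_shrunk_mask=shrunk,
        fraction_lost=float(reduction.mean()),
        fraction_basin_shrunk=float(shrunk.mean()),
    )
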