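"""Equilibrium enumeration, Jacobians, and stability classification.

For the default saturating forms the interior equilibria have a closed form:
eliminating ``S* = Seq(R*)`` and ``P* = q * ES(S*)`` from the steady-state
conditions leaves a single condition on the resource stock,

    c0 * (1 - R/K_max) * (C + D*R) = B,

with ``C = c1*c2*K_max``, ``D = c1 + S_max`` and ``B = h*q*ES_max*S_max`` —
a quadratic in ``R`` solved exactly.  Non-default forms fall back to
grid-seeded bracketed root-finding on the equivalent one-variable condition.

A brute-force sign-change scan (:func:`interior_root_scan`) is provided as an
independent oracle for the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import model
from .model import SERVICE_FLOOR, es_supply, es_supply_prime, seq_of_resource, seq_prime
from .params import ModelParams

__all__ = [
    "STABILITY_TOL",
    "EquilibriumRecord",
    "jacobian",
    "interior_equilibria",
    "boundary_equilibria",
    "classify_stability",
    "interior_root_scan",
    "stable_equilibria",
    "equilibrium_table",
    "quadratic_coefficients",
]

#: Eigenvalue real parts within this tolerance of zero (year^-1) are treated
#: as marginal; below typical eigen-solver noise at these parameter scales.
STABILITY_TOL = 1e-9

#: Residual bound (state units per year) for a state to count as an
#: equilibrium.
RESIDUAL_TOL = 1e-8

#: Interior roots closer than this fraction of K_max are merged into a double
#: root (the fold point).
_ROOT_MERGE_REL = 1e-9


@dataclass(frozen=True)
class EquilibriumRecord:
    """An equilibrium point with its linear-stability diagnostics."""

    variant: str
    kind: str  # origin | human-free | interior-low | interior-high
    state: np.ndarray
    eigenvalues: np.ndarray | None = None
    stability: str | None = None  # stable | unstable | marginal
    feasible: bool = True
    residual: float = field(default=float("nan"))

    @property
    def R(self) -> float:
        return float(self.state[0])

    @property
    def P(self) -> float:
        return float(self.state[1])

    @property
    def S(self) -> float:
        if self.state.shape[0] < 3:
            raise AttributeError(f"variant {self.variant!r} has no S state")
        return float(self.state[2])


def quadratic_coefficients(params: ModelParams) -> tuple[float, float, float]:
    """Coefficients (a2, a1, a0) of the interior equilibrium condition.

    ``a2*R**2 + a1*R + a0 = 0`` is the standard form of
    ``c0*(1 - R/K_max)*(C + D*R) - B = 0`` for the default saturating forms.
    """
    C = params.c1 * params.c2 * params.K_max
    D = params.c1 + params.S_max
    B = params.h * params.q * params.ES_max * params.S_max
    a2 = -params.c0 * D / params.K_max
    a1 = params.c0 * (D - C / params.K_max)
    a0 = params.c0 * C - B
    return a2, a1, a0


def _residual(state: np.ndarray, params: ModelParams, variant: str) -> float:
    return float(np.max(np.abs(model.rhs(variant)(state, params))))


def jacobian(state, params: ModelParams, variant: str = "extended") -> np.ndarray:
    """Analytic Jacobian of the selected variant at ``state``.

    The extended model's coupling structure leaves three exactly-zero
    entries: d(dR)/dS, d(dP)/dR and d(dS)/dP (harvest does not see
    biodiversity, population growth sees the resource only through services,
    and richness does not see people).

    Raises
    ------
    ValueError
        If the service-based carrying capacity is at the regularization
        floor, where the analytic form is invalid.
    """
    y = np.asarray(state, dtype=float)
    c0, K, h, r, q, d = params.c0, params.K_max, params.h, params.r, params.q, params.d
    if variant == "extended":
        R, P, S = y
        E = es_supply(S, params)
        cap = q * E
        if cap <= SERVICE_FLOOR:
            raise ValueError("state at the service regularization floor; analytic Jacobian invalid")
        J = np.zeros((3, 3))
        J[0, 0] = c0 * (1.0 - 2.0 * R / K)
        J[0, 1] = -h
        J[1, 1] = r * (1.0 - 2.0 * P / cap)
        J[1, 2] = r * P**2 * es_supply_prime(S, params) / (q * E**2)
        J[2, 0] = d * seq_prime(R, params)
        J[2, 2] = -d
        return J
    if variant == "baseline":
        R, P = y
        cap = q * R
        if cap <= SERVICE_FLOOR:
            raise ValueError("state at the regularization floor; analytic Jacobian invalid")
        return np.array(
            [
                [c0 * (1.0 - 2.0 * R / K), -h],
                [r * P**2 / (q * R**2), r * (1.0 - 2.0 * P / cap)],
            ]
        )
    if variant == "quasistatic":
        R, P = y
        Seq = seq_of_resource(R, params)
        E = es_supply(Seq, params)
        cap = q * E
        if cap <= SERVICE_FLOOR:
            raise ValueError("state at the regularization floor; analytic Jacobian invalid")
        dcap_dR = q * es_supply_prime(Seq, params) * seq_prime(R, params)
        return np.array(
            [
                [c0 * (1.0 - 2.0 * R / K), -h],
                [r * P**2 * dcap_dR / cap**2, r * (1.0 - 2.0 * P / cap)],
            ]
        )
    raise ValueError(f"unknown model variant {variant!r}")


def _classify(eigenvalues: np.ndarray) -> str:
    re = eigenvalues.real
    if np.all(re < -STABILITY_TOL):
        return "stable"
    if np.any(re > STABILITY_TOL):
        return "unstable"
    return "marginal"


def classify_stability(
    record: EquilibriumRecord, params: ModelParams, *, _floor_ok: bool = False
) -> EquilibriumRecord:
    """Complete a record with eigenvalues and a stability label.

    ``stable`` iff all eigenvalue real parts are below ``-STABILITY_TOL``,
    ``unstable`` iff any exceeds ``+STABILITY_TOL``, else ``marginal``.

    Raises
    ------
    ValueError
        If the state is not an equilibrium (residual >= 1e-8).
    """
    res = _residual(record.state, params, record.variant)
    if res >= RESIDUAL_TOL:
        raise ValueError(f"not an equilibrium: residual {res:.3e} >= {RESIDUAL_TOL:.0e}")
    try:
        J = jacobian(record.state, params, record.variant)
    except ValueError:
        if not _floor_ok:
            raise
        J = _jacobian_at_floor(record.state, params, record.variant)
    eig = np.linalg.eigvals(J)
    order = np.argsort(eig.real)[::-1]
    eig = eig[order]
    feasible = bool(np.all(record.state >= 0) and record.state[0] <= params.K_max)
    return replace(
        record,
        eigenvalues=eig,
        stability=_classify(eig),
        feasible=feasible,
        residual=res,
    )


def _jacobian_at_floor(state, params: ModelParams, variant: str) -> np.ndarray:
    """Jacobian of the regularized dynamics where the capacity floor binds.

    On the floor the logistic divisor is the constant ``SERVICE_FLOOR``, so
    the population row decouples from services.  Used only for boundary
    equilibria (the origin), where the analytic interior form is invalid.
    """
    y = np.asarray(state, dtype=float)
    c0, K, h, r, d = params.c0, params.K_max, params.h, params.r, params.d
    if variant == "extended":
        R, P, S = y
        J = np.zeros((3, 3))
        J[0, 0] = c0 * (1.0 - 2.0 * R / K)
        J[0, 1] = -h
        J[1, 1] = r * (1.0 - 2.0 * P / SERVICE_FLOOR)
        J[2, 0] = d * seq_prime(R, params)
        J[2, 2] = -d
        return J
    R, P = y
    return np.array(
        [
            [c0 * (1.0 - 2.0 * R / K), -h],
            [0.0, r * (1.0 - 2.0 * P / SERVICE_FLOOR)],
        ]
    )


def _complete_interior(R: float, params: ModelParams, variant: str, kind: str) -> EquilibriumRecord:
    S = float(seq_of_resource(R, params))
    P = float(params.q * es_supply(S, params))
    if variant == "extended":
        state = np.array([R, P, S])
    else:
        state = np.array([R, P])
    rec = EquilibriumRecord(variant=variant, kind=kind, state=state)
    return classify_stability(rec, params)


def _interior_roots_default(params: ModelParams) -> list[float]:
    """Real roots in (0, K_max] of the eliminated equilibrium condition."""
    K = params.K_max
    if params.c0 == 0.0:
        return []  # no production: no interior balance (h=0 too is degenerate)
    if params.h == 0.0:
        return [K]
    a2, a1, a0 = quadratic_coefficients(params)
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    roots = sorted(((-a1 - sq) / (2.0 * a2), (-a1 + sq) / (2.0 * a2)))
    if roots[1] - roots[0] < _ROOT_MERGE_REL * K:  # fold: double root
        roots = [0.5 * (roots[0] + roots[1])]
    return [R for R in roots if 0.0 < R <= K]


def _interior_roots_numeric(params: ModelParams, n_brackets: int = 1000) -> list[float]:
    """Bracketed root-finding fallback for non-default functional forms."""
    K = params.K_max

    def g(R: float) -> float:
        demand = params.h * params.q * es_supply(seq_of_resource(R, params), params)
        return params.c0 * R * (1.0 - R / K) - demand

    grid = np.linspace(1e-9 * K, K, n_brackets + 1)
    vals = np.array([g(R) for R in grid])
    roots: list[float] = []
    for i in range(n_brackets):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0:
            roots.append(float(brentq(g, grid[i], grid[i + 1], xtol=1e-12 * K)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    merged: list[float] = []
    for R in sorted(roots):
        if not merged or R - merged[-1] > _ROOT_MERGE_REL * K:
            merged.append(R)
    return [R for R in merged if R > 1e-6 * K]


def interior_equilibria(params: ModelParams, variant: str = "extended") -> list[EquilibriumRecord]:
    """All interior (all-components-present) equilibria of a variant.

    Returns 0, 1 or 2 records, sorted by increasing resource stock and
    labelled ``interior-low`` / ``interior-high`` (a single root is the high
    branch).  Each record carries eigenvalues, stability and residual.
    """
    if variant == "baseline":
        if params.c0 <= 0.0 or params.h * params.q >= params.c0:
            return []
        R = params.K_max * (1.0 - params.h * params.q / params.c0)
        P = params.q * R
        rec = EquilibriumRecord(
            variant=variant, kind="interior-high", state=np.array([R, P])
        )
        return [classify_stability(rec, params)]

    if variant not in ("extended", "quasistatic"):
        raise ValueError(f"unknown model variant {variant!r}")

    default_forms = params.es_form == "saturating" and params.sar_form == "saturating"
    roots = _interior_roots_default(params) if default_forms else _interior_roots_numeric(params)
    kinds = ["interior-high"] if len(roots) == 1 else ["interior-low", "interior-high"]
    return [_complete_interior(R, params, variant, kind) for R, kind in zip(roots, kinds)]


def boundary_equilibria(params: ModelParams, variant: str = "extended") -> list[EquilibriumRecord]:
    """The origin and the human-free equilibrium of a variant.

    The human-free point carries the full habitat (``R = K_max``) and, in the
    extended model, the species-area richness ``S_max/(1+c2)``.  It is
    unstable whenever services there are positive and ``r > 0`` (a human
    population can invade).
    """
    dim = model.state_dim(variant)
    origin = np.zeros(dim)
    if variant == "extended":
        humanfree = np.array(
            [params.K_max, 0.0, float(seq_of_resource(params.K_max, params))]
        )
    else:
        humanfree = np.array([params.K_max, 0.0])
    records = [
        EquilibriumRecord(variant=variant, kind="origin", state=origin),
        EquilibriumRecord(variant=variant, kind="human-free", state=humanfree),
    ]
    return [classify_stability(rec, params, _floor_ok=True) for rec in records]


def stable_equilibria(params: ModelParams, variant: str = "extended") -> list[EquilibriumRecord]:
    """Feasible stable equilibria (interior and boundary) of a variant."""
    records = interior_equilibria(params, variant) + boundary_equilibria(params, variant)
    return [r for r in records if r.stability == "stable" and r.feasible]


def interior_root_scan(params: ModelParams, n: int = 100_000) -> list[float]:
    """Brute-force oracle: interior roots located by dense sign-change scan.

    Evaluates the eliminated equilibrium condition on an ``n``-point grid
    over (0, K_max] and bisects every sign change.  Independent of the
    quadratic formula used by :func:`interior_equilibria`.
    """
    K = params.K_max
    C = params.c1 * params.c2 * params.K_max
    D = params.c1 + params.S_max
    B = params.h * params.q * params.ES_max * params.S_max

    def f(R):
        return params.c0 * (1.0 - R / K) * (C + D * R) - B

    grid = np.linspace(K / n, K, n)
    vals = f(grid)
    roots: list[float] = []
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-13 * K)))
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def equilibrium_table(records: list[EquilibriumRecord]) -> pd.DataFrame:
    """Tidy table of equilibrium records (one row per equilibrium)."""
    rows = []
    for rec in records:
        row: dict = {"kind": rec.kind, "R": rec.R, "P": rec.P}
        row["S"] = rec.S if rec.state.shape[0] == 3 else np.nan
        eig = rec.eigenvalues if rec.eigenvalues is not None else np.array([])
        for i in range(3):
            row[f"re_lambda_{i + 1}"] = eig[i].real if i < eig.size else np.nan
            row[f"im_lambda_{i + 1}"] = eig[i].imag if i < eig.size else np.nan
        row["stability"] = rec.stability
        row["feasible"] = rec.feasible
        row["residual"] = rec.residual
        rows.append(row)
    columns = (
        ["kind", "R", "P", "S"]
        + [f"re_lambda_{i}" for i in (1, 2, 3)]
        + [f"im_lambda_{i}" for i in (1, 2, 3)]
        + ["stability", "feasible", "residual"]
    )
    return pd.DataFrame(rows, columns=columns)
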