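"""Numerical integration, transient diagnostics and perturbation experiments.

Integration uses adaptive Dormand-Prince RK45 (`scipy.integrate.solve_ivp`).
Collapse — the resource or the population falling below an absolute floor —
terminates a run by default, which also keeps trajectories inside the
non-negative orthant (the harvest term would otherwise push ``R`` below zero
once the resource is exhausted).

The module provides the diagnostics used to study the model's long
transients: outcome classification, per-interval speed profiles, time spent
near the ghost attractor left behind by the fold, extinction-debt metrics and
the habitat-removal perturbation experiment with its no-debt (quasi-static)
counterfactual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import bifurcation, equilibria, model
from .params import ModelParams

__all__ = [
    "COLLAPSE_THRESHOLD",
    "DEFAULT_HORIZON",
    "IntegrateOptions",
    "Trajectory",
    "DebtMetrics",
    "PerturbationRecord",
    "integrate",
    "classify_outcome",
    "speed_profile",
    "ghost_transit_time",
    "perturbation_experiment",
    "find_reversal_case",
    "REVERSAL_FIXTURE",
    "debt_metrics",
    "relaxation_time",
]

#: Absolute floor (state units km^-2) below which the resource or the
#: population counts as collapsed.
COLLAPSE_THRESHOLD = 1e-3

#: Default outcome horizon (years); roughly 88 population-growth time
#: constants at the default r.
DEFAULT_HORIZON = 20_000.0


@dataclass(frozen=True)
class IntegrateOptions:
    """Solver settings.

    ``dt`` is the uniform reporting grid spacing (years); ``None`` reports
    the solver's natural accepted steps instead.  ``max_step`` defaults to
    1 year so that fast collapse phases are always resolved on the reporting
    grid; long-horizon diagnostics relax it and rely on the adaptive error
    control alone.
    """

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float | None = 1.0
    dt: float | None = 1.0
    stop_on_collapse: bool = True

    def solver_record(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "rtol": self.rtol,
            "atol": self.atol,
            "max_step": self.max_step,
            "dt": self.dt,
        }


@dataclass
class Trajectory:
    """A time-indexed solution of one model variant.

    ``times``/``states`` are the reported samples; ``t_end``/``y_end`` are
    the exact final solver state (they coincide with the last sample unless a
    terminal event cut the run between reporting points).  ``outcome`` is
    filled by :func:`classify_outcome`, ``speed`` by :func:`speed_profile`.
    """

    variant: str
    params: ModelParams
    times: np.ndarray
    states: np.ndarray
    solver: dict[str, Any]
    t_end: float
    y_end: np.ndarray
    termination: str  # "horizon" | "collapse" | "event"
    outcome: str | None = None  # sustainable | collapse | undecided
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory states must be finite")

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def S(self) -> np.ndarray:
        if self.states.shape[1] < 3:
            raise AttributeError(f"variant {self.variant!r} has no S state")
        return self.states[:, 2]


def _collapse_events(dim: int) -> list[Callable]:
    def resource_floor(t, y):
        return y[0] - COLLAPSE_THRESHOLD

    def population_floor(t, y):
        return y[1] - COLLAPSE_THRESHOLD

    for ev in (resource_floor, population_floor):
        ev.terminal = True
        ev.direction = -1.0
    return [resource_floor, population_floor]


def integrate(
    variant: str,
    state0: Sequence[float],
    params: ModelParams,
    t_span: tuple[float, float],
    opts: IntegrateOptions | None = None,
    extra_events: Iterable[Callable] | None = None,
) -> Trajectory:
    """Integrate a model variant and report on a uniform time grid.

    Raises on solver failure and on negative undershoot beyond ten times the
    absolute tolerance (the orthant should be invariant to solver accuracy).
    """
    opts = opts or IntegrateOptions()
    dim = model.state_dim(variant)
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (dim,):
        raise ValueError(f"state0 must have shape ({dim},) for variant {variant!r}")
    if np.any(y0 < 0):
        raise ValueError("state0 must be non-negative")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1)) or t1 <= t0:
        raise ValueError("t_span must be finite with t_span[1] > t_span[0]")

    rhs = model.rhs(variant)
    fun = lambda t, y: rhs(y, params)  # noqa: E731 - autonomous system
    events = list(extra_events or [])
    n_extra = len(events)
    if opts.stop_on_collapse:
        events = events + _collapse_events(dim)
    t_eval = None
    if opts.dt is not None:
        t_eval = np.arange(t0, t1 + 0.5 * opts.dt, opts.dt)
        t_eval[-1] = min(t_eval[-1], t1)
    sol = solve_ivp(
        fun,
        (t0, t1),
        y0,
        method=opts.method,
        rtol=opts.rtol,
        atol=opts.atol,
        max_step=opts.max_step if opts.max_step is not None else np.inf,
        t_eval=t_eval,
        events=events or None,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"solver failure for variant {variant!r}: {sol.message}")

    times, states = sol.t, sol.y.T
    if times.size < 2:
        # Terminal event before the second reporting point: keep the exact
        # endpoint so every trajectory has at least two samples.
        t_end = sol.t[-1] if sol.t.size else t0
        times = np.array([t0, max(t_end, t0 + 1e-9)])
        states = np.vstack([y0, sol.y.T[-1] if sol.y.size else y0])

    undershoot = float(states.min(initial=0.0))
    if undershoot < -10.0 * opts.atol:
        raise RuntimeError(
            f"negative undershoot {undershoot:.3e} beyond solver tolerance; "
            "reduce step size or tolerances"
        )

    termination = "horizon"
    t_end, y_end = float(sol.t[-1]), sol.y.T[-1].copy()
    if sol.status == 1:  # a terminal event fired
        for k, (te, ye) in enumerate(zip(sol.t_events, sol.y_events)):
            if te.size:
                t_end, y_end = float(te[-1]), np.asarray(ye[-1], dtype=float)
                termination = "event" if k < n_extra else "collapse"
        # The event time is appended to the reported samples; drop it when it
        # breaks a uniform reporting grid (t_end/y_end keep the exact stop).
        if (
            opts.dt is not None
            and times.size > 2
            and not np.isclose(times[-1] - times[-2], opts.dt)
        ):
            times, states = times[:-1], states[:-1]
    return Trajectory(
        variant=variant,
        params=params,
        times=times,
        states=states,
        solver=opts.solver_record(),
        t_end=t_end,
        y_end=y_end,
        termination=termination,
    )


def classify_outcome(
    traj: Trajectory,
    params: ModelParams | None = None,
    stable: list[equilibria.EquilibriumRecord] | None = None,
) -> str:
    """Label a finished trajectory sustainable, collapse or undecided.

    ``sustainable``: the final state lies within 1% relative distance of a
    feasible stable equilibrium.  ``collapse``: the resource or population is
    at/below the collapse floor.  Otherwise ``undecided`` — a run that merely
    looks stable (e.g. near a ghost) is not promoted to sustainable.
    """
    params = params or traj.params
    if stable is None:
        stable = equilibria.stable_equilibria(params, traj.variant)
    y = traj.y_end
    for rec in stable:
        ref = np.linalg.norm(rec.state)
        if ref > 0 and np.linalg.norm(y - rec.state) / ref <= 0.01:
            traj.outcome = "sustainable"
            return traj.outcome
    if traj.termination == "collapse" or min(y[0], y[1]) <= COLLAPSE_THRESHOLD * (1 + 1e-9):
        traj.outcome = "collapse"
        return traj.outcome
    traj.outcome = "undecided"
    return traj.outcome


def speed_profile(traj: Trajectory) -> np.ndarray:
    """Per-interval speed log(1 + (|dR| + |dP| [+ |dS|]) / dt).

    Requires a uniform reporting grid; absolute per-year changes of all state
    variables are summed (the logarithm compresses the fast collapse phase so
    slow ghost passages remain visible on the same scale).
    """
    if traj.times.size < 2:
        raise ValueError("speed profile needs at least two samples")
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("speed profile requires a uniform reporting grid; resample first")
    change = np.abs(np.diff(traj.states, axis=0)).sum(axis=1)
    traj.speed = np.log1p(change / dt)
    return traj.speed


def debt_metrics(state: Sequence[float], params: ModelParams) -> "DebtMetrics":
    """Extinction debt and service debt of a state (positive = debt).

    Both vanish on the species-area manifold ``S = Seq(R)``; negative values
    are immigration / service credits after habitat recovery.
    """
    y = np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("state must be non-negative")
    R, S = float(y[0]), float(y[-1] if y.size == 3 else model.seq_of_resource(y[0], params))
    seq = float(model.seq_of_resource(R, params))
    return DebtMetrics(
        extinction_debt=S - seq,
        service_debt=float(model.es_supply(S, params) - model.es_supply(seq, params)),
    )


@dataclass(frozen=True)
class DebtMetrics:
    """Extinction debt (species) and ecosystem-service debt (service units km^-2)."""

    extinction_debt: float
    service_debt: float


def relaxation_time(params: ModelParams, f: float) -> float:
    """Years to pay off a fraction ``f`` of a debt at fixed habitat.

    Biodiversity relaxes exponentially at rate ``d``, so the time is
    ``-ln(1-f)/d`` — 50 years for half of a debt at the default
    ``d = ln(2)/50``, and about 332 years for 99% of it.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"fraction f must lie in (0, 1), got {f!r}")
    if params.d <= 0:
        raise ValueError("relaxation requires d > 0")
    return -math.log1p(-f) / params.d


# -- ghost-attractor diagnostics --------------------------------------------


def ghost_transit_time(
    params: ModelParams,
    start: Sequence[float] | None = None,
    threshold: float = 0.10,
    t_max: float = 1e8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Time spent within a relative-distance ball around the ghost attractor.

    Valid only strictly below the fold (``c0 < c0_fold(h)``), where no
    sustainable equilibrium exists but the fold-point state lingers as a
    ghost.  ``start`` defaults to the ghost state itself.  Returns 0 if the
    trajectory never enters the ball.
    """
    if params.h <= 0:
        raise ValueError("ghost diagnostics need h > 0 (no fold at h = 0)")
    c0_fold = bifurcation.fold_locus(params, "c0_of_h")(params.h)
    if params.c0 >= c0_fold:
        raise ValueError(
            f"parameters not below the fold: c0 = {params.c0} >= c0_fold = {c0_fold}"
        )
    ghost = bifurcation.ghost_state(params)
    ref = float(np.linalg.norm(ghost))
    y0 = np.asarray(start, dtype=float) if start is not None else ghost.copy()

    def ball(t, y):
        return float(np.linalg.norm(y - ghost) / ref - threshold)

    ball.terminal = False
    traj = integrate(
        "extended",
        y0,
        params,
        (0.0, t_max),
        IntegrateOptions(rtol=rtol, atol=atol, max_step=None, dt=None),
        extra_events=[ball],
    )
    # Reconstruct inside-ball intervals from the crossing times.
    crossings = []
    # integrate() does not expose non-terminal event times, so recompute the
    # sign pattern on the reported (natural-step) grid and refine: cheap and
    # robust because the natural steps bracket every crossing the solver saw.
    dist = np.linalg.norm(traj.states - ghost, axis=1) / ref
    inside = dist < threshold
    if not inside.any():
        return 0.0
    t = traj.times
    total = 0.0
    entry: float | None = t[0] if inside[0] else None
    for i in range(1, t.size):
        if inside[i] and entry is None:
            # linear interpolation of the crossing between samples
            f = (threshold - dist[i - 1]) / (dist[i] - dist[i - 1])
            entry = t[i - 1] + f * (t[i] - t[i - 1])
        elif not inside[i] and entry is not None:
            f = (threshold - dist[i - 1]) / (dist[i] - dist[i - 1])
            total += t[i - 1] + f * (t[i] - t[i - 1]) - entry
            entry = None
    if entry is not None:
        total += t[-1] - entry
    return float(total)


# -- perturbation experiment -------------------------------------------------


@dataclass
class PerturbationRecord:
    """Result of a habitat-removal perturbation experiment.

    A fraction ``phi`` of the resource stock is removed instantaneously at
    ``t_pert``; population and richness are continuous across the jump (the
    habitat loss precedes the extinctions — that is what creates the debt).
    The unperturbed counterfactual and the quasi-static (no-debt) variant are
    run under the identical protocol.
    """

    params: ModelParams
    t_pert: float
    phi: float
    pre: Trajectory
    post: Trajectory
    counterfactual_post: Trajectory
    quasistatic_post: Trajectory
    outcome: str
    counterfactual_outcome: str
    quasistatic_outcome: str
    initial_recovery: tuple[float, float] | None
    collapse_onset: float | None


def _two_leg(
    variant: str,
    state0: np.ndarray,
    params: ModelParams,
    t_pert: float,
    horizon: float,
    opts: IntegrateOptions,
    phi: float,
) -> tuple[Trajectory, Trajectory]:
    pre = integrate(variant, state0, params, (0.0, t_pert), opts)
    y_mid = pre.y_end.copy()
    y_mid[0] *= 1.0 - phi
    post = integrate(variant, y_mid, params, (t_pert, horizon), opts)
    return pre, post


def perturbation_experiment(
    params: ModelParams,
    state0: Sequence[float],
    t_pert: float,
    phi: float,
    horizon: float = DEFAULT_HORIZON,
    opts: IntegrateOptions | None = None,
) -> PerturbationRecord:
    """Remove a fraction ``phi`` of the resource at ``t_pert`` and follow up.

    Requires the unperturbed extended trajectory to be sustainable (the
    experiment asks whether a perturbation can knock a sustainable system
    off course).  The counterfactual is integrated with the same two-leg
    protocol so a null perturbation reproduces it exactly.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    opts = opts or IntegrateOptions()
    y0 = np.asarray(state0, dtype=float)

    cf_pre, cf_post = _two_leg("extended", y0, params, t_pert, horizon, opts, 0.0)
    cf_outcome = classify_outcome(cf_post, params)
    if cf_outcome != "sustainable":
        raise ValueError(
            f"unperturbed trajectory is {cf_outcome!r}, not sustainable; "
            "the perturbation experiment is undefined here"
        )

    pre, post = _two_leg("extended", y0, params, t_pert, horizon, opts, phi)
    outcome = classify_outcome(post, params)

    qs0 = y0[:2]
    _, qs_post = _two_leg("quasistatic", qs0, params, t_pert, horizon, opts, phi)
    qs_outcome = classify_outcome(qs_post, params)

    # Initial recovery: does R rise after the jump, and until when?
    R = post.R
    recovery: tuple[float, float] | None = None
    if R.size >= 3 and R[1] > R[0]:
        peak = 1
        while peak + 1 < R.size and R[peak + 1] >= R[peak]:
            peak += 1
        recovery = (float(post.times[0]), float(post.times[peak]))

    onset: float | None = None
    if outcome == "collapse":
        if recovery is not None:
            # First time the resource falls back below where the jump left
            # it, after the recovery peak: the point where the apparent
            # recovery gives way to decline.
            peak_idx = int(np.searchsorted(post.times, recovery[1]))
            below = np.nonzero(R[peak_idx:] < R[0])[0]
            if below.size:
                onset = float(post.times[peak_idx + below[0]])
        else:
            ref = pre.y_end[0]  # resource level just before the perturbation
            below = np.nonzero(R < 0.5 * ref)[0]
            below = below[below >= 1]  # ignore the jump itself
            if below.size:
                onset = float(post.times[below[0]])

    return PerturbationRecord(
        params=params,
        t_pert=float(t_pert),
        phi=float(phi),
        pre=pre,
        post=post,
        counterfactual_post=cf_post,
        quasistatic_post=qs_post,
        outcome=outcome,
        counterfactual_outcome=cf_outcome,
        quasistatic_outcome=qs_outcome,
        initial_recovery=recovery,
        collapse_onset=onset,
    )


def find_reversal_case(
    params: ModelParams | None = None,
    c0_values: Sequence[float] | None = None,
    h_fractions: Sequence[float] = (0.7, 0.9, 0.95),
    phi_values: Sequence[float] | None = None,
    t_pert_values: Sequence[float] = (200.0, 400.0, 800.0),
    horizon: float = DEFAULT_HORIZON,
    opts: IntegrateOptions | None = None,
) -> dict[str, float] | None:
    """Grid-search a debt-driven perturbation reversal.

    Scans the bistable wedge (``c0`` between ``r`` and ``10 r``; ``h`` a
    fraction of the way from the exit locus toward the fold; ``phi`` in
    [0.3, 0.9]) for a combination where the extended model shows initial
    resource recovery followed by collapse while the no-debt variant returns
    to equilibrium under the identical perturbation.  The system starts as a
    debt-free colonization front (high habitat, small population) and is
    perturbed while the population is still growing — near the fold this is
    where the debt's delayed feedback bites.  Returns the first qualifying
    ``{c0, h, phi, t_pert, R0, P0, S0}`` or ``None``.
    """
    base = params or ModelParams()
    if c0_values is None:
        c0_values = [5.0 * base.r, 10.0 * base.r]
    if phi_values is None:
        phi_values = [round(0.3 + 0.05 * k, 2) for k in range(13)]
    # Natural-step reporting and adaptive step sizes keep the search cheap;
    # a candidate is re-run at reference tolerances by the caller if needed.
    opts = opts or IntegrateOptions(rtol=1e-8, atol=1e-10, max_step=None, dt=None)
    for c0 in c0_values:
        slope = bifurcation.fold_slope(base.replace(c0=c0))
        h_lo, h_hi = c0 / 50.0, slope * c0  # exit and fold loci
        for frac in h_fractions:
            h = h_lo + frac * (h_hi - h_lo)
            p = base.replace(c0=float(c0), h=float(h))
            if not any(r.stability == "stable" for r in equilibria.interior_equilibria(p)):
                continue
            R0 = 0.95 * p.K_max
            state0 = np.array([R0, 50.0, float(model.seq_of_resource(R0, p))])
            for t_pert in t_pert_values:
                for phi in phi_values:
                    try:
                        rec = perturbation_experiment(p, state0, t_pert, phi, horizon, opts)
                    except ValueError:
                        break
                    if (
                        rec.outcome == "collapse"
                        and rec.quasistatic_outcome == "sustainable"
                        and rec.initial_recovery is not None
                    ):
                        return {
                            "c0": float(c0),
                            "h": float(h),
                            "phi": float(phi),
                            "t_pert": float(t_pert),
                            "R0": float(state0[0]),
                            "P0": float(state0[1]),
                            "S0": float(state0[2]),
                        }
    return None


#: A debt-driven perturbation reversal located by the grid-search routine in
#: this module and pinned as a regression fixture: near the fold
#: (h at 90% of the way from the exit to the fold locus at c0 = 10*r), a
#: system colonizing from high habitat and low population is perturbed while
#: the population is still growing.  The extended model shows an initial
#: resource recovery and then collapses; the no-debt (quasi-static) variant
#: returns to equilibrium under the identical perturbation.
REVERSAL_FIXTURE: dict[str, float] = {
    "c0": 0.044,
    "h": 0.011378181818181818,  # c0/50 + 0.9*(fold_slope*c0 - c0/50)
    "R0": 665.0,  # 0.95 * K_max
    "P0": 50.0,
    "S0": 826.0869565217391,  # Seq(R0): colonization starts debt-free
    "t_pert": 400.0,
    "phi": 0.9,
}
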