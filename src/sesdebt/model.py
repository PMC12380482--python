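"""Right-hand sides of the three model variants and their building blocks.

State layout:

* extended variant — ``(R, P, S)``: resource stock, human population,
  species richness.  Richness relaxes toward the species-area equilibrium
  ``Seq(R)`` at rate ``d``, so habitat loss creates an extinction debt
  (``S > Seq``) and habitat recovery an immigration credit (``S < Seq``).
* baseline variant — ``(R, P)``: the human carrying capacity is ``q * R``.
* quasistatic (no-debt) variant — ``(R, P)``: the ``d -> inf`` limit of the
  extended model, with richness slaved to habitat, ``S == Seq(R)``.

All derivative evaluations are pure functions of (state, params); the system
is autonomous.
"""

from __future__ import annotations

import numpy as np

from .forms import ES_FORMS, SAR_FORMS
from .params import ModelParams

__all__ = [
    "SERVICE_FLOOR",
    "es_supply",
    "es_supply_prime",
    "seq_of_resource",
    "seq_prime",
    "rhs_extended",
    "rhs_baseline",
    "rhs_quasistatic",
    "rhs",
    "state_dim",
]

#: Regularization floor for the service-based carrying capacity q*ES(S)
#: (people km^-2).  The logistic human growth term divides by q*ES, which
#: vanishes with biodiversity; flooring the divisor keeps dP/dt strongly
#: negative but finite when services collapse, so the ODE stays integrable.
SERVICE_FLOOR = 1e-9


def _check_nonneg(x, name: str) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def es_supply(S, params: ModelParams):
    """Ecosystem service supply ES(S) (service units km^-2).

    Saturating in richness: zero at ``S = 0``, half of ``ES_max`` at
    ``S = c1`` for the default form, bounded above by ``ES_max``.
    """
    _check_nonneg(S, "S")
    return ES_FORMS[params.es_form].f(S, params)


def es_supply_prime(S, params: ModelParams):
    """d ES / d S for the selected service form."""
    return ES_FORMS[params.es_form].df(S, params)


def seq_of_resource(R, params: ModelParams):
    """Equilibrium species richness Seq(R) (species).

    The species-area relationship with habitat area proportional to the
    foundation-species stock (relative area A/A_max = R/K_max): zero at
    ``R = 0``, half of ``S_max`` at relative area ``c2`` for the default
    form, saturating toward ``S_max``.
    """
    _check_nonneg(R, "R")
    return SAR_FORMS[params.sar_form].f(R, params)


def seq_prime(R, params: ModelParams):
    """d Seq / d R for the selected species-area form."""
    return SAR_FORMS[params.sar_form].df(R, params)


def _check_state(state, dim: int) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (dim,):
        raise ValueError(f"state must have shape ({dim},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y}")
    return y


def _logistic_population(P: float, capacity: float, params: ModelParams) -> float:
    # Floored divisor: collapse of the carrying capacity gives a strongly
    # negative but finite growth term.
    return params.r * P * (1.0 - P / max(capacity, SERVICE_FLOOR))


def rhs_extended(state, params: ModelParams) -> np.ndarray:
    """Time derivatives (dR/dt, dP/dt, dS/dt) of the extended model."""
    R, P, S = _check_state(state, 3)
    # The saturating links are only defined on the orthant; adaptive solvers
    # may probe marginally negative values, which we clamp.
    Rc, Sc = max(R, 0.0), max(S, 0.0)
    dR = params.c0 * R * (1.0 - R / params.K_max) - params.h * P
    dP = _logistic_population(P, params.q * es_supply(Sc, params), params)
    dS = params.d * (seq_of_resource(Rc, params) - S)
    return np.array([dR, dP, dS])


def rhs_baseline(state, params: ModelParams) -> np.ndarray:
    """Time derivatives (dR/dt, dP/dt) of the baseline consumer-resource model."""
    R, P = _check_state(state, 2)
    dR = params.c0 * R * (1.0 - R / params.K_max) - params.h * P
    dP = _logistic_population(P, params.q * R, params)
    return np.array([dR, dP])


def rhs_quasistatic(state, params: ModelParams) -> np.ndarray:
    """Time derivatives (dR/dt, dP/dt) of the no-debt (d -> inf) variant."""
    R, P = _check_state(state, 2)
    Rc = max(R, 0.0)
    dR = params.c0 * R * (1.0 - R / params.K_max) - params.h * P
    capacity = params.q * es_supply(seq_of_resource(Rc, params), params)
    dP = _logistic_population(P, capacity, params)
    return np.array([dR, dP])


_RHS = {
    "extended": (3, rhs_extended),
    "baseline": (2, rhs_baseline),
    "quasistatic": (2, rhs_quasistatic),
}


def state_dim(variant: str) -> int:
    """Number of state variables of a model variant."""
    return _RHS[_validate_variant(variant)][0]


def _validate_variant(variant: str) -> str:
    if variant not in _RHS:
        raise ValueError(f"unknown model variant {variant!r}; known: {sorted(_RHS)}")
    return variant


def rhs(variant: str):
    """Return the derivative function ``f(state, params)`` for a variant."""
    return _RHS[_validate_variant(variant)][1]
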