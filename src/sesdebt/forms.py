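"""Registry of functional forms for the two saturating links in the model.

Two links are pluggable: the biodiversity -> ecosystem-service supply function
``ES(S)`` and the species-area relationship ``Seq(R)`` (equilibrium richness
as a function of the foundation-species stock, which is proportional to
habitat area).  The defaults are Michaelis-Menten-type saturating forms.

The alternative forms ("exponential" service saturation and the classic
power-law species-area curve) are documented stand-ins used for robustness
checks; they share the defaults' qualitative shape (zero at zero, monotone,
saturating/bounded growth) but are not calibrated alternatives.

Each registry entry provides the function and its derivative with respect to
the state argument, so the analytic Jacobian works for every form.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Callable, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelParams

__all__ = ["ES_FORMS", "SAR_FORMS", "FormPair"]

_LN2 = math.log(2.0)


class FormPair(NamedTuple):
    """A functional form and its derivative w.r.t. the state argument."""

    f: Callable
    df: Callable


# -- biodiversity -> ecosystem service supply --------------------------------


def _es_saturating(S, p: "ModelParams"):
    return p.ES_max * S / (p.c1 + S)


def _des_saturating(S, p: "ModelParams"):
    return p.ES_max * p.c1 / (p.c1 + S) ** 2


def _es_exponential(S, p: "ModelParams"):
    # Half-maximum at S = c1, like the default form.
    return p.ES_max * (1.0 - np.exp(-S * _LN2 / p.c1))


def _des_exponential(S, p: "ModelParams"):
    return p.ES_max * (_LN2 / p.c1) * np.exp(-S * _LN2 / p.c1)


# -- species-area relationship (richness vs. resource stock) -----------------


def _sar_saturating(R, p: "ModelParams"):
    return p.S_max * R / (p.c2 * p.K_max + R)


def _dsar_saturating(R, p: "ModelParams"):
    return p.S_max * p.c2 * p.K_max / (p.c2 * p.K_max + R) ** 2


def _sar_power(R, p: "ModelParams"):
    return p.S_max * (np.asarray(R, dtype=float) / p.K_max) ** p.sar_z


def _dsar_power(R, p: "ModelParams"):
    R = np.asarray(R, dtype=float)
    # Derivative diverges at R = 0 for z < 1; callers guard against that.
    with np.errstate(divide="ignore"):
        return p.S_max * p.sar_z / p.K_max * (R / p.K_max) ** (p.sar_z - 1.0)


ES_FORMS: dict[str, FormPair] = {
    "saturating": FormPair(_es_saturating, _des_saturating),
    "exponential": FormPair(_es_exponential, _des_exponential),
}

SAR_FORMS: dict[str, FormPair] = {
    "saturating": FormPair(_sar_saturating, _dsar_saturating),
    "power": FormPair(_sar_power, _dsar_power),
}
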