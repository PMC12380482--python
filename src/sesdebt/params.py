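"""Model parameters and their (de)serialization.

The model couples three state variables on a per-km^2 basis: a harvestable
foundation-species resource ``R`` (resource units km^-2), a human population
``P`` (people km^-2) and species richness ``S`` (species).  The ten
parameters below control resource growth and harvest, the saturating
biodiversity -> ecosystem-service link, the species-area relationship and
its relaxation rate.  Units follow the field's convention of local densities;
the model is never nondimensionalized.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["ModelParams", "C0_SCAN", "H_SCAN", "VARIANTS"]

#: Documented scan range for resource productivity c0 (year^-1).
C0_SCAN = (0.0, 0.044)
#: Documented scan range for the per-capita harvest rate h
#: (resource units person^-1 year^-1).
H_SCAN = (0.0, 0.0132)

#: The three model variants.  "extended" is the full three-variable model with
#: delayed biodiversity relaxation (and hence extinction/service debts);
#: "baseline" ties the human carrying capacity directly to the resource stock;
#: "quasistatic" is the no-debt d -> infinity limit in which biodiversity
#: tracks habitat instantaneously.
VARIANTS = ("extended", "baseline", "quasistatic")


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for all model variants.

    Attributes
    ----------
    r : float
        Relative human population growth rate (year^-1).
    q : float
        People sustained per unit of ecosystem service supply.
    ES_max : float
        Maximum ecosystem service supply (service units km^-2).
    c1 : float
        Biodiversity at which service supply is half of ``ES_max`` (species).
    c2 : float
        Relative habitat area at which equilibrium biodiversity is half of
        ``S_max`` (dimensionless).
    c0 : float
        Resource (foundation species) productivity (year^-1).
    K_max : float
        Resource carrying capacity (resource units km^-2).
    d : float
        Biodiversity relaxation rate (year^-1); 1/d is the e-folding time of
        extinction debts and immigration credits.
    S_max : float
        Maximum biodiversity (species).
    h : float
        Per-capita harvest rate (resource units person^-1 year^-1).
    es_form, sar_form : str
        Selectors for the biodiversity->service and species-area functional
        forms (see :mod:`sesdebt.forms`).
    sar_z : float
        Exponent of the power-law species-area form (only used when
        ``sar_form == "power"``).
    """

    r: float = 0.0044
    q: float = 1.0
    ES_max: float = 700.0
    c1: float = 100.0
    c2: float = 0.2
    c0: float = 0.0044
    K_max: float = 700.0
    d: float = math.log(2.0) / 50.0
    S_max: float = 1000.0
    h: float = 0.0
    es_form: str = "saturating"
    sar_form: str = "saturating"
    sar_z: float = 0.25

    def __post_init__(self) -> None:
        for name in ("r", "q", "ES_max", "c1", "c2", "c0", "K_max", "d", "S_max", "h", "sar_z"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
        for name in ("c1", "c2", "K_max", "S_max", "q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        # Form names are validated lazily by the registry, but catch obvious
        # mistakes early.
        from . import forms

        if self.es_form not in forms.ES_FORMS:
            raise ValueError(f"unknown es_form {self.es_form!r}; known: {sorted(forms.ES_FORMS)}")
        if self.sar_form not in forms.SAR_FORMS:
            raise ValueError(
                f"unknown sar_form {self.sar_form!r}; known: {sorted(forms.SAR_FORMS)}"
            )

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        """Write the parameter set as a flat key -> value YAML mapping.

        Keys are named exactly after the model symbols (r, q, ES_max, c1, c2,
        c0, K_max, d, S_max, h) plus the functional-form selectors.
        """
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path!r} must contain a mapping")
        return cls.from_dict(data)
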