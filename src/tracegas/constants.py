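"""Physical constants and domain types for seawater trace-gas chemistry.

Constants are shipped as a human-readable YAML file (``data/constants.yaml``)
so the sources can be audited or swapped. :func:`load_constants` parses the
file into frozen dataclasses; module-level helpers serve a cached default
registry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigurationError, ValidationError

#: Ideal gas constant (J mol^-1 K^-1).
R = 8.314
#: Ideal gas constant in volumetric units (L atm mol^-1 K^-1).
R_GAS_L_ATM = 0.08206
#: Reference temperature for Henry and Sechenov constants (K).
T_REF = 298.15
#: Default incubation / reference temperature (K): 20 degC.
T_DEFAULT = 293.15


@dataclass(frozen=True)
class GasSpecies:
    """Physical constants of a single gas.

    Parameters
    ----------
    name
        Gas identifier (``H2``, ``CO``, ``CH4``, ``O2``, ``CO2``).
    henry_ref
        Freshwater solubility (Henry's law constant) at 298.15 K,
        mol L^-1 atm^-1.
    vant_hoff
        Temperature slope ``-Delta_soln H / R`` in K; positive for gases
        whose solubility increases on cooling.
    sechenov_ref
        Gas-specific salting-out constant ``h_G,0`` at 298.15 K, m^3 kmol^-1.
    sechenov_temp
        Temperature slope ``h_T`` of the gas-specific constant,
        m^3 kmol^-1 K^-1.
    delta_g0
        Standard Gibbs free energy of the aerobic oxidation of one mole of
        the gas, J mol^-1 (``None`` if the oxidation is not modelled).
    stoichiometry
        Stoichiometric coefficients of the oxidation reaction; negative for
        species consumed, positive for species produced. The gas itself
        carries -1.
    """

    name: str
    henry_ref: float
    vant_hoff: float
    sechenov_ref: float
    sechenov_temp: float
    delta_g0: float | None = None
    stoichiometry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.henry_ref <= 0:
            raise ValidationError(f"{self.name}: henry_ref must be positive")
        if self.stoichiometry and self.stoichiometry.get(self.name) != -1.0:
            raise ValidationError(
                f"{self.name}: the gas itself must appear with coefficient -1 "
                "in its oxidation stoichiometry"
            )


@dataclass(frozen=True)
class SeawaterMatrix:
    """Ionic composition of a water matrix with per-ion Sechenov constants.

    ``ions`` is a tuple of ``(ion name, concentration kmol/m^3, h_i m^3/kmol)``.
    An empty tuple represents freshwater.
    """

    label: str
    ions: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        for name, conc, _ in self.ions:
            if conc < 0:
                raise ValidationError(f"ion {name}: concentration must be >= 0")

    @classmethod
    def freshwater(cls) -> "SeawaterMatrix":
        return cls(label="freshwater", ions=())


@dataclass(frozen=True)
class PowerReference:
    """Cellular power thresholds (W per cell) for regime classification."""

    maintenance_median: float
    growth_median: float
    growth_range: tuple[float, float]


@dataclass(frozen=True)
class ConstantsRegistry:
    gases: Mapping[str, GasSpecies]
    matrices: Mapping[str, SeawaterMatrix]
    atmosphere: Mapping[str, float]
    power_reference: PowerReference


def load_constants(path: str | Path | None = None) -> ConstantsRegistry:
    """Parse a constants YAML file into a :class:`ConstantsRegistry`.

    With ``path=None`` the packaged default file is used.
    """
    if path is None:
        text = (resources.files("tracegas") / "data/constants.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    gases = {
        name: GasSpecies(
            name=name,
            henry_ref=float(spec["henry_ref"]),
            vant_hoff=float(spec["vant_hoff"]),
            sechenov_ref=float(spec["sechenov_ref"]),
            sechenov_temp=float(spec["sechenov_temp"]),
            delta_g0=None if spec.get("delta_g0") is None else float(spec["delta_g0"]),
            stoichiometry={k: float(v) for k, v in (spec.get("stoichiometry") or {}).items()},
        )
        for name, spec in raw["gases"].items()
    }
    matrices = {
        name: SeawaterMatrix(
            label=str(spec.get("label", name)),
            ions=tuple(
                (ion, float(cv[0]), float(cv[1]))
                for ion, cv in (spec.get("ions") or {}).items()
            ),
        )
        for name, spec in raw["seawater"].items()
    }
    pr = raw["power_reference"]
    power_reference = PowerReference(
        maintenance_median=float(pr["maintenance_median"]),
        growth_median=float(pr["growth_median"]),
        growth_range=(float(pr["growth_range"][0]), float(pr["growth_range"][1])),
    )
    atmosphere = {k: float(v) for k, v in raw["atmosphere"].items()}
    return ConstantsRegistry(gases, matrices, atmosphere, power_reference)


@lru_cache(maxsize=1)
def default_registry() -> ConstantsRegistry:
    return load_constants(None)


def get_gas(name: str) -> GasSpecies:
    """Look up a gas in the default constants registry."""
    try:
        return default_registry().gases[name]
    except KeyError:
        known = ", ".join(sorted(default_registry().gases))
        raise ConfigurationError(f"unknown gas {name!r}; known gases: {known}") from None


def get_matrix(name: str) -> SeawaterMatrix:
    """Look up a water matrix (``mean_seawater`` or ``freshwater``)."""
    try:
        return default_registry().matrices[name]
    except KeyError:
        known = ", ".join(sorted(default_registry().matrices))
        raise ConfigurationError(f"unknown matrix {name!r}; known: {known}") from None


def atmospheric_ppmv(gas: str) -> float:
    """Default atmospheric mixing ratio of a gas (ppmv)."""
    try:
        return default_registry().atmosphere[gas]
    except KeyError:
        raise ConfigurationError(f"no atmospheric mixing ratio configured for {gas!r}") from None


def power_reference() -> PowerReference:
    return default_registry().power_reference
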