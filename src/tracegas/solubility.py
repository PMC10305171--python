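"""Gas solubility in seawater and atmospheric supersaturation.

The effective solubility of a trace gas in seawater is modelled in three
steps:

1. the freshwater Henry's law constant at temperature ``T`` via the combined
   Henry / van 't Hoff relation
   ``k_G,0(T) = k'_G,0 * exp(vant_hoff * (1/T - 1/298.15))``;
2. the salting-out correction for a mixed electrolyte via the Sechenov
   relation ``log10(k_G,0 / k_G) = sum_i (h_i + h_G) * c_i`` with the
   gas-specific constant ``h_G = h_G,0 + h_T * (T - 298.15)``;
3. the equilibrium dissolved concentration from the partial pressure,
   ``C = k_G * x * 1e-6 * P`` for a mixing ratio ``x`` in ppmv at total
   pressure ``P`` in atm.

Supersaturation is the ratio of a measured dissolved concentration to the
air-equilibrated concentration under the same conditions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    GasSpecies,
    SeawaterMatrix,
    T_DEFAULT,
    T_REF,
    atmospheric_ppmv,
    get_matrix,
)
from .exceptions import DomainError, ValidationError

#: Supported temperature range (K) for the shipped constants.
T_MIN, T_MAX = 270.0, 320.0


@dataclass(frozen=True)
class EquilibriumResult:
    """Air-equilibrium state of one gas in one water matrix."""

    gas: str
    temperature: float  # K
    mixing_ratio: float  # ppmv
    k_g: float  # effective solubility, mol L^-1 atm^-1
    concentration: float  # dissolved concentration, nM


def _check_temperature(t_kelvin: float) -> None:
    if not (T_MIN < t_kelvin < T_MAX):
        raise DomainError(
            f"temperature {t_kelvin} K outside supported range ({T_MIN}, {T_MAX}) K"
        )


def henry_at_temperature(gas: GasSpecies, t_kelvin: float) -> float:
    """Freshwater Henry's law constant at ``t_kelvin`` (mol L^-1 atm^-1)."""
    _check_temperature(t_kelvin)
    return gas.henry_ref * math.exp(gas.vant_hoff * (1.0 / t_kelvin - 1.0 / T_REF))


def sechenov_factor(gas: GasSpecies, matrix: SeawaterMatrix, t_kelvin: float) -> float:
    """Salting-out ratio ``k_G / k_G,0`` for a mixed electrolyte (0, 1].

    Returns 1.0 for freshwater (empty ion list). The factor drops below one
    whenever the summed ``(h_i + h_G) * c_i`` terms are positive, the usual
    salting-out case for marine ions.
    """
    _check_temperature(t_kelvin)
    h_gas = gas.sechenov_ref + gas.sechenov_temp * (t_kelvin - T_REF)
    log_ratio = 0.0
    for name, conc, h_ion in matrix.ions:
        if conc < 0:
            raise ValidationError(f"ion {name}: negative concentration")
        log_ratio += (h_ion + h_gas) * conc
    return 10.0 ** (-log_ratio)


def equilibrium_concentration(
    gas: GasSpecies,
    mixing_ratio: float,
    t_kelvin: float = T_DEFAULT,
    matrix: SeawaterMatrix | None = None,
    pressure: float = 1.0,
) -> float:
    """Dissolved concentration (nM) in equilibrium with a gas phase.

    ``mixing_ratio`` is in ppmv at total pressure ``pressure`` (atm);
    ``matrix`` defaults to mean seawater. Linear in both ``mixing_ratio``
    and ``pressure``.
    """
    if mixing_ratio < 0:
        raise ValidationError("mixing_ratio must be >= 0 ppmv")
    if pressure <= 0:
        raise ValidationError("pressure must be positive")
    if matrix is None:
        matrix = get_matrix("mean_seawater")
    k_g = henry_at_temperature(gas, t_kelvin) * sechenov_factor(gas, matrix, t_kelvin)
    partial_pressure = mixing_ratio * 1e-6 * pressure  # atm
    return k_g * partial_pressure * 1e9  # mol/L -> nM


def equilibrium_state(
    gas: GasSpecies,
    mixing_ratio: float,
    t_kelvin: float = T_DEFAULT,
    matrix: SeawaterMatrix | None = None,
    pressure: float = 1.0,
) -> EquilibriumResult:
    """Like :func:`equilibrium_concentration` but returns the full record."""
    if matrix is None:
        matrix = get_matrix("mean_seawater")
    k_g = henry_at_temperature(gas, t_kelvin) * sechenov_factor(gas, matrix, t_kelvin)
    conc = equilibrium_concentration(gas, mixing_ratio, t_kelvin, matrix, pressure)
    return EquilibriumResult(gas.name, t_kelvin, mixing_ratio, k_g, conc)


def saturation_fold(
    measured_nm: float,
    gas: GasSpecies,
    atm_mixing_ratio: float | None = None,
    t_kelvin: float = T_DEFAULT,
    matrix: SeawaterMatrix | None = None,
    pressure: float = 1.0,
) -> float:
    """Supersaturation of a measured dissolved concentration vs the atmosphere.

    ``atm_mixing_ratio`` defaults to the configured atmospheric mixing ratio
    of the gas. A fold of 1.0 means air-equilibrated; > 1 supersaturated.
    """
    if measured_nm < 0:
        raise ValidationError("measured concentration must be >= 0 nM")
    if atm_mixing_ratio is None:
        atm_mixing_ratio = atmospheric_ppmv(gas.name)
    eq = equilibrium_concentration(gas, atm_mixing_ratio, t_kelvin, matrix, pressure)
    if eq == 0.0:
        raise ValidationError(
            "equilibrium concentration is zero (zero atmospheric mixing ratio); "
            "saturation fold is undefined"
        )
    return measured_nm / eq
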