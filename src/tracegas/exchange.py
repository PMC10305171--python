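"""Gas partitioning between vial headspace and seawater.

Closed serum vials with continuous agitation are treated as two-phase
equilibrium systems: an ideal-gas headspace at the vial's total pressure
plus a liquid phase obeying the Sechenov-corrected Henry's law of
:mod:`tracegas.solubility`. The same mass balance inverts the N2-headspace
extraction procedure used to measure in situ dissolved gases: a known water
volume is equilibrated with an introduced N2 headspace and the original
dissolved concentration is back-calculated from the measured headspace
mixing ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    GasSpecies,
    R_GAS_L_ATM,
    SeawaterMatrix,
    T_DEFAULT,
    get_matrix,
)
from .exceptions import ConfigurationError, ValidationError
from .solubility import equilibrium_concentration, henry_at_temperature, sechenov_factor


@dataclass(frozen=True)
class VialConfig:
    """Geometry and conditions of a sealed incubation vial."""

    v_liquid: float  # L
    v_headspace: float  # L
    temperature: float = T_DEFAULT  # K
    pressure: float = 1.0  # atm
    matrix: SeawaterMatrix = field(default_factory=lambda: get_matrix("mean_seawater"))

    def __post_init__(self) -> None:
        if self.v_liquid <= 0:
            raise ValidationError("v_liquid must be positive")
        if self.v_headspace < 0:
            raise ValidationError("v_headspace must be >= 0")


#: Vial presets: oceanic-transect / temperate-bay microcosms (60 mL seawater
#: in 120 mL vials), tropical-island microcosms (80 mL in 160 mL) and the
#: in situ extraction vials (140 mL water, 20 mL N2 headspace).
VIAL_PRESETS: dict[str, VialConfig] = {
    "munida": VialConfig(v_liquid=0.060, v_headspace=0.060),
    "heron": VialConfig(v_liquid=0.080, v_headspace=0.080),
    "extraction": VialConfig(v_liquid=0.140, v_headspace=0.020),
}


def get_vial(name: str) -> VialConfig:
    try:
        return VIAL_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(VIAL_PRESETS))
        raise ConfigurationError(f"unknown vial preset {name!r}; known: {known}") from None


@dataclass(frozen=True)
class GasInventory:
    """Mass-balance snapshot of one gas in a two-phase vial."""

    gas: str
    mixing_ratio: float  # ppmv
    dissolved: float  # nM
    moles_headspace: float  # mol
    moles_dissolved: float  # mol

    @property
    def total_moles(self) -> float:
        return self.moles_headspace + self.moles_dissolved


def _effective_solubility(gas: GasSpecies, vial: VialConfig) -> float:
    """Sechenov-corrected solubility at the vial conditions (mol/L/atm)."""
    return henry_at_temperature(gas, vial.temperature) * sechenov_factor(
        gas, vial.matrix, vial.temperature
    )


def headspace_to_dissolved(mixing_ratio: float, gas: GasSpecies, vial: VialConfig) -> float:
    """Dissolved concentration (nM) in equilibrium with the headspace."""
    return equilibrium_concentration(
        gas, mixing_ratio, vial.temperature, vial.matrix, vial.pressure
    )


def vial_inventory(mixing_ratio: float, gas: GasSpecies, vial: VialConfig) -> GasInventory:
    """Headspace and dissolved gas amounts at phase equilibrium.

    The headspace is an ideal gas at the vial's temperature and total
    pressure; the dissolved pool is the Henry-law equilibrium with the same
    partial pressure.
    """
    if mixing_ratio < 0:
        raise ValidationError("mixing_ratio must be >= 0 ppmv")
    partial_pressure = mixing_ratio * 1e-6 * vial.pressure  # atm
    moles_headspace = (
        partial_pressure * vial.v_headspace / (R_GAS_L_ATM * vial.temperature)
    )
    dissolved_nm = headspace_to_dissolved(mixing_ratio, gas, vial)
    moles_dissolved = dissolved_nm * 1e-9 * vial.v_liquid
    return GasInventory(gas.name, mixing_ratio, dissolved_nm, moles_headspace, moles_dissolved)


def partition_moles(total_moles: float, gas: GasSpecies, vial: VialConfig) -> GasInventory:
    """Distribute a total gas amount between the two phases at equilibrium.

    Inverse of :func:`vial_inventory`'s total: solves the linear mass balance
    ``n_total = p * V_h / (R T) + k_G * p * V_l`` for the partial pressure
    ``p`` and returns the resulting inventory.
    """
    if total_moles < 0:
        raise ValidationError("total_moles must be >= 0")
    k_g = _effective_solubility(gas, vial)
    capacity = (
        vial.v_headspace / (R_GAS_L_ATM * vial.temperature) + k_g * vial.v_liquid
    )  # mol per atm of partial pressure
    partial_pressure = total_moles / capacity
    mixing_ratio = partial_pressure / vial.pressure * 1e6
    return vial_inventory(mixing_ratio, gas, vial)


def insitu_from_extraction(
    measured_headspace_ppmv: float,
    gas: GasSpecies,
    v_water: float = 0.140,
    v_headspace: float = 0.020,
    t_kelvin: float = T_DEFAULT,
    matrix: SeawaterMatrix | None = None,
    pressure: float = 1.0,
) -> float:
    """In situ dissolved concentration (nM) from an N2-headspace extraction.

    A water sample of ``v_water`` L initially free of headspace is
    equilibrated with an introduced N2 headspace of ``v_headspace`` L; the
    gas mixing ratio measured in that headspace is fed back through the mass
    balance to recover the pre-extraction dissolved concentration. Assumes
    full phase equilibration (vigorous shaking).
    """
    if measured_headspace_ppmv < 0:
        raise ValidationError("measured mixing ratio must be >= 0 ppmv")
    if matrix is None:
        matrix = get_matrix("mean_seawater")
    vial = VialConfig(
        v_liquid=v_water,
        v_headspace=v_headspace,
        temperature=t_kelvin,
        pressure=pressure,
        matrix=matrix,
    )
    inventory = vial_inventory(measured_headspace_ppmv, gas, vial)
    return inventory.total_moles / v_water * 1e9  # mol -> nM over the water volume
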