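"""Thermodynamics of aerobic trace-gas oxidation: Gibbs energy and cell power.

For a reaction such as H2 + 0.5 O2 -> H2O the Gibbs free energy at ambient
conditions is ``dG_r = dG_r0 + R T ln(Q_r)`` with the reaction quotient
``Q_r = prod_i a_i^{n_i}`` over dissolved activities (water activity fixed
at 1; activities taken equal to concentrations at the dilute limit). The
power harvested per cell from a bulk consumption rate ``v`` (mol L^-1 s^-1)
by ``B`` oxidizer cells per litre is ``P = |v * dG_r| / B`` (W per cell),
and the cell abundance a given rate could sustain at a maintenance power
``m`` is ``|v * dG_r| / m``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .constants import (
    GasSpecies,
    PowerReference,
    R,
    SeawaterMatrix,
    T_DEFAULT,
    atmospheric_ppmv,
    get_gas,
    power_reference,
)
from .exceptions import DomainError, ValidationError
from .solubility import equilibrium_concentration

#: Default maintenance power, W per cell (median endogenous metabolic rate
#: of organoheterotrophic bacterial isolates at 20 degC).
MAINTENANCE_W = 1.9e-15


@dataclass(frozen=True)
class AmbientChemistry:
    """Dissolved activities (mol/L) of the species entering the quotient."""

    activities: Mapping[str, float]
    temperature: float = T_DEFAULT  # K

    @classmethod
    def air_equilibrated(
        cls,
        donor_gas: str,
        donor_nm: float,
        t_kelvin: float = T_DEFAULT,
        matrix: SeawaterMatrix | None = None,
        o2_ppmv: float | None = None,
        co2_ppmv: float | None = None,
    ) -> "AmbientChemistry":
        """Ambient chemistry with O2 and CO2 at air equilibrium.

        The electron donor (H2 or CO) is set to the supplied dissolved
        concentration in nM; O2 and CO2 default to equilibrium with their
        atmospheric mixing ratios.
        """
        o2_ppmv = atmospheric_ppmv("O2") if o2_ppmv is None else o2_ppmv
        co2_ppmv = atmospheric_ppmv("CO2") if co2_ppmv is None else co2_ppmv
        activities = {
            donor_gas: donor_nm * 1e-9,
            "O2": equilibrium_concentration(get_gas("O2"), o2_ppmv, t_kelvin, matrix) * 1e-9,
            "CO2": equilibrium_concentration(get_gas("CO2"), co2_ppmv, t_kelvin, matrix) * 1e-9,
        }
        return cls(activities=activities, temperature=t_kelvin)


@dataclass(frozen=True)
class PowerEstimate:
    """Per-sample thermodynamic summary of one gas's oxidation."""

    gas: str
    q_r: float
    delta_g_r: float  # J mol^-1 (negative for exergonic)
    v: float  # mol L^-1 s^-1
    b: float  # oxidizer cells L^-1
    power_per_cell: float  # W, positive magnitude
    supported_cells: float  # cells L^-1 at the stated maintenance power
    maintenance: float = MAINTENANCE_W


def reaction_quotient(gas: GasSpecies, chem: AmbientChemistry) -> float:
    """Reaction quotient ``Q_r = prod a_i^{n_i}`` (water activity = 1)."""
    if not gas.stoichiometry:
        raise ValidationError(f"{gas.name}: no oxidation stoichiometry configured")
    q = 1.0
    for species, coeff in gas.stoichiometry.items():
        if species == "H2O":
            continue
        activity = chem.activities.get(species)
        if activity is None:
            raise ValidationError(f"missing activity for species {species!r}")
        if activity <= 0:
            raise ValidationError(f"activity of {species!r} must be positive")
        q *= activity**coeff
    return q


def gibbs_energy(gas: GasSpecies, chem: AmbientChemistry) -> float:
    """Gibbs free energy of oxidation at ambient conditions (J mol^-1)."""
    if chem.temperature <= 0:
        raise DomainError("temperature must be positive (K)")
    if gas.delta_g0 is None:
        raise ValidationError(f"{gas.name}: no standard Gibbs energy configured")
    q_r = reaction_quotient(gas, chem)
    if q_r <= 0:
        raise DomainError("reaction quotient must be positive")
    return gas.delta_g0 + R * chem.temperature * math.log(q_r)


def power_per_cell(v: float, delta_g_r: float, b: float) -> float:
    """Power per cell ``|v * dG_r| / B`` in W.

    Reported as a positive magnitude for exergonic reactions; the sign of
    ``dG_r`` is preserved in the caller's Gibbs-energy field.
    """
    if b <= 0:
        raise ValidationError("oxidizer abundance B must be positive")
    if v < 0:
        raise ValidationError("consumption rate v must be >= 0")
    return abs(v * delta_g_r) / b


def supported_cells(v: float, delta_g_r: float, maintenance: float = MAINTENANCE_W) -> float:
    """Cell abundance (cells L^-1) sustainable at a given maintenance power."""
    if maintenance <= 0:
        raise ValidationError("maintenance power must be positive")
    if v < 0:
        raise ValidationError("consumption rate v must be >= 0")
    return abs(v * delta_g_r) / maintenance


def classify_power(
    power: float, reference: PowerReference | None = None
) -> str:
    """Assign a metabolic regime label to a per-cell power (W).

    Labels: ``below-maintenance`` (below the maintenance median),
    ``maintenance`` (between the maintenance and growth medians; the
    boundary value itself belongs here) and ``growth-range`` (at or above
    the growth median).
    """
    if reference is None:
        reference = power_reference()
    if power < 0:
        raise ValidationError("power must be >= 0")
    if power < reference.maintenance_median:
        return "below-maintenance"
    if power < reference.growth_median:
        return "maintenance"
    return "growth-range"


def estimate_power(
    gas_name: str,
    v: float,
    b: float,
    donor_nm: float,
    t_kelvin: float = T_DEFAULT,
    matrix: SeawaterMatrix | None = None,
    maintenance: float = MAINTENANCE_W,
) -> PowerEstimate:
    """Convenience pipeline from rate + cell abundance to a PowerEstimate."""
    gas = get_gas(gas_name)
    chem = AmbientChemistry.air_equilibrated(gas_name, donor_nm, t_kelvin, matrix)
    q_r = reaction_quotient(gas, chem)
    dg = gibbs_energy(gas, chem)
    return PowerEstimate(
        gas=gas_name,
        q_r=q_r,
        delta_g_r=dg,
        v=v,
        b=b,
        power_per_cell=power_per_cell(v, dg, b),
        supported_cells=supported_cells(v, dg, maintenance),
        maintenance=maintenance,
    )
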