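# Physical constants for seawater trace-gas calculations.
#
# Sources (versioned here so they can be audited or swapped):
#   - Henry's law constants at 298.15 K and van 't Hoff temperature slopes:
#     Sander (2015) compilation / Wilhelm, Battino & Wilcock (1977).
#   - Sechenov (salting-out) gas and ion constants: Weisenberger & Schumpe
#     (1996) mixed-electrolyte model (log10 convention).
#   - Mean seawater ionic composition: Millero et al. (2008) reference
#     composition at practical salinity 35, converted from mol/kg-solution to
#     mol/L (= kmol/m^3) with the 20 degC seawater density 1.0248 kg/L.
#   - Standard Gibbs free energies of aerobic oxidation (aqueous standard
#     states, 25 degC) from standard free energies of formation.
#
# Units:
#   henry_ref      mol L^-1 atm^-1   (freshwater solubility at 298.15 K)
#   vant_hoff      K                 (-Delta_soln H / R)
#   sechenov_ref   m^3 kmol^-1       (gas-specific salting-out constant h_G,0)
#   sechenov_temp  m^3 kmol^-1 K^-1  (temperature slope h_T of h_G)
#   delta_g0       J mol^-1          (standard Gibbs energy of aerobic
#                                     oxidation, per mole of gas; null where
#                                     the oxidation reaction is not modelled)
#   stoichiometry  unitless          (negative = consumed, positive = produced;
#                                     the gas itself always carries -1)
#   ion concentrations  kmol m^-3 (= mol/L); Sechenov h_i in m^3 kmol^-1

gases:
  H2:
    henry_ref: 7.8e-4
    vant_hoff: 530.0
    sechenov_ref: -0.0218
    sechenov_temp: -2.99e-4
    delta_g0: -263130.0
    stoichiometry: {H2: -1.0, O2: -0.5, H2O: 1.0}
  CO:
    henry_ref: 9.7e-4
    vant_hoff: 1300.0
    sechenov_ref: -0.0183
    sechenov_temp: -3.04e-4
    delta_g0: -274240.0
    stoichiometry: {CO: -1.0, O2: -0.5, CO2: 1.0}
  CH4:
    henry_ref: 1.4e-3
    vant_hoff: 1600.0
    sechenov_ref: 0.0022
    sechenov_temp: -5.24e-4
    delta_g0: -859000.0
    stoichiometry: {CH4: -1.0, O2: -2.0, CO2: 1.0, H2O: 2.0}
  O2:
    henry_ref: 1.27e-3
    vant_hoff: 1500.0
    sechenov_ref: 0.0
    sechenov_temp: -3.34e-4
    delta_g0: null
    stoichiometry: {}
  CO2:
    henry_ref: 3.4e-2
    vant_hoff: 2400.0
    sechenov_ref: -0.0172
    sechenov_temp: -3.38e-4
    delta_g0: null
    stoichiometry: {}

# Default atmospheric mixing ratios (ppmv).
atmosphere:
  H2: 0.53
  CO: 0.09
  CH4: 1.9
  O2: 209500.0
  CO2: 410.0

seawater:
  mean_seawater:
    label: "mean seawater (S=35 reference composition)"
    # ion: [concentration kmol/m^3, Sechenov h_i m^3/kmol]
    # Sr2+ uses the Ca2+ Schumpe constant (no published value; contribution
    # to the salting-out sum is < 0.03%).
    ions:
      Na+:    [0.48070, 0.1143]
      Mg2+:   [0.05413, 0.1694]
      Ca2+:   [0.010535, 0.1762]
      K+:     [0.010463, 0.0922]
      Sr2+:   [9.22e-5, 0.1762]
      Cl-:    [0.55941, 0.0318]
      SO42-:  [0.028941, 0.1117]
      HCO3-:  [0.001814, 0.0967]
      Br-:    [8.61e-4, 0.0269]
      CO32-:  [2.66e-4, 0.1423]
      F-:     [7.17e-5, 0.0920]
  freshwater:
    label: "freshwater (no dissolved salts)"
    ions: {}

# Cellular power reference (W per cell) for regime classification:
# median maintenance (endogenous) and growth (active) metabolic rates of
# organoheterotrophic bacterial isolates at 20 degC.
power_reference:
  maintenance_median: 1.9e-15
  growth_median: 2.6e-14
  growth_range: [2.8e-17, 2.1e-11]
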