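# Methods

This note documents the models implemented in `tracegas`, the defaults and
their provenance, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real data.

## Solubility and supersaturation

The dissolved concentration of a trace gas in equilibrium with a gas phase
is computed in three steps. The freshwater Henry's law constant at
temperature T (K) follows the combined Henry / van 't Hoff relation

    k_G,0(T) = k′_G,0 · exp[(−Δ_soln H / R)(1/T − 1/298.15)]

with R = 8.314 J mol⁻¹ K⁻¹. Salting-out in a mixed electrolyte follows the
Sechenov relation

    log₁₀(k_G,0 / k_G) = Σᵢ (hᵢ + h_G) cᵢ,   h_G = h_G,0 + h_T (T − 298.15)

with per-ion constants hᵢ (m³ kmol⁻¹), gas constants h_G,0 and h_T, and ion
concentrations cᵢ (kmol m⁻³). The logarithm is base 10, the convention of
the mixed-electrolyte formulation the constants come from. The equilibrium
concentration at mixing ratio x (ppmv) and total pressure P (atm) is
C = k_G · x·10⁻⁶·P, and the supersaturation fold of a measured dissolved
concentration is its ratio to C.

Constants ship in `src/tracegas/data/constants.yaml`: Henry constants and
van 't Hoff slopes from the Sander (2015) / Wilhelm et al. (1977)
compilations; Schumpe-model ion and gas constants from Weisenberger &
Schumpe (1996); the mean-seawater composition from the Millero et al.
(2008) salinity-35 reference composition converted to mol/L at the 20 °C
density (1.0248 kg/L). Sr²⁺, which lacks a published Schumpe constant, is
approximated with the Ca²⁺ value; its contribution to the salting-out sum
is under 0.03%. With these constants, mean seawater at 20 °C dissolves
0.367 nM H₂ at the atmospheric 0.53 ppmv and 0.080 nM CO at 0.09 ppmv.
Published Henry constants for CO vary by ~10–15% between compilations, and
the supersaturation folds inherit that spread; the shipped values are the
compilation means, not values tuned to any particular field dataset.

Defaults: 20 °C, 1 atm, mean seawater, and atmospheric mixing ratios
H₂ 0.53 ppmv / CO 0.09 ppmv / CH₄ 1.9 ppmv. In situ water temperature can
be passed per sample; the fixed 20 °C default matches the incubation
condition of the protocol the package models. Activities are not
fugacity-corrected and Henry constants carry no pressure dependence beyond
the linear partial-pressure term — both negligible at 1 atm surface
conditions.

## Closed-vial exchange and the extraction inversion

Sealed, continuously agitated serum vials are treated as two-phase
equilibrium systems: an ideal-gas headspace at the vial's total pressure
(R_gas = 0.08206 L atm mol⁻¹ K⁻¹) plus a liquid phase at the
Sechenov-corrected Henry equilibrium. Phase equilibration is assumed
complete at every timepoint; no film/mass-transfer model is included.
Headspace expansion from syringe sampling is ignored (no pressure
bookkeeping is attempted). The mass balance

    n_total = p·V_h/(R_gas·T) + k_G·p·V_l

is linear in the partial pressure p, so partitioning a known total and
inverting a measured headspace mixing ratio are exact inverses; the
extraction back-calculation (default 140 mL water equilibrated with a
20 mL N₂ headspace) recovers a known dissolved concentration to machine
precision in the round-trip property test. Vial presets: 60/60 mL,
80/80 mL and the 140/20 mL extraction geometry.

## Consumption kinetics

Each replicate headspace series (≥ 3 timepoints) is fitted with both an
exponential model C(t) = C₀e^(−kt) (nonlinear least squares initialised
from a log-linear regression) and a linear model C(t) = C₀ + bt (OLS). The
linear fit stores k = −b so that k > 0 means net consumption under either
model. Model selection minimises the least-squares AIC

    AIC = n·ln(RSS/n) + 2p,  p = 2,

with RSS floored at 10⁻¹² so noiseless synthetic series keep a finite AIC;
exact ties resolve to the exponential model. A configurable time-window
filter (default 30 d) truncates series before fitting.

QC: a sample shows confident consumption when at least two replicates have
a positive rate constant. A fitted k on a flat noisy series is positive
about half the time, so the sign alone would flag roughly half of all
sterile controls as consuming; a replicate therefore counts as positive
only when its k additionally exceeds a one-sided t threshold
(α = 0.05, df = n − 2) built from the fit's standard error. Fits supplied
without a standard error are judged on sign alone. The mean rate constant
is taken over the positive replicates only — averaging in negative k would
bias rates downward.

Bulk rates apply k to the vial's gas inventory at a stated reference
mixing ratio — by default the full two-phase inventory, the only
convention that conserves mass in a closed agitated vial; a
dissolved-pool-only variant is available (`inventory="dissolved"`), and an
in situ variant applies k directly to a measured dissolved concentration
(open water, no headspace reservoir). Rates are expressed in
mol L⁻¹ seawater s⁻¹. Cell-specific rates divide by
B = total cells × oxidizer fraction.

## Thermodynamic power

For H₂ + ½O₂ → H₂O and CO + ½O₂ → CO₂,

    ΔG_r = ΔG_r⁰ + RT ln Q_r,   Q_r = Π a_i^{n_i}

with water activity 1 and activities equal to dissolved concentrations
(infinite-dilution limit; no activity coefficients). ΔG_r⁰ uses aqueous
standard states (H₂: −263.13 kJ mol⁻¹; CO: −274.24 kJ mol⁻¹); its own
temperature dependence is neglected — only the RT·ln Q term varies, and
the model is applied at a single incubation temperature. O₂ and CO₂
default to air-equilibrated concentrations computed by the solubility
module (209,500 and 410 ppmv, configurable); the result is insensitive to
these because the dependence is logarithmic. Across the full ambient grid
(0.1–100 nM donor, 50–400 µM O₂, 5–30 °C) both oxidations remain below
−150 kJ mol⁻¹.

Power per cell is P = |v·ΔG_r|/B (W), reported as a positive magnitude
with the signed ΔG_r retained alongside; the supported cell abundance at
maintenance power m is |v·ΔG_r|/m, so P·B = supported·m identically.
Default m = 1.9 × 10⁻¹⁵ W per cell, the median endogenous metabolic rate
of organoheterotrophic bacterial isolates at 20 °C. Regime labels compare
P with the maintenance median and the growth median (2.6 × 10⁻¹⁴ W): below
the maintenance median → `below-maintenance`; between the medians
(including the maintenance boundary itself) → `maintenance`; at or above
the growth median → `growth-range`. The published growth range
(2.8 × 10⁻¹⁷–2.1 × 10⁻¹¹ W) overlaps the maintenance median, so range
membership alone cannot separate the labels; the median-based thresholds
are this package's resolution and ship in the constants file.

## Marker-gene abundance

Short-read hit tables are filtered by a per-gene minimum percent identity
(80% PsaA; 75% HbsT; 70% PsbA/IsoA/AtpA/YgfK/ARO; 60%
CoxL/MmoA/AmoA/NxrA/RbcL/NuoF/FeFe/NiFe-group-4; 50% all others) and a
minimum alignment length (40 aa for 150 bp reads; 32 aa for 100 bp reads).
Thresholds are inclusive: a hit exactly at the threshold passes. A second
mode for predicted proteins replaces the length rule with ≥ 80% query-or-
subject coverage and applies the protein-mode identity overrides (AtpA and
PsbA 60%, RdhA 45%, Cyc2 35%, RHO 30%). Running the aligner itself is out
of scope; the module consumes its tabular output.

Gene abundance is normalized to "average gene copies per organism" by
dividing the gene's RPKM by the mean RPKM of 14 universal single-copy
ribosomal markers (an opaque configurable column list — the identity of
the 14 genes is not assumed). A zero marker mean yields NaN (undefined),
never zero. RNA:DNA expression ratios divide metatranscriptome RPKM by
metagenome RPKM after averaging replicates within sample; samples with
zero metagenome abundance are excluded with a flag rather than returned as
zero. Abundance–rate coupling uses simple linear regression (rate on
abundance), reporting R² and the two-sided slope p-value.

## Synthetic data

The generators emulate the study design: triplicate live microcosms plus
an autoclaved triplicate per sample; a ~2 ppmv headspace spike in 60/60 mL
vials (2.5 and 10 ppmv variants configurable); daily headspace sampling
for 8 days (up to 30 d supported); multiplicative lognormal measurement
noise with σ = 0.05, reflecting the relative precision of gas
chromatography; and a quantification floor of 0.042 ppmv for H₂ at which
trajectories are censored. Autoclaved controls use k = 0 with an optional
linear drift (default 0) for QC false-positive testing. Hit-table
generation places identities at known offsets around the filtering
thresholds so removal counts are predictable, and sets gene RPKM to
fraction × mean marker RPKM so the true oxidizer fraction is recoverable.
The coupled survey draws lognormal abundances (mean 0.02, CV 0.8 across
14 samples) and sets rates = slope × abundance + Gaussian noise whose
variance is chosen from the realized abundance variance to hit a requested
expected R². Every generator is a pure function of its seed.

What passing tests show — and what they do not: the closure tests
demonstrate that the estimators are consistent and approximately unbiased
*under the generator's assumptions* (exact first-order decay, lognormal
noise, no endogenous gas production, full phase equilibration, known
oxidizer fractions). Real incubations add endogenous H₂ production (net
rates underestimate gross consumption), possible substrate thresholds,
community change over 30 d incubations, and cell counts and oxidizer
fractions with their own substantial errors; none of these are modelled,
so recovery percentages here bound estimator error only, not field error.

## Problem sizes and numerics

The simulation studies use the design scales throughout: 500 simulated
triplicate microcosms for the rate-recovery/QC study (k log-uniform in
0.005–0.2 h⁻¹, 5% noise, 8 daily points), 500 survey seeds for the R²
closure and 1,000 for the null-slope calibration (14 samples each). These
complete in seconds on one CPU. Nonlinear fits use analytic-free
Levenberg–Marquardt with log-linear initialisation and 10,000 function
evaluations; non-convergence is flagged rather than raised, and the
flagged fit is excluded by QC. Degenerate inputs (all-zero series, fewer
than three timepoints, zero marker mean, zero atmospheric mixing ratio)
raise typed validation errors rather than propagating NaN.

## Known limitations

- No Michaelis–Menten or threshold kinetics; first-order decay only.
- No fugacity or activity-coefficient corrections.
- ΔG_r⁰ temperature dependence neglected.
- The Sechenov correction's constant sources carry ~10–15% spread for CO;
  the shipped values are compilation means and the supersaturation folds
  inherit this uncertainty.
- No read-level sequence simulation; abundance structure only.
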