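# tracegas

Marine surface waters are supersaturated in molecular hydrogen (H₂) and
carbon monoxide (CO) relative to the atmosphere, and a small fraction of
the bacterial community can oxidize these trace gases as an energy source.
`tracegas` implements the quantitative chain used to evaluate that process
from raw measurements to ecological conclusions:

1. **Seawater solubility** — the freshwater Henry's law constant with its
   van 't Hoff temperature dependence,
   k_G,0(T) = k′_G,0 · exp[(−Δ_soln H/R)(1/T − 1/298.15)],
   corrected for salting-out with the Sechenov mixed-electrolyte relation
   log₁₀(k_G,0/k_G) = Σᵢ (hᵢ + h_G)cᵢ, where h_G = h_G,0 + h_T(T − 298.15).
   Equilibrium dissolved concentrations and supersaturation folds follow
   directly.
2. **Closed-vial gas exchange** — ideal-gas headspace + Henry-law liquid
   mass balance for sealed microcosms, including inversion of the
   N₂-headspace extraction used to measure in situ dissolved gases.
3. **Consumption kinetics** — exponential C(t) = C₀e^(−kt) and linear decay
   fits to headspace time series, model selection by AIC, a replicate QC
   rule (confident consumption needs ≥ 2 replicates with a positive rate
   constant), and conversion of k to bulk oxidation rates
   (mol L⁻¹ seawater s⁻¹) at a reference mixing ratio.
4. **Thermodynamic power** — ΔG_r = ΔG_r⁰ + RT ln Q_r with
   Q_r = Π a_i^{n_i}; per-cell power P = |v·ΔG_r|/B; the cell abundance a
   rate can sustain at a maintenance power m is |v·ΔG_r|/m (default
   m = 1.9 × 10⁻¹⁵ W per cell), with regime labels against literature
   maintenance/growth medians.
5. **Marker-gene abundance** — tiered identity/length filtering of
   alignment hit tables, RPKM, normalization to "average gene copies per
   organism" against 14 universal single-copy markers, RNA:DNA expression
   ratios, and regression of oxidation rates on oxidizer abundance.
6. **Synthetic data** — generators that emulate the study design
   (triplicate live + autoclaved microcosms, lognormal gas-chromatograph
   noise, hit tables with known oxidizer fractions, coupled
   abundance–rate surveys), so every stage is testable without downloads.

It is written for biogeochemists and microbial ecologists analysing
headspace gas-chromatography incubations alongside metagenomic marker-gene
surveys.

## Worked example

Supersaturation of surface seawater at 20 °C, 1 atm, mean seawater:

```python
>>> import tracegas as tg
>>> h2 = tg.get_gas("H2")
>>> tg.equilibrium_concentration(h2, tg.atmospheric_ppmv("H2"))
0.36696...   # nM dissolved H2 in equilibrium with 0.53 ppmv air
>>> tg.saturation_fold(2.0, h2)
5.450...     # a 2.0 nM field measurement is ~5.5x supersaturated
```

The same from the command line, plus the kinetics → power chain:

```bash
$ tracegas saturation --gas H2 --measured-nm 2.0
saturation fold = 5.45
$ tracegas simulate microcosm --seed 5 --n-samples 2 --out series.csv
$ tracegas fit --input series.csv --out fits.tsv
$ tracegas rates --input series.csv --reference-ppmv 0.53 --out rates.tsv
$ tracegas power --gas H2 --rate 1e-12 --cells 1e6 --donor-nm 2.0
Q_r = 3.2577e+10
dG_r = -204.1 kJ/mol
power per cell = 2.041e-13 W (growth-range)
supported cells = 1.074e+08 per litre
```

The numbered drivers under `analysis/` run the full chain on synthetic
surveys and write tables under `results/`:

```bash
$ python analysis/01_supersaturation.py
            site gas  atm_ppmv  equilibrium_nM  measured_nM  saturation_fold
oceanic transect  H2      0.53          0.3670         2.00             5.45
   temperate bay  H2      0.53          0.3670         1.80             4.91
 tropical island  H2      0.53          0.3670         4.60            12.54
oceanic transect  CO      0.09          0.0802         0.36             4.49
   temperate bay  CO      0.09          0.0802         8.50           105.94
 tropical island  CO      0.09          0.0802         8.20           102.20
```

`02_microcosm_kinetics.py` fits a simulated 14-sample survey (AIC picks the
exponential model for 100% of live replicates; median rate-constant error
1.5%), `03_thermo_power.py` converts the confident rates to per-cell power
and regime labels, and `04_gene_abundance.py` filters synthetic hit tables
and recovers a programmed abundance–rate R² of 0.88 (observed 0.90).

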