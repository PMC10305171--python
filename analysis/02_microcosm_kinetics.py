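#!/usr/bin/env python
"""Microcosm consumption kinetics on a synthetic 14-sample survey.

Simulates triplicate live + autoclaved microcosms for 14 samples with known
first-order rate constants, fits exponential and linear decay models to
every replicate, selects by AIC, applies the replicate QC rule and converts
confident samples to bulk oxidation rates at the atmospheric H2 mixing
ratio. Writes results/kinetic_fits.tsv and results/sample_rates.tsv.
"""
from pathlib import Path

import pandas as pd

import tracegas as tg
from tracegas.kinetics import analyse_sample, fit_replicate, fits_to_frame

SEED = 20190723


def main() -> None:
    spec = tg.ScenarioSpec(n_samples=14, seed=SEED)
    series, truth = tg.simulate_microcosm(spec)

    pairs = [(s, fit_replicate(s)) for s in series]
    fits = fits_to_frame(pairs)

    rates = []
    for sample_id, grp in truth[truth.treatment == "live"].groupby("sample_id"):
        live = [s for s in series if s.sample_id == sample_id and s.treatment == "live"]
        sr = analyse_sample(live, reference_ppmv=tg.atmospheric_ppmv("H2"))
        rates.append(
            {
                "sample_id": sample_id,
                "gas": sr.gas,
                "true_k_per_h": grp["true_k"].iloc[0],
                "k_mean_per_h": sr.k_mean,
                "confident": sr.confident,
                "bulk_rate_mol_L_s": sr.bulk_rate,
                "reference_ppmv": sr.reference_ppmv,
            }
        )
    rates = pd.DataFrame(rates)

    out_dir = Path(__file__).resolve().parents[1] / "results"
    out_dir.mkdir(exist_ok=True)
    fits.to_csv(out_dir / "kinetic_fits.tsv", sep="\t", index=False)
    rates.to_csv(out_dir / "sample_rates.tsv", sep="\t", index=False)

    live_fits = fits[fits.treatment == "live"]
    frac_exp = (live_fits.model == "exponential").mean()
    rel_err = (
        (rates.k_mean_per_h - rates.true_k_per_h).abs() / rates.true_k_per_h
    ).median()
    print(rates.to_string(index=False))
    print(
        f"\nAIC preferred the exponential model for {frac_exp:.0%} of live "
        f"replicates; median |k_hat - k|/k = {rel_err:.1%}; "
        f"{int(rates.confident.sum())}/14 samples confident."
    )
    print(f"wrote {out_dir / 'kinetic_fits.tsv'} and {out_dir / 'sample_rates.tsv'}")


if __name__ == "__main__":
    main()
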