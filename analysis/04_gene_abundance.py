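#!/usr/bin/env python
"""Marker-gene abundances and their coupling to oxidation rates.

Simulates alignment hit tables and single-copy marker RPKMs with known
oxidizer fractions, applies the tiered identity/length filters, normalizes
to copies per organism, and regresses bulk rates on abundances in a
coupled survey programmed at R^2 = 0.88.
Writes results/abundance.tsv and results/abundance_rate_regression.tsv.
"""
from pathlib import Path

import pandas as pd

import tracegas as tg
from tracegas.abundance import abundance_table, filter_hits

SEED = 20190723


def main() -> None:
    root = Path(__file__).resolve().parents[1]
    out_dir = root / "results"
    out_dir.mkdir(exist_ok=True)

    spec = tg.ScenarioSpec(n_samples=14, seed=SEED)
    hits, markers, truth = tg.simulate_hit_table(
        spec, genes={"NiFe-1d": 0.01, "CoxL": 0.12}, marker_cv=0.1
    )
    kept, report = filter_hits(hits)
    gene_rpkm = truth.pivot(index="sample_id", columns="gene_family", values="rpkm")
    table = abundance_table(gene_rpkm, markers)
    table.to_csv(out_dir / "abundance.tsv", sep="\t")

    survey = tg.simulate_coupled_survey(spec, target_r2=0.88)
    reg = tg.correlate_abundance_rate(survey["abundance"], survey["rate"])
    pd.DataFrame([reg.__dict__]).to_csv(
        out_dir / "abundance_rate_regression.tsv", sep="\t", index=False
    )

    print(table.round(4).to_string())
    print(
        f"\nHit filtering removed {report['identity']} of {len(hits)} rows below "
        f"the identity tiers (none by length)."
    )
    print(
        f"Oxidizer abundance predicts bulk rate: R^2 = {reg.r2:.2f}, "
        f"p = {reg.p_value:.2e} (n = {reg.n}; programmed R^2 0.88)."
    )
    print(f"wrote {out_dir / 'abundance.tsv'} and {out_dir / 'abundance_rate_regression.tsv'}")


if __name__ == "__main__":
    main()
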