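"""Hit filtering, RPKM normalization and abundance-rate regression."""
import math

import numpy as np
import pandas as pd
import pytest

from tracegas.abundance import (
    RegressionResult,
    ThresholdConfig,
    abundance_table,
    copies_per_organism,
    correlate_abundance_rate,
    expression_ratio,
    expression_ratio_table,
    filter_hits,
    rpkm,
    sum_marker_set,
)
from tracegas.exceptions import ValidationError


def _toy_hits():
    rows = [
        ("r1", "CoxL", 59.0), ("r2", "CoxL", 61.0),
        ("r3", "NiFe-1d", 49.0), ("r4", "NiFe-1d", 51.0),
        ("r5", "PsaA", 79.0), ("r6", "PsaA", 81.0),
    ]
    return pd.DataFrame(
        [
            {
                "read_id": rid,
                "gene_family": gene,
                "percent_identity": pid,
                "alignment_length_aa": 45,
                "sample_id": "S01",
                "dataset": "metagenome",
            }
            for rid, gene, pid in rows
        ]
    )


class TestFilterHits:
    def test_tiered_identity_thresholds_on_toy_table(self):
        kept, report = filter_hits(_toy_hits())
        # CoxL tier 60, PsaA tier 80, NiFe-1d falls back to tier 50
        assert sorted(kept["read_id"]) == ["r2", "r4", "r6"]
        assert report == {"length": 0, "identity": 3}

    def test_empty_table_passes_through(self):
        kept, report = filter_hits(_toy_hits().iloc[0:0])
        assert kept.empty and report == {"length": 0, "identity": 0}

    def test_thresholds_are_inclusive(self):
        hits = _toy_hits().iloc[:1].assign(percent_identity=60.0)
        kept, _ = filter_hits(hits)
        assert len(kept) == 1

    def test_short_alignments_removed(self):
        hits = _toy_hits().assign(alignment_length_aa=[45, 30, 45, 30, 45, 30])
        kept, report = filter_hits(hits)
        assert report["length"] == 3

    def test_idempotent(self):
        kept, _ = filter_hits(_toy_hits())
        again, report = filter_hits(kept)
        pd.testing.assert_frame_equal(kept, again)
        assert report == {"length": 0, "identity": 0}

    def test_fallback_can_be_disabled(self):
        cfg = ThresholdConfig(allow_fallback=False)
        with pytest.raises(ValidationError, match="NiFe-1d"):
            filter_hits(_toy_hits(), cfg)

    def test_protein_mode_uses_coverage_and_overrides(self):
        hits = pd.DataFrame(
            {
                "read_id": ["p1", "p2"],
                "gene_family": ["PsbA", "PsbA"],
                "percent_identity": [65.0, 65.0],  # protein-mode PsbA tier is 60
                "query_coverage": [85.0, 10.0],
                "subject_coverage": [10.0, 20.0],
            }
        )
        kept, _ = filter_hits(hits, ThresholdConfig(mode="proteins"))
        assert list(kept["read_id"]) == ["p1"]


class TestRpkm:
    def test_zero_reads_zero(self):
        assert rpkm(0, 1000, 1e6) == 0.0

    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 1000, 1e6, 100.0), (250, 2500, 5e7, 2.0)],
    )
    def test_definitional_values(self, count, length, lib, expected):
        assert rpkm(count, length, lib) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rpkm(10, 0, 1e6)
        with pytest.raises(ValidationError):
            rpkm(10, 1000, 0)


class TestCopiesPerOrganism:
    def test_gene_equal_to_markers_gives_unity(self):
        assert copies_per_organism(50.0, [50.0] * 14) == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        assert copies_per_organism(5.0, [50.0] * 14) == pytest.approx(0.10)

    def test_absent_gene_is_zero(self):
        assert copies_per_organism(0.0, [50.0] * 14) == 0.0

    def test_zero_marker_mean_flagged_undefined(self):
        assert math.isnan(copies_per_organism(5.0, [0.0] * 14))

    def test_scale_invariance(self, rng):
        markers = rng.uniform(10, 100, 14)
        base = copies_per_organism(7.0, markers)
        assert copies_per_organism(7.0 * 3.7, markers * 3.7) == pytest.approx(base, rel=1e-12)

    def test_table_variant_matches_scalar(self):
        genes = pd.DataFrame({"CoxL": [5.0, 10.0]}, index=["S01", "S02"])
        markers = pd.DataFrame(np.full((2, 14), 50.0), index=["S01", "S02"])
        table = abundance_table(genes, markers)
        assert table.loc["S01", "CoxL"] == pytest.approx(0.10)
        assert table.loc["S02", "CoxL"] == pytest.approx(0.20)


class TestSumMarkerSet:
    def test_singleton_group_unchanged(self):
        assert sum_marker_set({"NiFe-1d": 0.02}, ["NiFe-1d"]) == 0.02

    def test_uptake_hydrogenase_group_sum(self):
        vals = {"NiFe-1d": 0.02, "NiFe-1l": 0.005, "NiFe-2a": 0.01}
        assert sum_marker_set(vals, ["NiFe-1d", "NiFe-1l", "NiFe-2a"]) == pytest.approx(0.035)

    def test_empty_group_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert sum_marker_set({"a": 1.0}, []) == 0.0

    def test_sum_commutes_with_normalization(self):
        # sum of ratios equals ratio of sums given the shared marker mean
        markers = [50.0] * 14
        parts = [copies_per_organism(g, markers) for g in (1.0, 2.0, 3.0)]
        assert sum(parts) == pytest.approx(copies_per_organism(6.0, markers), rel=1e-12)


class TestExpressionRatio:
    def test_equal_abundance_gives_unity(self):
        assert expression_ratio(3.3, 3.3) == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        assert expression_ratio(25.8, 2.0) == pytest.approx(12.9)

    def test_silent_gene_is_zero(self):
        assert expression_ratio(0.0, 2.0) == 0.0

    def test_zero_metagenome_rejected(self):
        with pytest.raises(ValidationError):
            expression_ratio(5.0, 0.0)

    def test_table_averages_replicates_before_division(self):
        mt = pd.DataFrame(
            {"sample_id": ["S01", "S01"], "gene": ["CoxL", "CoxL"], "rpkm": [20.0, 30.0]}
        )
        mg = pd.DataFrame({"sample_id": ["S01"], "gene": ["CoxL"], "rpkm": [2.0]})
        out = expression_ratio_table(mt, mg)
        assert out.loc[0, "rna_dna_ratio"] == pytest.approx(12.5)

    def test_table_flags_zero_metagenome_as_nan(self):
        mt = pd.DataFrame({"sample_id": ["S01"], "gene": ["CoxL"], "rpkm": [5.0]})
        mg = pd.DataFrame({"sample_id": ["S01"], "gene": ["CoxL"], "rpkm": [0.0]})
        assert math.isnan(expression_ratio_table(mt, mg).loc[0, "rna_dna_ratio"])


class TestCorrelateAbundanceRate:
    def test_collinear_pairs_give_r2_one(self):
        x = [0.01, 0.02, 0.05, 0.1]
        y = [2e-12 * v for v in x]
        res = correlate_abundance_rate(x, y)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_shuffled_pairs_lose_the_signal(self, rng):
        x = np.linspace(0.01, 0.1, 40)
        y = 2e-12 * x
        res = correlate_abundance_rate(x, rng.permutation(y))
        assert res.r2 < 0.3

    def test_noise_calibrated_r2_recovery(self, rng):
        """sigma chosen for an expected R^2 of 0.6 recovers it on average."""
        r2s = []
        for _ in range(300):
            x = rng.lognormal(math.log(0.02), 0.7, 14)
            signal = 1e-10 * x
            sigma = math.sqrt(np.var(signal) * (1 - 0.6) / 0.6)
            y = signal + rng.normal(0, sigma, x.size)
            r2s.append(correlate_abundance_rate(x, y).r2)
        assert np.mean(r2s) == pytest.approx(0.6, abs=0.08)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate_abundance_rate([1, 2], [1, 2])

    def test_constant_predictor_flagged(self):
        with pytest.warns(UserWarning):
            res = correlate_abundance_rate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.r2)
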