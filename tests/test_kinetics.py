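"""Decay-model fitting, AIC selection, replicate QC and rate conversion."""
import math

import numpy as np
import pytest

import tracegas as tg
from tracegas.exceptions import FitError, ValidationError
from tracegas.kinetics import (
    KineticFit,
    MicrocosmSeries,
    bulk_oxidation_rate,
    cell_specific_rate,
    fit_exponential,
    fit_linear,
    in_situ_rate,
    qc_sample,
    select_model,
)


def _series(times, ppmv, vial, sample="S01", rep="R1", treatment="live", gas="H2"):
    return MicrocosmSeries(sample, rep, treatment, gas, np.asarray(times, float),
                           np.asarray(ppmv, float), vial)


class TestFitExponential:
    def test_noiseless_series_recovered_exactly(self, munida_vial):
        t = np.arange(8) * 24.0
        s = _series(t, 2.0 * np.exp(-0.05 * t), munida_vial)
        fit = fit_exponential(s)
        assert fit.converged
        assert fit.k == pytest.approx(0.05, abs=1e-6)
        assert fit.c0 == pytest.approx(2.0, abs=1e-6)
        assert fit.rss < 1e-12
        assert math.isfinite(fit.aic)  # rss floor keeps the AIC finite

    def test_noisy_recovery_unbiased_over_seeds(self, munida_vial, rng):
        errors = []
        t = np.arange(8) * 24.0
        for _ in range(200):
            noisy = 2.0 * np.exp(-0.03 * t) * rng.lognormal(0.0, 0.05, t.size)
            k = fit_exponential(_series(t, noisy, munida_vial)).k
            errors.append(abs(k - 0.03) / 0.03)
        assert np.median(errors) < 0.10

    def test_flat_series_yields_rate_near_zero(self, munida_vial, rng):
        t = np.arange(10) * 24.0
        flat = 2.0 * rng.lognormal(0.0, 0.05, t.size)
        fit = fit_exponential(_series(t, flat, munida_vial))
        # not significantly different from zero
        assert abs(fit.k) < 3 * fit.k_se

    def test_too_few_points_rejected(self, munida_vial):
        with pytest.raises(ValidationError):
            fit_exponential(_series([0.0, 24.0], [2.0, 1.8], munida_vial))

    def test_all_zero_series_is_degenerate(self, munida_vial):
        with pytest.raises(ValidationError):
            fit_exponential(_series([0, 24, 48], [0, 0, 0], munida_vial))


class TestFitLinearAndSelection:
    def test_perfectly_linear_decay_exact(self, munida_vial):
        t = np.arange(6) * 24.0
        fit = fit_linear(_series(t, 2.0 - 0.004 * t, munida_vial))
        assert fit.k == pytest.approx(0.004, rel=1e-10)  # k = -slope
        assert fit.rss < 1e-18

    def test_exponential_data_prefers_exponential_model(self, munida_vial):
        t = np.arange(8) * 24.0
        s = _series(t, 2.0 * np.exp(-0.05 * t), munida_vial)
        exp_fit, lin_fit = fit_exponential(s), fit_linear(s)
        assert lin_fit.rss > exp_fit.rss
        assert select_model(exp_fit, lin_fit).model == "exponential"

    def test_linear_data_prefers_linear_model(self, munida_vial, rng):
        t = np.arange(8) * 24.0
        chosen = []
        for _ in range(50):
            noisy = (2.0 - 0.004 * t) + rng.normal(0.0, 0.01, t.size)
            s = _series(t, np.clip(noisy, 0, None), munida_vial)
            chosen.append(select_model(fit_exponential(s), fit_linear(s)).model)
        assert chosen.count("linear") > 25

    def test_aic_tie_resolves_to_exponential(self):
        e = KineticFit("exponential", 0.01, 2.0, 1e-4, 8, -50.0, True)
        l = KineticFit("linear", 0.01, 2.0, 1e-4, 8, -50.0, True)
        assert select_model(e, l).model == "exponential"

    def test_selection_requires_a_converged_fit(self):
        bad = KineticFit("exponential", math.nan, math.nan, math.nan, 8, math.nan, False)
        with pytest.raises(FitError):
            select_model(bad, bad)


class TestQC:
    @staticmethod
    def _fit(k):
        return KineticFit("exponential", k, 2.0, 1e-4, 8, -50.0, True, k_se=None)

    def test_two_positive_replicates_confident(self):
        qc = qc_sample([self._fit(0.03), self._fit(0.04), self._fit(-0.01)])
        assert qc.confident
        assert qc.k_mean == pytest.approx(0.035)  # mean over positive replicates only

    def test_single_positive_replicate_not_confident(self):
        assert not qc_sample([self._fit(0.03), self._fit(-0.01), self._fit(-0.02)]).confident

    def test_empty_replicate_list_not_confident(self):
        qc = qc_sample([])
        assert not qc.confident and qc.k_mean is None

    def test_insignificant_positive_rate_does_not_count(self):
        shaky = KineticFit("exponential", 0.001, 2.0, 1e-2, 8, -20.0, True, k_se=0.01)
        solid = KineticFit("exponential", 0.05, 2.0, 1e-4, 8, -50.0, True, k_se=0.001)
        assert not qc_sample([shaky, shaky, solid]).confident
        assert qc_sample([solid, solid, shaky]).confident


class TestRates:
    def test_zero_rate_constant_gives_zero_rate(self, h2, munida_vial):
        assert bulk_oxidation_rate(0.0, h2, munida_vial, 0.53) == 0.0

    def test_mass_balance_hand_oracle(self, h2, munida_vial):
        # v = k * (n_headspace + n_dissolved) / (V_liquid * 3600)
        inv = tg.vial_inventory(0.53, h2, munida_vial)
        expected = 0.05 * (inv.moles_headspace + inv.moles_dissolved) / (0.060 * 3600.0)
        assert bulk_oxidation_rate(0.05, h2, munida_vial, 0.53) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rate_linear_in_reference_mixing_ratio(self, h2, munida_vial):
        v1 = bulk_oxidation_rate(0.05, h2, munida_vial, 0.53)
        v2 = bulk_oxidation_rate(0.05, h2, munida_vial, 1.06)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_dissolved_inventory_smaller_than_total(self, h2, munida_vial):
        total = bulk_oxidation_rate(0.05, h2, munida_vial, 0.53, inventory="total")
        dissolved = bulk_oxidation_rate(0.05, h2, munida_vial, 0.53, inventory="dissolved")
        assert 0 < dissolved < total

    def test_unit_conversion_invariance(self, h2, munida_vial):
        # k expressed per day, converted to per hour, must give the same rate
        k_per_day = 1.2
        assert bulk_oxidation_rate(k_per_day / 24.0, h2, munida_vial, 0.53) == pytest.approx(
            bulk_oxidation_rate(0.05, h2, munida_vial, 0.53), rel=1e-12
        )

    def test_in_situ_variant_uses_dissolved_pool_only(self):
        assert in_situ_rate(0.05, 2.0) == pytest.approx(0.05 * 2e-9 / 3600.0, rel=1e-12)

    def test_negative_rate_constant_rejected(self, h2, munida_vial):
        with pytest.raises(ValidationError):
            bulk_oxidation_rate(-0.01, h2, munida_vial, 0.53)


class TestCellSpecificRate:
    def test_identity_when_fraction_one_cell_one(self):
        rate, b = cell_specific_rate(1e-12, 1.0, 1.0)
        assert rate == 1e-12 and b == 1.0

    def test_halving_fraction_doubles_per_cell_rate(self):
        full, _ = cell_specific_rate(1e-12, 1e9, 0.02)
        half, _ = cell_specific_rate(1e-12, 1e9, 0.01)
        assert half == pytest.approx(2 * full, rel=1e-12)

    def test_arithmetic_oracle(self):
        rate, b = cell_specific_rate(1e-12, 1e9, 0.01)
        assert b == pytest.approx(1e7)
        assert rate == pytest.approx(1e-19, rel=1e-12)

    def test_zero_oxidizers_rejected(self):
        with pytest.raises(ValidationError):
            cell_specific_rate(1e-12, 1e9, 0.0)
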