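"""Microcosm gas-consumption kinetics.

Headspace mixing-ratio time series from sealed, agitated microcosms are
fitted with a first-order (exponential) and a zero-order (linear) decay
model; the model with the lower Akaike information criterion is kept. A
sample is deemed to show confident consumption when at least two replicates
carry a positive rate constant (by default, positive and statistically
distinguishable from zero; see :func:`qc_sample`). Rate constants are then
converted to bulk oxidation rates per litre of seawater at a stated
reference mixing ratio via the vial mass balance, and to cell-specific
rates with cell counts and oxidizer fractions.

AIC convention for least-squares fits: ``n * ln(rss / n) + 2p`` with
``p = 2`` parameters for both models; ``rss`` floored at 1e-12 so noiseless
synthetic series do not produce ``-inf``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import GasSpecies, get_gas
from .exceptions import FitError, ValidationError
from .exchange import VialConfig, get_vial, vial_inventory

_RSS_FLOOR = 1e-12
_N_PARAMS = 2  # both models fit (c0, k)


@dataclass(frozen=True)
class MicrocosmSeries:
    """One replicate time series of headspace mixing ratios in a vial."""

    sample_id: str
    replicate_id: str
    treatment: str  # "live" | "autoclaved"
    gas: str
    times: np.ndarray  # hours
    mixing_ratios: np.ndarray  # ppmv
    vial: VialConfig

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ratios = np.asarray(self.mixing_ratios, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mixing_ratios", ratios)
        if times.shape != ratios.shape:
            raise ValidationError("times and mixing_ratios must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(ratios < 0):
            raise ValidationError("mixing_ratios must be >= 0 ppmv")

    def truncated(self, max_hours: float) -> "MicrocosmSeries":
        """Restrict the series to timepoints at or before ``max_hours``."""
        keep = self.times <= max_hours
        return MicrocosmSeries(
            self.sample_id,
            self.replicate_id,
            self.treatment,
            self.gas,
            self.times[keep],
            self.mixing_ratios[keep],
            self.vial,
        )


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one decay model to one replicate series.

    ``k`` is the consumption rate under either model: the first-order rate
    constant (h^-1) for the exponential model, or minus the OLS slope
    (ppmv h^-1) for the linear model, so that ``k > 0`` always means net
    consumption.
    """

    model: str  # "exponential" | "linear"
    k: float
    c0: float
    rss: float
    n: int
    aic: float
    converged: bool
    k_se: float | None = None


@dataclass(frozen=True)
class QCResult:
    """Replicate-level quality control of a sample's consumption signal."""

    confident: bool
    k_mean: float | None  # mean k over positive replicates (h^-1)
    n_positive: int
    n_replicates: int


@dataclass(frozen=True)
class SampleRate:
    """Per-sample consumption summary at a stated reference mixing ratio."""

    sample_id: str
    gas: str
    k_mean: float | None  # h^-1
    confident: bool
    bulk_rate: float | None  # mol L^-1 s^-1
    reference_ppmv: float


def _aic(rss: float, n: int) -> float:
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * _N_PARAMS


def _check_series(series: MicrocosmSeries) -> None:
    if series.times.size < 3:
        raise ValidationError("at least 3 timepoints are required for fitting")
    if np.all(series.mixing_ratios == 0):
        raise ValidationError("all-zero series: nothing to fit")


def fit_exponential(series: MicrocosmSeries) -> KineticFit:
    """Least-squares fit of ``C(t) = c0 * exp(-k t)``.

    The nonlinear fit is initialised from a log-linear regression over the
    positive observations.
    """
    _check_series(series)
    t = series.times
    c = series.mixing_ratios

    positive = c > 0
    if positive.sum() >= 2:
        slope, intercept = np.polyfit(t[positive], np.log(c[positive]), 1)
        p0 = (math.exp(intercept), -slope)
    else:
        p0 = (max(c.max(), 1e-6), 0.01)

    def model(tt: np.ndarray, c0: float, k: float) -> np.ndarray:
        return c0 * np.exp(-k * tt)

    try:
        popt, pcov = optimize.curve_fit(model, t, c, p0=p0, maxfev=10000)
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, optimize.OptimizeWarning):
        return KineticFit("exponential", math.nan, math.nan, math.nan,
                          int(t.size), math.nan, False)
    c0, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((c - model(t, c0, k)) ** 2))
    k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else None
    return KineticFit("exponential", k, c0, rss, int(t.size), _aic(rss, t.size),
                      bool(converged), k_se)


def fit_linear(series: MicrocosmSeries) -> KineticFit:
    """Ordinary least squares fit of ``C(t) = c0 + b t``; stores ``k = -b``."""
    _check_series(series)
    t = series.times
    c = series.mixing_ratios
    res = stats.linregress(t, c)
    predicted = res.intercept + res.slope * t
    rss = float(np.sum((c - predicted) ** 2))
    return KineticFit(
        "linear",
        k=-float(res.slope),
        c0=float(res.intercept),
        rss=rss,
        n=int(t.size),
        aic=_aic(rss, t.size),
        converged=True,
        k_se=float(res.stderr) if np.isfinite(res.stderr) else None,
    )


def select_model(exp_fit: KineticFit, lin_fit: KineticFit) -> KineticFit:
    """Return the fit with the lower AIC; ties resolve to the exponential."""
    if not exp_fit.converged and not lin_fit.converged:
        raise FitError("neither model converged; cannot select")
    if not exp_fit.converged:
        return lin_fit
    if not lin_fit.converged:
        return exp_fit
    if lin_fit.aic < exp_fit.aic - 1e-9:
        return lin_fit
    return exp_fit


def _is_positive(fit: KineticFit, alpha: float) -> bool:
    """A replicate counts as positive when its k is positive and, where a
    standard error is available, one-sided significantly greater than zero."""
    if not fit.converged or not np.isfinite(fit.k) or fit.k <= 0:
        return False
    if fit.k_se is None or fit.k_se == 0 or not np.isfinite(fit.k_se):
        return True
    df = max(fit.n - _N_PARAMS, 1)
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return fit.k / fit.k_se > t_crit


def qc_sample(fits: Sequence[KineticFit], alpha: float = 0.05) -> QCResult:
    """Apply the replicate QC rule: confident iff >= 2 positive replicates.

    ``k_mean`` averages only the positive replicates (negative rate
    constants would bias consumption rates downward). Fits carrying a
    standard error must also pass a one-sided t-test at ``alpha``; fits
    without one are judged on sign alone.
    """
    positive = [f for f in fits if _is_positive(f, alpha)]
    confident = len(positive) >= 2
    k_mean = float(np.mean([f.k for f in positive])) if positive else None
    return QCResult(confident, k_mean, len(positive), len(fits))


def bulk_oxidation_rate(
    k_per_hour: float,
    gas: GasSpecies,
    vial: VialConfig,
    reference_ppmv: float,
    inventory: str = "total",
) -> float:
    """Bulk consumption rate (mol L^-1 seawater s^-1) at a reference mixing ratio.

    The first-order constant is applied to the vial gas inventory at the
    reference mixing ratio — the full two-phase inventory by default
    (``inventory="total"``), or the dissolved pool only
    (``inventory="dissolved"``) — and expressed per litre of seawater per
    second.
    """
    if k_per_hour < 0:
        raise ValidationError("k must be >= 0 (apply QC before computing rates)")
    inv = vial_inventory(reference_ppmv, gas, vial)
    if inventory == "total":
        moles = inv.total_moles
    elif inventory == "dissolved":
        moles = inv.moles_dissolved
    else:
        raise ValidationError("inventory must be 'total' or 'dissolved'")
    return k_per_hour * moles / vial.v_liquid / 3600.0


def in_situ_rate(k_per_hour: float, dissolved_nm: float) -> float:
    """Consumption rate (mol L^-1 s^-1) at a measured in situ concentration.

    Open-water variant of :func:`bulk_oxidation_rate`: the rate constant
    acts on the dissolved pool alone, with no headspace reservoir.
    """
    if k_per_hour < 0:
        raise ValidationError("k must be >= 0")
    if dissolved_nm < 0:
        raise ValidationError("dissolved concentration must be >= 0 nM")
    return k_per_hour * dissolved_nm * 1e-9 / 3600.0


def cell_specific_rate(
    bulk_rate: float, total_cells: float, oxidizer_fraction: float
) -> tuple[float, float]:
    """Per-cell rate (mol cell^-1 s^-1) and oxidizer abundance B (cells L^-1).

    ``B = total_cells * oxidizer_fraction`` is returned alongside for reuse
    in the power calculation.
    """
    if total_cells <= 0:
        raise ValidationError("total_cells must be positive")
    if not (0.0 < oxidizer_fraction <= 1.0):
        raise ValidationError("oxidizer_fraction must be in (0, 1]")
    b = total_cells * oxidizer_fraction
    if b == 0:
        raise ValidationError("zero oxidizer abundance; check upstream QC")
    return bulk_rate / b, b


def fit_replicate(series: MicrocosmSeries, max_hours: float | None = None) -> KineticFit:
    """Fit both models to one replicate (optionally truncated) and select by AIC."""
    if max_hours is not None:
        series = series.truncated(max_hours)
    return select_model(fit_exponential(series), fit_linear(series))


def analyse_sample(
    replicates: Iterable[MicrocosmSeries],
    reference_ppmv: float,
    max_hours: float | None = None,
    inventory: str = "total",
    alpha: float = 0.05,
) -> SampleRate:
    """Full per-sample pipeline: fit, select, QC and bulk rate."""
    replicates = list(replicates)
    if not replicates:
        raise ValidationError("no replicate series supplied")
    first = replicates[0]
    fits = [fit_replicate(s, max_hours) for s in replicates]
    qc = qc_sample(fits, alpha=alpha)
    bulk = None
    if qc.confident and qc.k_mean is not None:
        gas = get_gas(first.gas)
        bulk = bulk_oxidation_rate(qc.k_mean, gas, first.vial, reference_ppmv, inventory)
    return SampleRate(
        sample_id=first.sample_id,
        gas=first.gas,
        k_mean=qc.k_mean,
        confident=qc.confident,
        bulk_rate=bulk,
        reference_ppmv=reference_ppmv,
    )


def read_microcosm_csv(path, vial: str | VialConfig = "munida") -> list[MicrocosmSeries]:
    """Read a long-format CSV into replicate series.

    Expected columns: ``sample_id, replicate, treatment, gas, time_h, ppmv``.
    """
    frame = pd.read_csv(path)
    required = {"sample_id", "replicate", "treatment", "gas", "time_h", "ppmv"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"input CSV missing columns: {sorted(missing)}")
    vial_cfg = get_vial(vial) if isinstance(vial, str) else vial
    out: list[MicrocosmSeries] = []
    for (sample, rep, treat, gas), grp in frame.groupby(
        ["sample_id", "replicate", "treatment", "gas"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            MicrocosmSeries(
                sample_id=str(sample),
                replicate_id=str(rep),
                treatment=str(treat),
                gas=str(gas),
                times=grp["time_h"].to_numpy(float),
                mixing_ratios=grp["ppmv"].to_numpy(float),
                vial=vial_cfg,
            )
        )
    return out


def fits_to_frame(fits: Iterable[tuple[MicrocosmSeries, KineticFit]]) -> pd.DataFrame:
    """Tabulate (series, fit) pairs for TSV export."""
    rows = []
    for series, fit in fits:
        rows.append(
            {
                "sample_id": series.sample_id,
                "replicate": series.replicate_id,
                "treatment": series.treatment,
                "gas": series.gas,
                "model": fit.model,
                "k": fit.k,
                "k_se": fit.k_se,
                "c0": fit.c0,
                "rss": fit.rss,
                "n": fit.n,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
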