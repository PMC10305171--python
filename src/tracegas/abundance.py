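"""Marker-gene abundance normalization and hit filtering.

Alignment hit tables (reads against metabolic marker protein databases) are
filtered by per-gene minimum percent identity and minimum alignment length;
gene abundances in RPKM are normalized to "average gene copies per
organism" by dividing by the mean RPKM of a set of universal single-copy
ribosomal marker genes; metatranscriptome/metagenome RPKM ratios give
RNA:DNA expression ratios; and per-sample abundances are regressed against
bulk oxidation rates.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

#: Per-gene minimum percent identity for short-read hits. Genes absent from
#: the table fall back to the 50% tier.
DEFAULT_IDENTITY_TIERS: dict[str, float] = {
    "PsaA": 80.0,
    "HbsT": 75.0,
    "PsbA": 70.0,
    "IsoA": 70.0,
    "AtpA": 70.0,
    "YgfK": 70.0,
    "ARO": 70.0,
    "CoxL": 60.0,
    "MmoA": 60.0,
    "AmoA": 60.0,
    "NxrA": 60.0,
    "RbcL": 60.0,
    "NuoF": 60.0,
    "FeFe": 60.0,
    "NiFe-group4": 60.0,
}

#: Overrides applied in "proteins" mode (predicted proteins from assemblies).
PROTEIN_MODE_OVERRIDES: dict[str, float] = {
    "AtpA": 60.0,
    "PsbA": 60.0,
    "RdhA": 45.0,
    "Cyc2": 35.0,
    "RHO": 30.0,
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Hit-filtering thresholds.

    ``mode="reads"`` filters by minimum alignment length in amino acids
    (40 aa for 150 bp reads; use 32 for 100 bp reads); ``mode="proteins"``
    instead requires ``min_coverage`` percent query-or-subject coverage and
    applies the protein-mode identity overrides.
    """

    identity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_TIERS)
    )
    default_identity: float = 50.0
    min_alignment_aa: float = 40.0
    mode: str = "reads"
    min_coverage: float = 80.0
    allow_fallback: bool = True

    def identity_threshold(self, gene: str) -> float:
        table = dict(self.identity)
        if self.mode == "proteins":
            table.update(PROTEIN_MODE_OVERRIDES)
        if gene in table:
            return table[gene]
        if not self.allow_fallback:
            raise ValidationError(
                f"gene family {gene!r} has no identity threshold and fallback is disabled"
            )
        return self.default_identity


def filter_hits(
    hits: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply length/coverage and per-gene identity filters to a hit table.

    Expects columns ``gene_family``, ``percent_identity`` and, in reads
    mode, ``alignment_length_aa`` (in proteins mode, ``query_coverage`` and
    ``subject_coverage``). Thresholds are inclusive (a hit exactly at the
    threshold is retained). Returns the surviving rows and a report of how
    many rows each rule removed.
    """
    cfg = cfg or ThresholdConfig()
    if hits.empty:
        return hits.copy(), {"length": 0, "identity": 0}

    if cfg.mode == "reads":
        pass_length = hits["alignment_length_aa"] >= cfg.min_alignment_aa
    elif cfg.mode == "proteins":
        pass_length = (hits["query_coverage"] >= cfg.min_coverage) | (
            hits["subject_coverage"] >= cfg.min_coverage
        )
    else:
        raise ValidationError("mode must be 'reads' or 'proteins'")

    thresholds = hits["gene_family"].map(cfg.identity_threshold)
    pass_identity = hits["percent_identity"] >= thresholds

    report = {
        "length": int((~pass_length).sum()),
        "identity": int((pass_length & ~pass_identity).sum()),
    }
    return hits.loc[pass_length & pass_identity].copy(), report


def rpkm(read_count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValidationError("gene_length_bp must be positive")
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    return read_count / (gene_length_bp / 1e3) / (library_size / 1e6)


def copies_per_organism(gene_rpkm: float, marker_rpkms: Sequence[float]) -> float:
    """Average gene copies per organism: gene RPKM over mean marker RPKM.

    For a single-copy gene this approximates the fraction of community
    members encoding it. Returns NaN (flagged undefined, not zero) when the
    marker mean is zero.
    """
    marker_rpkms = np.asarray(list(marker_rpkms), dtype=float)
    if marker_rpkms.size == 0:
        raise ValidationError("marker_rpkms must be nonempty")
    mean_marker = marker_rpkms.mean()
    if mean_marker == 0:
        return math.nan
    return gene_rpkm / mean_marker


def abundance_table(
    gene_rpkm: pd.DataFrame, marker_rpkm: pd.DataFrame
) -> pd.DataFrame:
    """Copies-per-organism for a samples x genes RPKM table.

    Both inputs are indexed by sample; ``marker_rpkm`` columns are the
    single-copy marker genes. Samples whose marker mean is zero come back
    as NaN.
    """
    marker_mean = marker_rpkm.mean(axis=1)
    out = gene_rpkm.div(marker_mean, axis=0)
    out[marker_mean == 0] = math.nan
    return out


def sum_marker_set(
    abundances: Mapping[str, float] | pd.Series, group: Iterable[str]
) -> float:
    """Sum abundances across the genes of a named functional group.

    Genes missing from ``abundances`` are warned about and treated as
    absent; an empty group sums to 0 with a warning.
    """
    group = list(group)
    if not group:
        warnings.warn("empty marker group; returning 0", stacklevel=2)
        return 0.0
    total = 0.0
    for gene in group:
        if gene in abundances:
            total += float(abundances[gene])
        else:
            warnings.warn(f"gene {gene!r} absent from abundances", stacklevel=2)
    return total


def expression_ratio(mt_rpkm: float, mg_rpkm: float) -> float:
    """RNA:DNA ratio — metatranscriptome RPKM over metagenome RPKM."""
    if mg_rpkm <= 0:
        raise ValidationError("metagenome RPKM must be positive for an RNA:DNA ratio")
    return mt_rpkm / mg_rpkm


def expression_ratio_table(
    mt: pd.DataFrame, mg: pd.DataFrame, sample_col: str = "sample_id"
) -> pd.DataFrame:
    """Per-sample RNA:DNA ratios with replicate averaging.

    Both inputs are long tables with ``sample_col``, ``gene`` and ``rpkm``
    columns; replicate rows are averaged by sample before division. Samples
    with zero metagenome abundance for a gene are excluded (NaN) rather
    than returned as zero.
    """
    mt_avg = mt.groupby([sample_col, "gene"])["rpkm"].mean().rename("mt")
    mg_avg = mg.groupby([sample_col, "gene"])["rpkm"].mean().rename("mg")
    joined = pd.concat([mt_avg, mg_avg], axis=1, join="inner").reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        joined["rna_dna_ratio"] = np.where(
            joined["mg"] > 0, joined["mt"] / joined["mg"], math.nan
        )
    return joined


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary for abundance vs rate."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def correlate_abundance_rate(
    abundances: Sequence[float], rates: Sequence[float]
) -> RegressionResult:
    """Regress bulk oxidation rates on oxidizer abundances across samples.

    Returns the coefficient of determination and the two-sided p-value of
    the slope. Requires >= 3 paired samples; a constant predictor gives an
    undefined (NaN) R^2 with a warning.
    """
    x = np.asarray(list(abundances), dtype=float)
    y = np.asarray(list(rates), dtype=float)
    if x.size != y.size:
        raise ValidationError("abundances and rates must be paired")
    if x.size < 3:
        raise ValidationError("at least 3 paired samples are required")
    if np.ptp(x) == 0:
        warnings.warn("constant predictor; R^2 undefined", stacklevel=2)
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
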