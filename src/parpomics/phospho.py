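"""Phosphosite collapse, censoring and median-centering normalization.

Phosphopeptide quantifications (DIA, library-free) are collapsed to site
level by summing the linear intensities of qualifying peptides per site and
sample; peptides below the localization-score cutoff (default 0.75) are
excluded. Downstream analysis is on log2 intensities. Two cleaning steps are
specific to this layer:

* *censoring* — log2 values below 0 are artifacts of the quantification
  software and are set to missing (0 itself is retained);
* *median-centering* — per-sample normalization factors align every sample
  median to the grand mean of the input sample medians, preserving
  within-sample differences exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adpr import SITE_KEY, SiteMatrix

__all__ = [
    "NormalizationReport",
    "collapse_to_sites",
    "censor_log_matrix",
    "median_center",
]


@dataclass(frozen=True)
class NormalizationReport:
    """Per-sample medians and the factors that align them.

    factor_j = grand_mean - median_j, so adding factor_j to sample j moves
    its median onto the grand mean of input medians. Factors sum to zero
    when all samples are weighted equally.
    """

    sample_medians: pd.Series
    grand_mean: float
    factors: pd.Series


class NormalizationError(ValueError):
    pass


def collapse_to_sites(
    peptide_table: pd.DataFrame,
    loc_cutoff: float = 0.75,
) -> SiteMatrix:
    """Collapse phosphopeptide quantifications to site-level values.

    ``peptide_table`` has one row per peptide x sample with columns
    ``protein``, ``position``, ``residue``, ``localization_prob``,
    ``sample``, ``intensity`` (linear). Peptides with localization below the
    cutoff are excluded; per-site per-sample value is the sum of qualifying
    peptide intensities.
    """
    ok = peptide_table.loc[
        (peptide_table["localization_prob"] >= loc_cutoff)
        & peptide_table["intensity"].notna()
    ]
    if ok.empty:
        idx = pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
        return SiteMatrix(
            values=pd.DataFrame(index=idx, dtype=float),
            best_localization=pd.Series(index=idx, dtype=float),
        )
    wide = ok.groupby([*SITE_KEY, "sample"])["intensity"].sum().unstack("sample")
    best = peptide_table.groupby(list(SITE_KEY))["localization_prob"].max().reindex(wide.index)
    return SiteMatrix(values=wide, best_localization=best, scale="linear")


def censor_log_matrix(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Set log2 values strictly below 0 to missing; 0 and above are kept."""
    return log2_matrix.where(~(log2_matrix < 0))


def median_center(log2_matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationReport]:
    """Median-center samples of a log2 matrix.

    Each sample's normalization factor is the grand mean of sample medians
    minus that sample's median; the factor is added to the sample so every
    output sample median equals the grand mean. Medians use present values
    only; missing values stay missing.
    """
    empties = [c for c in log2_matrix.columns if log2_matrix[c].notna().sum() == 0]
    if empties:
        raise NormalizationError(f"samples with no present values: {empties}")
    medians = log2_matrix.median(axis=0, skipna=True)
    grand_mean = float(medians.mean())
    factors = grand_mean - medians
    centered = log2_matrix.add(factors, axis=1)
    report = NormalizationReport(
        sample_medians=medians, grand_mean=grand_mean, factors=factors
    )
    return centered, report
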