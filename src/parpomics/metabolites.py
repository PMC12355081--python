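"""Weighted calibration, point exclusion, LoQ and sample quantitation for
targeted LC-MS/MS metabolite measurements.

Calibration curves are fitted to (nominal concentration, analyte/internal-
standard area ratio) points by weighted least squares with weights
``1/x^exponent`` (default exponent 2, the standard choice for calibration
series spanning orders of magnitude, which equalizes relative rather than
absolute residuals). Points whose back-calculated concentration error
exceeds 15% are excluded and the curve refitted once. The limit of
quantitation is the lowest retained calibration level whose signal reaches
10x the blank noise (blank-signal standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationParams",
    "CalibrationSeries",
    "CalibrationError",
    "fit_weighted_line",
    "exclude_and_refit",
    "loq_and_quantify",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationParams:
    weight_exponent: float = 2.0
    max_backcalc_error_pct: float = 15.0
    snr_threshold: float = 10.0
    iterate_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.max_backcalc_error_pct <= 0 or self.snr_threshold <= 0:
            raise ValueError("parameters must be positive")


@dataclass
class CalibrationSeries:
    """One analyte's calibration state."""

    analyte: str
    concentrations: np.ndarray  # nominal, > 0
    ratios: np.ndarray  # analyte / internal-standard area ratio
    blanks: np.ndarray = field(default_factory=lambda: np.array([]))
    slope: float | None = None
    intercept: float | None = None
    initial_fit: tuple[float, float] | None = None
    excluded: list[int] = field(default_factory=list)
    loq: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        if (self.concentrations <= 0).any():
            raise CalibrationError(f"{self.analyte}: nominal concentrations must be > 0")
        if len(self.concentrations) != len(self.ratios):
            raise CalibrationError(f"{self.analyte}: point arrays differ in length")

    @property
    def retained(self) -> np.ndarray:
        mask = np.ones(len(self.concentrations), dtype=bool)
        mask[self.excluded] = False
        return mask


def fit_weighted_line(
    x: Sequence[float], y: Sequence[float], weight_exponent: float = 2.0
) -> tuple[float, float]:
    """Weighted least-squares line with weights ``1/x^exponent``.

    Closed-form normal-equation solution; exponent 0 reduces to ordinary
    least squares. Requires >= 2 points with distinct x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise CalibrationError("need >= 2 calibration points")
    if np.allclose(x, x[0]):
        raise CalibrationError("all x identical; line is undetermined")
    w = 1.0 / np.power(x, weight_exponent)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    return float(slope), float(intercept)


def _backcalc_errors(series: CalibrationSeries, slope: float, intercept: float) -> np.ndarray:
    xhat = (series.ratios - intercept) / slope
    return np.abs(xhat - series.concentrations) / series.concentrations * 100.0


def exclude_and_refit(
    series: CalibrationSeries, params: CalibrationParams = CalibrationParams()
) -> CalibrationSeries:
    """Fit, exclude points with back-calculated error > 15%, refit.

    Exclusion is single-pass by default (exclude then refit once); with
    ``iterate_exclusion`` the cycle repeats until no retained point exceeds
    the bound. Both the initial and final fits are kept on the record.
    Fails if fewer than 2 points survive.
    """
    slope, intercept = fit_weighted_line(
        series.concentrations, series.ratios, params.weight_exponent
    )
    series.initial_fit = (slope, intercept)
    excluded: list[int] = []
    while True:
        mask = np.ones(len(series.concentrations), dtype=bool)
        mask[excluded] = False
        errors = _backcalc_errors(series, slope, intercept)
        newly = [
            i
            for i in np.flatnonzero(mask)
            if errors[i] > params.max_backcalc_error_pct
        ]
        if not newly:
            break
        excluded.extend(newly)
        mask[newly] = False
        if mask.sum() < 2:
            raise CalibrationError(
                f"{series.analyte}: fewer than 2 calibration points survive exclusion"
            )
        slope, intercept = fit_weighted_line(
            series.concentrations[mask], series.ratios[mask], params.weight_exponent
        )
        if not params.iterate_exclusion:
            break
    series.slope, series.intercept = slope, intercept
    series.excluded = sorted(excluded)
    return series


def loq_and_quantify(
    series: CalibrationSeries,
    sample_ratios: pd.Series,
    protein_amounts: pd.Series | None = None,
    params: CalibrationParams = CalibrationParams(),
) -> pd.DataFrame:
    """Quantify samples against a fitted calibration and flag below-LoQ values.

    Noise is the standard deviation of blank signals; the LoQ is the lowest
    retained calibration level whose signal-to-noise ratio reaches the
    threshold (default 10). Sample concentration is
    ``(ratio - intercept) / slope``. Below-LoQ samples are flagged, not
    dropped. If ``protein_amounts`` (indexed like the samples, e.g. average
    protein per cell line) is given, a normalized concentration column is
    added. Zero blank variance leaves the LoQ undefined: a warning is
    emitted and nothing is flagged.
    """
    if series.slope is None or series.intercept is None:
        raise CalibrationError(f"{series.analyte}: calibration not fitted")
    noise = float(np.std(series.blanks, ddof=0)) if len(series.blanks) else 0.0
    loq = None
    if noise == 0:
        warnings.warn(
            f"{series.analyte}: zero blank variance, LoQ undefined; "
            "treating all values as above LoQ",
            stacklevel=2,
        )
    else:
        retained = series.retained
        levels = series.concentrations[retained]
        signals = series.ratios[retained]
        order = np.argsort(levels)
        for i in order:
            if signals[i] / noise >= params.snr_threshold:
                loq = float(levels[i])
                break
    series.loq = loq
    conc = (sample_ratios - series.intercept) / series.slope
    out = pd.DataFrame({"concentration": conc})
    out["below_loq"] = False if loq is None else conc < loq
    if protein_amounts is not None:
        out["normalized"] = conc / protein_amounts.reindex(sample_ratios.index)
    return out
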