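"""Marker-compound quantitation: calibration curves, contents, percent contents.

Contents are normalized per marker to the across-batch mean (percent
content); a batch's overall content index is the mean of its marker
percent contents.  Not-detected (ND) entries count as zero in column
summaries but are left out of percent-content display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

ND = float("nan")  # not-detected marker inside numeric grids


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float  # area per (ug/mL)
    intercept: float  # area
    r_squared: float
    linear_range: tuple[float, float] | None = None  # ug/mL
    lod: float | None = None  # ug/mL
    loq: float | None = None  # ug/mL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"calibration slope must be positive ({self.analyte})")
        if self.linear_range is not None and self.linear_range[0] >= self.linear_range[1]:
            raise ValidationError("linear_range low must be below high")
        if self.lod is not None and self.loq is not None and self.lod >= self.loq:
            raise ValidationError("LOD must be below LOQ")


@dataclass(frozen=True)
class QuantResult:
    concentration: float  # mg/L in the preparation after dilution factor
    below_loq: bool = False
    outside_linear_range: bool = False


@dataclass
class MarkerContentTable:
    batch_ids: list[str]
    markers: list[str]
    contents: np.ndarray  # B x M, NaN = not detected
    percent_contents: np.ndarray  # B x M, percent of across-batch mean
    p7c: np.ndarray  # per-batch mean percent content

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.percent_contents, index=self.batch_ids, columns=self.markers)
        df["P_mean"] = self.p7c
        return df


def fit_calibration(concentrations: Sequence[float], areas: Sequence[float],
                    analyte: str = "") -> CalibrationCurve:
    """Ordinary least squares of peak area on injected concentration."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(areas, dtype=float)
    if c.shape != a.shape:
        raise ValidationError("concentration and area lists differ in length")
    if c.size < 3:
        raise ValidationError(f"need at least 3 calibration points, got {c.size}")
    if np.ptp(c) == 0:
        raise DegenerateInputError("calibration concentrations are all identical")
    res = stats.linregress(c, a)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        linear_range=(float(c.min()), float(c.max())),
    )


def quantify(curve: CalibrationCurve, area: float, dilution_factor: float = 1.0) -> QuantResult:
    """Invert the calibration line; flags (not errors) mark suspect values."""
    injected = (area - curve.intercept) / curve.slope
    below_loq = curve.loq is not None and injected < curve.loq
    outside = curve.linear_range is not None and not (
        curve.linear_range[0] <= injected <= curve.linear_range[1]
    )
    return QuantResult(concentration=injected * dilution_factor,
                       below_loq=below_loq, outside_linear_range=outside)


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits at S/N = 3 and S/N = 10."""
    if noise_sd <= 0 or slope <= 0:
        raise ValidationError("noise_sd and slope must be positive")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def _nd_to_zero(values: np.ndarray) -> np.ndarray:
    return np.where(np.isnan(values), 0.0, values)


def percent_contents(contents, batch_ids: Sequence[str] | None = None,
                     markers: Sequence[str] | None = None) -> MarkerContentTable:
    """Normalize each marker column to its across-batch mean (ND counts as 0).

    Percent content is computed against the unrounded column mean; a batch's
    summary index is the arithmetic mean of its marker percents.  ND cells
    stay ND in the percent grid for display but count as zero in the row mean.
    """
    if isinstance(contents, pd.DataFrame):
        batch_ids = batch_ids or [str(i) for i in contents.index]
        markers = markers or [str(c) for c in contents.columns]
        grid = contents.to_numpy(dtype=float)
    else:
        grid = np.asarray(contents, dtype=float)
        batch_ids = list(batch_ids or [f"B{i+1}" for i in range(grid.shape[0])])
        markers = list(markers or [f"M{j+1}" for j in range(grid.shape[1])])
    if grid.ndim != 2 or grid.shape[0] < 1:
        raise ValidationError("contents must be a non-empty 2-D grid")
    col_means = _nd_to_zero(grid).mean(axis=0)
    dead = col_means <= 0
    if dead.any():
        raise DegenerateInputError(
            f"marker column(s) {[markers[j] for j in np.flatnonzero(dead)]} have no detected content"
        )
    pct = grid / col_means * 100.0
    p7c = _nd_to_zero(pct).mean(axis=1)
    return MarkerContentTable(list(batch_ids), list(markers), grid, pct, p7c)


def summarize_column(values) -> tuple[float, float]:
    """(mean, RSD%) of one marker column with ND treated as zero.

    Mean is over all B entries; RSD uses the n-1 sample standard deviation.
    """
    v = _nd_to_zero(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValidationError("need at least 2 values to summarize")
    mean = float(v.mean())
    if mean == 0:
        raise DegenerateInputError("RSD undefined for zero-mean column")
    rsd = float(v.std(ddof=1) / mean * 100.0)
    return mean, rsd


def read_contents_csv(path) -> pd.DataFrame:
    """Wide or long contents CSV -> DataFrame (batches x markers, NaN for 'ND')."""
    df = pd.read_csv(path)
    if {"batch_id", "analyte", "content_mg_l"}.issubset(df.columns):
        df = df.pivot(index="batch_id", columns="analyte", values="content_mg_l")
    else:
        df = df.set_index(df.columns[0])
    return df.apply(pd.to_numeric, errors="coerce")
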