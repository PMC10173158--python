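"""Per-metal descriptive statistics in the spreadsheet convention.

Thirteen statistics per metal — min, max, mean, standard error, median,
SD, variance, excess kurtosis, skewness, range, sum, count — plus a
symmetry label.  Estimator conventions:

* SD and variance use the n-1 (sample) denominator.
* Skewness is the adjusted Fisher-Pearson coefficient and kurtosis the
  sample *excess* kurtosis, i.e. the spreadsheet SKEW/KURT formulas
  (``scipy.stats`` with ``bias=False``).
* The even-count median is the mean of the two central order statistics.

The derived statistics are computed from their defining identities
(mean = sum/count, SE = SD/sqrt(count), variance = SD^2, range = max - min)
so those identities hold to machine precision on unrounded values; the
two-decimal report rounding is applied independently per cell, as survey
tables conventionally do.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ConcentrationTable, ValidationError, format_stat

__all__ = ["SummaryStatistics", "summarize", "classify_symmetry", "STAT_ROWS"]

#: Report row order, mirroring the survey tables.
STAT_ROWS = (
    "Min", "Max", "Mean", "St. Error", "Median", "SD",
    "Variance", "Kurt", "Skew", "Range", "Sum", "Count",
)

SYMMETRIC = "approximately symmetric"
SKEWED = "skewed"


def classify_symmetry(skewness: float) -> str:
    """Label a distribution by its skewness: ``|skew| <= 1`` is symmetric enough.

    The +-1 band is the conventional screening rule for calling a
    concentration distribution approximately symmetric.
    """
    if skewness is None or not math.isfinite(skewness):
        raise ValidationError(f"skewness must be finite, got {skewness!r}")
    return SYMMETRIC if abs(skewness) <= 1.0 else SKEWED


@dataclass(frozen=True)
class SummaryStatistics:
    """Statistics x metals table for one site, plus per-metal symmetry labels.

    ``table`` rows follow :data:`STAT_ROWS`; shape statistics that are
    undefined at the sample size (skewness below n=3, kurtosis below n=4)
    are NaN and listed in ``undefined``.
    """

    site_id: str
    table: pd.DataFrame
    symmetry: pd.Series
    undefined: tuple[str, ...] = ()

    def stat(self, name: str, metal: str) -> float:
        return float(self.table.loc[name, metal])

    def to_report_frame(self) -> pd.DataFrame:
        """Two-decimal rendering in the survey-table layout."""
        return self.table.map(format_stat)

    def to_report_dict(self) -> dict:
        out: dict = {"site_id": self.site_id}
        for metal in self.table.columns:
            out[metal] = {row: format_stat(self.table.loc[row, metal]) for row in STAT_ROWS}
            out[metal]["symmetry"] = self.symmetry[metal]
        return out


def summarize(table: ConcentrationTable) -> SummaryStatistics:
    """Compute the thirteen-statistic summary of each metal column.

    Requires at least two samples; with fewer than 3 (skewness) or 4
    (kurtosis) samples the shape statistics are flagged undefined (NaN plus
    a warning), never silently zero.
    """
    n = table.n_samples
    if n < 2:
        raise ValidationError(f"need at least 2 samples for summary statistics, got {n}")
    rows: dict[str, list[float]] = {row: [] for row in STAT_ROWS}
    symmetry: dict[str, str] = {}
    undefined: list[str] = []
    for metal in table.metals:
        x = table.column(metal)
        total = float(x.sum())
        mean = total / n
        sd = float(np.std(x, ddof=1))
        if n < 3:
            skew = math.nan
            undefined.append(f"{metal}: skewness undefined for n < 3")
        elif sd == 0:
            skew = math.nan
            undefined.append(f"{metal}: skewness undefined for a constant column")
        else:
            skew = float(stats.skew(x, bias=False))
        if n >= 4:
            kurt = float(stats.kurtosis(x, bias=False, fisher=True)) if sd > 0 else math.nan
            if sd == 0:
                undefined.append(f"{metal}: kurtosis undefined for a constant column")
        else:
            kurt = math.nan
            undefined.append(f"{metal}: kurtosis undefined for n < 4")
        rows["Min"].append(float(x.min()))
        rows["Max"].append(float(x.max()))
        rows["Mean"].append(mean)
        rows["St. Error"].append(sd / math.sqrt(n))
        rows["Median"].append(float(np.median(x)))
        rows["SD"].append(sd)
        rows["Variance"].append(sd * sd)
        rows["Kurt"].append(kurt)
        rows["Skew"].append(skew)
        rows["Range"].append(float(x.max()) - float(x.min()))
        rows["Sum"].append(total)
        rows["Count"].append(float(n))
        symmetry[metal] = classify_symmetry(skew) if math.isfinite(skew) else "undefined"
    if undefined:
        warnings.warn("; ".join(undefined), stacklevel=2)
    frame = pd.DataFrame(rows, index=table.metals).T
    frame = frame.loc[list(STAT_ROWS)]
    return SummaryStatistics(
        site_id=table.site_id,
        table=frame,
        symmetry=pd.Series(symmetry, name="symmetry"),
        undefined=tuple(undefined),
    )
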