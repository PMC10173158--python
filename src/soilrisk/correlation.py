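"""Pearson correlation screening across metals.

Computes the product-moment correlation matrix of a concentration table
and assigns each pair the four-tier magnitude category used in
environmental geochemistry screening:

* ``strong``        |R| >= 0.8
* ``significant``   0.5 <= |R| < 0.8
* ``weak``          0.3 <= |R| < 0.5
* ``insignificant`` |R| < 0.3

The published tier bounds overlap at 0.5 and 0.8; here a boundary value
belongs to the stronger tier, which flags the stronger association
conservatively.  Categorization is by magnitude only — no significance
testing is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import ConcentrationTable, ValidationError

__all__ = ["CorrelationResult", "pearson_matrix", "categorize"]

STRONG = "strong"
SIGNIFICANT = "significant"
WEAK = "weak"
INSIGNIFICANT = "insignificant"
UNDEFINED = "undefined"


def categorize(r: float) -> str:
    """Four-tier magnitude category of a Pearson coefficient."""
    if r is None or not math.isfinite(r):
        raise ValidationError(f"correlation coefficient must be finite, got {r!r}")
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValidationError(f"|R| must be <= 1, got {r}")
    a = min(a, 1.0)
    if a >= 0.8:
        return STRONG
    if a >= 0.5:
        return SIGNIFICANT
    if a >= 0.3:
        return WEAK
    return INSIGNIFICANT


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson matrix plus the paired category matrix for one site.

    ``R`` is symmetric with unit diagonal; entries involving a
    zero-variance metal are NaN and their category is ``undefined``.
    """

    site_id: str
    R: pd.DataFrame
    categories: pd.DataFrame

    @property
    def metals(self) -> list[str]:
        return list(self.R.columns)

    def lower_triangle(self) -> pd.DataFrame:
        """Lower-triangular rendering (diagonal kept), upper cells blank."""
        mask = np.tril(np.ones(self.R.shape, dtype=bool))
        out = self.R.where(mask)
        return out.map(lambda v: "" if pd.isna(v) else f"{v:.4f}")

    def to_report_frame(self) -> pd.DataFrame:
        return self.lower_triangle()

    def to_report_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "R": {m: {k: (None if pd.isna(v) else round(float(v), 4))
                      for k, v in self.R[m].items()} for m in self.metals},
            "categories": {m: dict(self.categories[m]) for m in self.metals},
        }


def pearson_matrix(table: ConcentrationTable) -> CorrelationResult:
    """Product-moment correlation matrix across the table's metals.

    Requires at least 3 samples.  Zero-variance columns make a coefficient
    undefined: those entries are NaN, categorised ``undefined``, and a
    warning names the metals rather than letting NaN pass silently.
    """
    if table.n_samples < 3:
        raise ValidationError(
            f"need at least 3 samples for correlations, got {table.n_samples}"
        )
    X = table.values
    metals = table.metals
    sd = X.std(axis=0, ddof=1)
    constant = [m for m, s in zip(metals, sd) if s == 0]
    if constant:
        warnings.warn(
            f"zero-variance column(s) {constant}: correlations undefined", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    np.fill_diagonal(R, 1.0)
    for m in constant:
        j = metals.index(m)
        R[j, :] = np.nan
        R[:, j] = np.nan
        R[j, j] = np.nan
    R = np.clip(R, -1.0, 1.0)  # guard rounding spill past +-1
    R = (R + R.T) / 2.0
    ok = ~np.isnan(np.diag(R))
    np.fill_diagonal(R, np.where(ok, 1.0, np.nan))
    cats = np.empty(R.shape, dtype=object)
    for i in range(len(metals)):
        for j in range(len(metals)):
            if i == j:
                cats[i, j] = "" if ok[i] else UNDEFINED
            elif np.isnan(R[i, j]):
                cats[i, j] = UNDEFINED
            else:
                cats[i, j] = categorize(R[i, j])
    return CorrelationResult(
        site_id=table.site_id,
        R=pd.DataFrame(R, index=metals, columns=metals),
        categories=pd.DataFrame(cats, index=metals, columns=metals),
    )
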