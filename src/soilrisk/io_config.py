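"""Input/output and configuration for soil heavy-metal risk analysis.

This module defines the validated containers the rest of the package works
on — per-site concentration tables, exposure-scenario parameters and
per-metal toxicity profiles — together with readers for CSV/YAML/JSON input
and a report writer that mimics the rounding conventions of environmental
geochemistry tables (two decimals for descriptive statistics, three
significant figures in scientific notation for risk quantities).

Concentrations are interpreted as mg/kg dry weight throughout.  The input
tables carry no unit metadata, so this assumption is global and should be
kept in mind when supplying data measured on another scale.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "ConcentrationTable",
    "ExposureParameters",
    "ToxicityProfile",
    "read_concentration_table",
    "load_exposure_parameters",
    "load_toxicity_profiles",
    "write_report",
    "format_risk",
    "format_stat",
]

#: The ten analytes of the reference survey, in reporting order.
STUDY_METALS = ("Ni", "Cu", "Pb", "Mn", "Mg", "As", "Zn", "Cd", "Cr", "Fe")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


# ---------------------------------------------------------------------------
# Concentration tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentrationTable:
    """Per-site matrix of sample x metal concentrations in mg/kg dry weight.

    Parameters
    ----------
    site_id:
        Label of the sampling site (e.g. ``"Moro"``).
    data:
        DataFrame with one row per soil sample and one column per metal
        (element symbols).  All values must be finite and non-negative.
    """

    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("concentration table must have at least one sample and one metal")
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValidationError(f"duplicate metal columns: {dupes}")
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("concentration table contains non-numeric cells")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite concentration for {df.columns[j]} in sample {df.index[i]}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative concentration {values[i, j]} for {df.columns[j]} "
                f"in sample {df.index[i]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def metals(self) -> list[str]:
        return [str(m) for m in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """Concentration matrix (samples x metals), mg/kg."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, metal: str) -> np.ndarray:
        """One metal's concentrations across samples, mg/kg."""
        if metal not in self.data.columns:
            raise KeyError(f"metal {metal!r} not in table for site {self.site_id!r}")
        return self.data[metal].to_numpy(dtype=float)

    def means(self) -> pd.Series:
        """Per-metal mean concentration, the Cs used in risk equations."""
        return pd.Series(self.values.mean(axis=0), index=self.metals, name=self.site_id)

    def to_csv(self, path: str | Path) -> None:
        """Write the table at full float precision (lossless round trip)."""
        self.data.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_concentration_table(path: str | Path, site_id: str | None = None) -> ConcentrationTable:
    """Read a tidy CSV (rows = samples, columns = metals) as a table.

    The first column is used as the sample identifier when its header is
    ``sample_id`` (or the file was written by :meth:`ConcentrationTable.to_csv`);
    otherwise sequential identifiers ``S1..Sn`` are assigned.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValidationError
        For non-numeric cells (naming row and column), negative values or
        duplicate metal headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"concentration table not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty table")
    first = str(raw.columns[0]).strip().lower()
    if first in {"sample_id", "sample", "id"}:
        raw = raw.set_index(raw.columns[0])
    else:
        raw.index = pd.Index([f"S{i + 1}" for i in range(len(raw))])
    # Duplicate headers: pandas mangles them to "X.1", so check the raw header.
    header = [h.strip() for h in path.read_text().splitlines()[0].split(",")]
    body_header = header[1:] if first in {"sample_id", "sample", "id"} else header
    seen: set[str] = set()
    for name in body_header:
        if name in seen:
            raise ValidationError(f"{path}: duplicate metal header {name!r}")
        seen.add(name)
    parsed = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        values = []
        for row_label, cell in raw[col].items():
            try:
                values.append(float(cell))  # exact strtod, unlike to_numeric's fast path
            except (ValueError, TypeError):
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} for {col} in row {row_label}"
                ) from None
        parsed[col] = values
    return ConcentrationTable(site_id=site_id or path.stem, data=parsed)


# ---------------------------------------------------------------------------
# Exposure parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureParameters:
    """Adult-resident exposure scenario for soil contact.

    Defaults follow standard USEPA residential screening practice.  Risk
    magnitudes scale directly with these choices, so site-specific values
    should be supplied whenever they are known.

    Attributes
    ----------
    IngRs : float
        Soil ingestion rate, mg/day.
    InhRs : float
        Inhalation rate, m^3/day.
    EF : float
        Exposure frequency, days/year.
    ED : float
        Exposure duration, years.
    BW : float
        Body weight of the exposed individual, kg.
    AT_nc : float
        Averaging time for non-carcinogenic risk, days (ED x 365).
    AT_ca : float
        Averaging time for carcinogenic risk, days (lifetime, 70 x 365).
    PEF : float
        Particle emission factor converting soil concentration to an
        inhalable-dust air concentration, m^3/kg.
    SA : float
        Exposed skin surface area, cm^2.
    AF : float
        Soil-to-skin adherence factor, mg/(cm^2 day).
    ABS : float
        Default dermal absorption fraction (unitless); overridable per
        metal through ``ABS_by_metal``.
    ABS_by_metal : mapping
        Per-metal dermal absorption fractions (e.g. arsenic 0.03).
    CF : float
        Mass conversion factor, kg/mg, carried by the ingestion and dermal
        intake equations so the dose comes out in mg/(kg day).
    """

    IngRs: float = 100.0
    InhRs: float = 20.0
    EF: float = 350.0
    ED: float = 30.0
    BW: float = 70.0
    AT_nc: float = 30.0 * 365.0
    AT_ca: float = 70.0 * 365.0
    PEF: float = 1.36e9
    SA: float = 5700.0
    AF: float = 0.07
    ABS: float = 0.001
    ABS_by_metal: Mapping[str, float] = field(default_factory=lambda: {"As": 0.03})
    CF: float = 1e-6

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "ABS_by_metal":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
                raise ValidationError(f"exposure parameter {f.name} must be a positive number, got {v!r}")
        if self.EF > 366:
            raise ValidationError(f"EF must be <= 366 days/year, got {self.EF}")
        if not 0 < self.ABS <= 1:
            raise ValidationError(f"ABS must lie in (0, 1], got {self.ABS}")
        for metal, a in self.ABS_by_metal.items():
            if not 0 < a <= 1:
                raise ValidationError(f"ABS for {metal} must lie in (0, 1], got {a}")
        for name in ("AT_nc", "AT_ca"):
            at = getattr(self, name)
            if at < self.ED * 365.0 - 1e-9:
                raise ValidationError(f"{name} ({at} d) must be >= ED x 365 ({self.ED * 365.0} d)")

    def abs_for(self, metal: str) -> float:
        """Dermal absorption fraction for *metal* (per-metal override or default)."""
        return float(self.ABS_by_metal.get(metal, self.ABS))

    def to_dict(self) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["ABS_by_metal"] = dict(self.ABS_by_metal)
        return d


def load_exposure_parameters(config: Mapping[str, Any] | str | Path | None = None) -> ExposureParameters:
    """Build :class:`ExposureParameters` from a mapping or YAML/JSON file.

    Unspecified fields take the documented adult-resident defaults
    (BW 70 kg, EF 350 d/yr, ED 30 yr, ...).  ``AT_nc`` follows ED unless
    given explicitly.  Loading the output of
    :meth:`ExposureParameters.to_dict` reproduces an equal object.
    """
    cfg = _as_mapping(config)
    known = {f.name for f in fields(ExposureParameters)}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown exposure parameter(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in cfg.items():
        if key == "ABS_by_metal":
            if not isinstance(value, Mapping):
                raise ValidationError("ABS_by_metal must be a mapping of metal -> fraction")
            kwargs[key] = {str(k): float(v) for k, v in value.items()}
            continue
        try:
            kwargs[key] = float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"exposure parameter {key} must be numeric, got {value!r}") from None
    if "ED" in kwargs and "AT_nc" not in kwargs:
        kwargs["AT_nc"] = kwargs["ED"] * 365.0
    return ExposureParameters(**kwargs)


# ---------------------------------------------------------------------------
# Toxicity profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToxicityProfile:
    """Reference doses and carcinogenic slope factor for one metal.

    ``RfD_*`` are pathway reference doses in mg/(kg day); ``SF_ing`` is the
    oral slope factor in (mg/(kg day))^-1.  Any of them may be absent
    (``None``): metals with no RfD simply contribute nothing to the hazard
    index and metals with no slope factor nothing to cancer risk — both are
    reported as warnings, never as silent zeros.
    """

    metal: str
    RfD_ing: float | None = None
    RfD_inh: float | None = None
    RfD_derm: float | None = None
    SF_ing: float | None = None
    carcinogen: bool = False

    def __post_init__(self) -> None:
        for name in ("RfD_ing", "RfD_inh", "RfD_derm", "SF_ing"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValidationError(f"{name} for {self.metal} must be positive, got {v}")
        if self.carcinogen and self.SF_ing is None:
            raise ValidationError(f"{self.metal} flagged carcinogenic but has no SF_ing")

    def rfd(self, pathway: str) -> float | None:
        return {"ingestion": self.RfD_ing, "inhalation": self.RfD_inh, "dermal": self.RfD_derm}[pathway]


def _default_toxicity_path() -> Path:
    return Path(str(resources.files("soilrisk").joinpath("data/toxicity.yaml")))


def load_toxicity_profiles(
    config: Mapping[str, Any] | str | Path | None = None,
    *,
    include_defaults: bool = True,
) -> dict[str, ToxicityProfile]:
    """Load per-metal toxicity profiles, merging overrides over the shipped table.

    The shipped table (``data/toxicity.yaml``) carries USEPA IRIS-style
    screening values for the ten study metals; magnesium deliberately ships
    with no reference dose and no slope factor (an essential macro-element
    with no established soil toxicity criteria).
    """
    base: dict[str, dict[str, Any]] = {}
    if include_defaults:
        with open(_default_toxicity_path()) as fh:
            base = yaml.safe_load(fh) or {}
    overrides = _as_mapping(config)
    merged: dict[str, dict[str, Any]] = {m: dict(v or {}) for m, v in base.items()}
    for metal, entry in overrides.items():
        if not isinstance(entry, Mapping):
            raise ValidationError(f"toxicity override for {metal} must be a mapping")
        merged.setdefault(str(metal), {}).update(entry)
    profiles: dict[str, ToxicityProfile] = {}
    for metal, entry in merged.items():
        kwargs = {k: entry.get(k) for k in ("RfD_ing", "RfD_inh", "RfD_derm", "SF_ing")}
        kwargs = {k: (None if v is None else float(v)) for k, v in kwargs.items()}
        carcinogen = bool(entry.get("carcinogen", kwargs["SF_ing"] is not None))
        profiles[metal] = ToxicityProfile(metal=metal, carcinogen=carcinogen, **kwargs)
    return profiles


def _as_mapping(config: Mapping[str, Any] | str | Path | None) -> dict[str, Any]:
    """Accept an in-memory mapping, a YAML/JSON path, or None (empty)."""
    if config is None:
        return {}
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text) or {}
    return yaml.safe_load(text) or {}


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def format_risk(x: float) -> str:
    """Render a risk quantity with 3 significant figures, e.g. ``3.38E-1``."""
    if not math.isfinite(x):
        return "NA"
    if x == 0:
        return "0.00E0"
    mantissa_exp = f"{x:.2E}"  # e.g. '3.38E-01'
    mantissa, exp = mantissa_exp.split("E")
    return f"{mantissa}E{int(exp)}"


def format_stat(x: float) -> str:
    """Render a descriptive statistic with two decimals, e.g. ``6.37``."""
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NA"
    return f"{x:.2f}"


def _result_payload(results: Any) -> Any:
    """Coerce a result bundle to plain JSON-serializable structures."""
    if results is None:
        return {}
    if hasattr(results, "to_report_dict"):
        return results.to_report_dict()
    if isinstance(results, pd.DataFrame):
        return {str(c): {str(i): v for i, v in results[c].items()} for c in results.columns}
    if isinstance(results, pd.Series):
        return {str(i): v for i, v in results.items()}
    if isinstance(results, Mapping):
        return {str(k): _result_payload(v) if isinstance(v, (Mapping, pd.DataFrame, pd.Series)) else v
                for k, v in results.items()}
    return results


def write_report(results: Any, path: str | Path, format: str = "json") -> None:
    """Write a finalized result bundle to *path* as JSON, CSV or plain text.

    Result objects of this package expose ``to_report_dict`` /
    ``to_report_frame`` with values already rounded by the table
    conventions (two decimals for statistics, three significant figures
    scientific for risk).  Field order is deterministic.  Empty results
    produce a valid empty document.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in {"json", "csv", "text"}:
        raise ValueError(f"unknown report format: {format!r}")
    if fmt == "json":
        payload = _result_payload(results)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        return
    if hasattr(results, "to_report_frame"):
        frame = results.to_report_frame()
    elif isinstance(results, pd.DataFrame):
        frame = results
    elif isinstance(results, pd.Series):
        frame = results.to_frame()
    elif not results:
        frame = pd.DataFrame()
    else:
        frame = pd.DataFrame(_result_payload(results), index=[0]).T
    if fmt == "csv":
        frame.to_csv(path)
    else:
        path.write_text(frame.to_string() + "\n")
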