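"""Deterministic human health risk assessment for metals in soil.

The USEPA-style index chain for a resident exposed to contaminated soil:

* Chronic daily intake (CDI, mg/(kg day)) by three pathways::

      CDI_ing  = Cs * IngRs * EF * ED * CF / (BW * AT)
      CDI_inh  = Cs * InhRs * EF * ED      / (PEF * BW * AT)
      CDI_derm = Cs * SA * AF * ABS * EF * ED * CF / (BW * AT)

  with Cs the soil concentration (mg/kg).  CF = 1e-6 kg/mg converts the
  soil mass units so the dose comes out in mg/(kg day); the inhalation
  route instead divides by the particle emission factor PEF (m^3/kg),
  which performs the mass-to-air conversion.  The averaging time AT is
  ED*365 days for non-carcinogenic indices and a 70-year lifetime
  (25550 days) for carcinogenic ones, so CDI_ca <= CDI_nc always.

* Hazard quotient HQ = CDI / RfD per metal and pathway; pathway totals
  THQ = sum over metals; hazard index HI = sum of the three THQs.
  HI <= 1 is the acceptability criterion for non-cancer effects.

* Incremental lifetime cancer risk ILCR = CDI_ca * SF per carcinogenic
  metal (ingestion route), summed into a total.  Risk below 1e-6 is
  negligible, 1e-6 to 1e-4 acceptable, above 1e-4 high.

Metals without a reference dose (Mg in the shipped table) or without a
slope factor are excluded from the respective totals with an explicit
warning — never silently counted as zero.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_config import (
    ConcentrationTable,
    ExposureParameters,
    ToxicityProfile,
    ValidationError,
    format_risk,
)

__all__ = [
    "PATHWAYS",
    "RiskResult",
    "cdi_ingestion",
    "cdi_inhalation",
    "cdi_dermal",
    "hazard_quotient",
    "hazard_index",
    "ilcr",
    "classify_risk",
    "assess_site",
]

PATHWAYS = ("ingestion", "inhalation", "dermal")

#: Risk classification thresholds.
HI_THRESHOLD = 1.0
ILCR_NEGLIGIBLE = 1e-6
ILCR_HIGH = 1e-4

ACCEPTABLE = "acceptable"
ELEVATED = "elevated"
NEGLIGIBLE = "negligible"
HIGH = "high"


def _averaging_time(p: ExposureParameters, averaging: str) -> float:
    if averaging == "nc":
        return p.AT_nc
    if averaging == "ca":
        return p.AT_ca
    raise ValidationError(f"averaging must be 'nc' or 'ca', got {averaging!r}")


def cdi_ingestion(Cs: float, p: ExposureParameters, averaging: str = "nc") -> float:
    """Chronic daily intake through incidental soil ingestion, mg/(kg day)."""
    if Cs < 0:
        raise ValidationError(f"concentration must be >= 0, got {Cs}")
    AT = _averaging_time(p, averaging)
    return Cs * p.IngRs * p.EF * p.ED * p.CF / (p.BW * AT)


def cdi_inhalation(Cs: float, p: ExposureParameters, averaging: str = "nc") -> float:
    """Chronic daily intake through inhalation of soil dust, mg/(kg day)."""
    if Cs < 0:
        raise ValidationError(f"concentration must be >= 0, got {Cs}")
    AT = _averaging_time(p, averaging)
    return Cs * p.InhRs * p.EF * p.ED / (p.PEF * p.BW * AT)


def cdi_dermal(Cs: float, p: ExposureParameters, metal: str = "", averaging: str = "nc") -> float:
    """Chronic daily intake through dermal contact with soil, mg/(kg day).

    The absorption fraction is metal-specific where configured (e.g.
    arsenic); otherwise the scenario default applies.
    """
    if Cs < 0:
        raise ValidationError(f"concentration must be >= 0, got {Cs}")
    AT = _averaging_time(p, averaging)
    return Cs * p.SA * p.AF * p.abs_for(metal) * p.EF * p.ED * p.CF / (p.BW * AT)


def hazard_quotient(cdi: float, rfd: float) -> float:
    """Non-cancer hazard quotient CDI / RfD (unitless)."""
    if rfd is None or not math.isfinite(rfd) or rfd <= 0:
        raise ValidationError(f"RfD must be positive, got {rfd!r}")
    if cdi < 0:
        raise ValidationError(f"CDI must be >= 0, got {cdi}")
    return cdi / rfd


def hazard_index(thq_by_pathway) -> float:
    """Hazard index: exact sum of per-pathway total hazard quotients."""
    values = [float(v) for v in thq_by_pathway]
    if any(v < 0 for v in values):
        raise ValidationError("THQ values must be >= 0")
    return float(sum(values))


def ilcr(cdi_ca: float, sf: float) -> float:
    """Incremental lifetime cancer risk: lifetime-averaged CDI times slope factor."""
    if sf < 0:
        raise ValidationError(f"slope factor must be >= 0, got {sf}")
    if cdi_ca < 0:
        raise ValidationError(f"CDI must be >= 0, got {cdi_ca}")
    return cdi_ca * sf


def classify_risk(hi: float, ilcr_total: float) -> tuple[str, str]:
    """Classify (non-cancer, cancer) risk against the USEPA thresholds.

    HI above 1 is ``elevated``; cancer risk below 1e-6 is ``negligible``,
    within [1e-6, 1e-4] ``acceptable`` (boundaries inclusive) and above
    1e-4 ``high``.
    """
    for name, v in (("HI", hi), ("ILCR", ilcr_total)):
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {v}")
    noncancer = ACCEPTABLE if hi <= HI_THRESHOLD else ELEVATED
    if ilcr_total < ILCR_NEGLIGIBLE:
        cancer = NEGLIGIBLE
    elif ilcr_total <= ILCR_HIGH:
        cancer = ACCEPTABLE
    else:
        cancer = HIGH
    return noncancer, cancer


@dataclass(frozen=True)
class RiskResult:
    """Full deterministic risk bundle for one site.

    ``cdi_nc``/``cdi_ca`` and ``hq`` are metals x pathways frames (NaN in
    ``hq`` where the RfD is missing); ``thq`` sums HQ over metals per
    pathway, ``hi`` sums the three THQs, ``ilcr_by_metal`` covers the
    carcinogenic metals (ingestion route, lifetime averaging).
    """

    site_id: str
    cdi_nc: pd.DataFrame
    cdi_ca: pd.DataFrame
    hq: pd.DataFrame
    thq: pd.Series
    hi: float
    ilcr_by_metal: pd.Series
    ilcr_total: float
    noncancer_label: str
    cancer_label: str
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def summary_row(self) -> pd.Series:
        """Site summary shaped like the published risk table: pathway CDI
        totals (summed over metals, non-carcinogenic averaging), pathway
        THQs, HI and total ILCR."""
        return pd.Series(
            {
                "CDI_ing": self.cdi_nc["ingestion"].sum(),
                "CDI_inh": self.cdi_nc["inhalation"].sum(),
                "CDI_derm": self.cdi_nc["dermal"].sum(),
                "THQ_ing": self.thq["ingestion"],
                "THQ_inh": self.thq["inhalation"],
                "THQ_derm": self.thq["dermal"],
                "HI": self.hi,
                "ILCR": self.ilcr_total,
            },
            name=self.site_id,
        )

    def to_report_frame(self) -> pd.DataFrame:
        row = self.summary_row().map(format_risk)
        return row.to_frame().T

    def to_report_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "summary": {k: format_risk(v) for k, v in self.summary_row().items()},
            "classification": {
                "noncancer": self.noncancer_label,
                "cancer": self.cancer_label,
            },
            "ILCR_by_metal": {m: format_risk(v) for m, v in self.ilcr_by_metal.items()},
            "HQ": {
                m: {pw: (None if pd.isna(self.hq.loc[m, pw]) else format_risk(self.hq.loc[m, pw]))
                    for pw in PATHWAYS}
                for m in self.hq.index
            },
            "warnings": list(self.warnings),
        }


def assess_site(
    table: ConcentrationTable,
    p: ExposureParameters,
    tox: Mapping[str, ToxicityProfile],
    pathways: tuple[str, ...] = PATHWAYS,
) -> RiskResult:
    """Run the full deterministic index chain on a site's mean concentrations.

    Per-metal mean concentrations serve as Cs.  Metals absent from the
    toxicity map or lacking an RfD for a pathway are skipped in that
    pathway's THQ with a warning; metals lacking a slope factor are skipped
    in the cancer total likewise.  Raises if no metal contributes to the
    hazard index at all (an empty HI is undefined).
    """
    unknown = [pw for pw in pathways if pw not in PATHWAYS]
    if unknown:
        raise ValidationError(f"unknown pathway(s): {unknown}")
    means = table.means()
    metals = table.metals
    warn: list[str] = []

    cdi_fns = {"ingestion": cdi_ingestion, "inhalation": cdi_inhalation, "dermal": cdi_dermal}
    cdi_nc = pd.DataFrame(0.0, index=metals, columns=list(PATHWAYS))
    cdi_ca = pd.DataFrame(0.0, index=metals, columns=list(PATHWAYS))
    hq = pd.DataFrame(np.nan, index=metals, columns=list(PATHWAYS))

    for metal in metals:
        Cs = float(means[metal])
        for pw in pathways:
            kwargs = {"metal": metal} if pw == "dermal" else {}
            cdi_nc.loc[metal, pw] = cdi_fns[pw](Cs, p, averaging="nc", **kwargs)
            cdi_ca.loc[metal, pw] = cdi_fns[pw](Cs, p, averaging="ca", **kwargs)
        profile = tox.get(metal)
        if profile is None:
            warn.append(f"{metal}: no toxicity profile; excluded from HI and ILCR")
            continue
        for pw in pathways:
            rfd = profile.rfd(pw)
            if rfd is None:
                warn.append(f"{metal}: no RfD for {pw}; excluded from that THQ")
            else:
                hq.loc[metal, pw] = hazard_quotient(float(cdi_nc.loc[metal, pw]), rfd)

    if hq.notna().sum().sum() == 0:
        raise ValidationError("no metal has a reference dose: hazard index undefined")

    thq = pd.Series(
        {pw: float(hq[pw].dropna().sum()) if pw in pathways else 0.0 for pw in PATHWAYS}
    )
    hi = hazard_index(thq[list(pathways)])

    ilcr_vals: dict[str, float] = {}
    for metal in metals:
        profile = tox.get(metal)
        if profile is None:
            continue
        if profile.carcinogen and profile.SF_ing is not None:
            ilcr_vals[metal] = ilcr(float(cdi_ca.loc[metal, "ingestion"]), profile.SF_ing)
        elif profile.carcinogen:
            warn.append(f"{metal}: carcinogenic but no slope factor; excluded from ILCR")
    ilcr_by_metal = pd.Series(ilcr_vals, dtype=float)
    # sequential sum in metal order, matching the Monte Carlo accumulation
    ilcr_total = float(sum(ilcr_vals.values()))
    noncancer, cancer = classify_risk(hi, ilcr_total)
    return RiskResult(
        site_id=table.site_id,
        cdi_nc=cdi_nc,
        cdi_ca=cdi_ca,
        hq=hq,
        thq=thq,
        hi=hi,
        ilcr_by_metal=ilcr_by_metal,
        ilcr_total=ilcr_total,
        noncancer_label=noncancer,
        cancer_label=cancer,
        warnings=tuple(warn),
    )
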