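"""Monte Carlo uncertainty propagation for the soil risk model.

The deterministic index chain treats every exposure input as known.  In
practice the soil ingestion rate, the body weight of the exposed
individual, the metal concentrations and the carcinogenic slope factors
are all uncertain; this module propagates those uncertainties through the
ingestion cancer-risk model (and optionally the hazard index) by plain
Monte Carlo — independent draws per variable, a fixed iteration count
(10,000 by default) and explicit seeding for bit-reproducibility.

Default input distributions, all overridable:

* concentration per metal — lognormal matched to the sample mean and SD
  of the site table, truncated at the observed [min, max];
* body weight — normal, mean 70 kg, CV 0.2, truncated to [40, 120] kg;
* soil ingestion rate — triangular(50, 100, 200) mg/day;
* slope factors — point masses at their configured values.

Outputs are summarised by empirical quantiles (linear interpolation
between order statistics, the numpy default), means, and exceedance
probabilities against the 1e-6 / 1e-4 cancer-risk band.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hhra import ILCR_HIGH, ILCR_NEGLIGIBLE, PATHWAYS
from .io_config import (
    ConcentrationTable,
    ExposureParameters,
    ToxicityProfile,
    ValidationError,
    format_risk,
)

__all__ = [
    "DistributionSpec",
    "SimulationResult",
    "RiskModel",
    "build_default_distributions",
    "sample",
    "run_simulation",
    "summarize_simulation",
]

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution assigned to one uncertain model variable.

    ``params`` is family-specific: ``{"value"}`` (point), ``{"mean", "sd"}``
    (normal), ``{"mu", "sigma"}`` on the log scale (lognormal),
    ``{"lower", "upper"}`` (uniform), ``{"lower", "mode", "upper"}``
    (triangular).  ``truncation = (lo, hi)`` optionally restricts the
    support; either end may be None.
    """

    name: str
    family: str
    params: Mapping[str, float]
    truncation: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        required = {
            "point": {"value"},
            "normal": {"mean", "sd"},
            "lognormal": {"mu", "sigma"},
            "uniform": {"lower", "upper"},
            "triangular": {"lower", "mode", "upper"},
        }[self.family]
        missing = required - set(self.params)
        extra = set(self.params) - required
        if missing or extra:
            raise ValidationError(
                f"{self.name}: {self.family} needs parameters {sorted(required)}, "
                f"got {sorted(self.params)}"
            )
        pr = self.params
        if self.family in ("normal", "lognormal") and pr["sd" if self.family == "normal" else "sigma"] < 0:
            raise ValidationError(f"{self.name}: scale parameter must be >= 0")
        if self.family == "uniform" and not pr["lower"] < pr["upper"]:
            raise ValidationError(f"{self.name}: need lower < upper")
        if self.family == "triangular" and not pr["lower"] <= pr["mode"] <= pr["upper"]:
            raise ValidationError(f"{self.name}: need lower <= mode <= upper")
        if self.family == "triangular" and not pr["lower"] < pr["upper"]:
            raise ValidationError(f"{self.name}: need lower < upper")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and not lo < hi:
                raise ValidationError(f"{self.name}: truncation bounds must be ordered")

    def _frozen(self):
        pr = self.params
        if self.family == "normal":
            return stats.norm(loc=pr["mean"], scale=pr["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=pr["sigma"], scale=math.exp(pr["mu"]))
        if self.family == "uniform":
            return stats.uniform(loc=pr["lower"], scale=pr["upper"] - pr["lower"])
        if self.family == "triangular":
            lo, mode, hi = pr["lower"], pr["mode"], pr["upper"]
            return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
        raise AssertionError(self.family)


def sample(spec: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from ``spec``; identical (spec, n, seed) give identical draws.

    Truncation is applied by inverse-CDF restriction (draw uniforms on
    [F(lo), F(hi)] and map through the quantile function), which keeps the
    draw count exact and deterministic.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "point":
        return np.full(n, float(spec.params["value"]))
    dist = spec._frozen()
    u = rng.uniform(size=n)
    if spec.truncation is not None:
        lo, hi = spec.truncation
        flo = 0.0 if lo is None else float(dist.cdf(lo))
        fhi = 1.0 if hi is None else float(dist.cdf(hi))
        if fhi <= flo:
            raise ValidationError(f"{spec.name}: truncation excludes all probability mass")
        u = flo + u * (fhi - flo)
        u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    return np.asarray(dist.ppf(u), dtype=float)


def lognormal_from_moments(mean: float, sd: float) -> dict[str, float]:
    """Log-scale (mu, sigma) of the lognormal with given arithmetic mean and SD."""
    if mean <= 0:
        raise ValidationError(f"lognormal mean must be positive, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}


def build_default_distributions(
    table: ConcentrationTable,
    p: ExposureParameters,
    tox: Mapping[str, ToxicityProfile],
) -> list[DistributionSpec]:
    """Default uncertain-variable specs for a site simulation.

    Concentrations become truncated lognormals matched to each column's
    sample moments; a zero-variance column degrades to a point mass with a
    warning.  Body weight, ingestion rate and slope factors follow the
    module-level defaults.  The returned list is plain data — edit or
    replace entries to change the hypothesis set.
    """
    specs: list[DistributionSpec] = []
    for metal in table.metals:
        x = table.column(metal)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or mean == 0:
            warnings.warn(f"{metal}: zero-variance column, using a point concentration",
                          stacklevel=2)
            specs.append(DistributionSpec(f"Cs_{metal}", "point", {"value": mean}))
            continue
        specs.append(
            DistributionSpec(
                f"Cs_{metal}",
                "lognormal",
                lognormal_from_moments(mean, sd),
                truncation=(float(x.min()), float(x.max())),
            )
        )
    specs.append(
        DistributionSpec("BW", "normal", {"mean": p.BW, "sd": 0.2 * p.BW}, truncation=(40.0, 120.0))
    )
    specs.append(DistributionSpec("IngRs", "triangular", {"lower": 50.0, "mode": 100.0, "upper": 200.0}))
    for metal, profile in tox.items():
        if profile.carcinogen and profile.SF_ing is not None:
            specs.append(DistributionSpec(f"SF_{metal}", "point", {"value": profile.SF_ing}))
    return specs


class RiskModel:
    """Cancer-risk (and optional hazard-index) model read by the simulator.

    The model evaluates, per iteration, the ingestion chronic daily intake
    and ILCR of every carcinogenic metal with a slope factor, plus their
    total; with ``include_hi=True`` it also evaluates HQ/HI over
    ``hi_pathways`` (ingestion only by default) for every metal with an
    RfD.  Any symbol not covered by a distribution spec is fixed at its
    :class:`ExposureParameters` / toxicity-table value.
    """

    def __init__(
        self,
        table: ConcentrationTable,
        params: ExposureParameters,
        tox: Mapping[str, ToxicityProfile],
        include_hi: bool = False,
        hi_pathways: Sequence[str] = ("ingestion",),
    ) -> None:
        bad = [pw for pw in hi_pathways if pw not in PATHWAYS]
        if bad:
            raise ValidationError(f"unknown pathway(s): {bad}")
        self.params = params
        self.tox = dict(tox)
        self.include_hi = include_hi
        self.hi_pathways = tuple(hi_pathways)
        self.metals = table.metals
        self._means = table.means()
        self.carcinogens = [
            m for m in self.metals
            if m in self.tox and self.tox[m].carcinogen and self.tox[m].SF_ing is not None
        ]
        if not self.carcinogens:
            raise ValidationError("no carcinogenic metal with a slope factor in the table")

    def symbols(self) -> set[str]:
        """Every symbol the model reads and a spec may therefore vary."""
        syms = {"IngRs", "EF", "ED", "BW", "AT_ca", "CF"}
        syms |= {f"Cs_{m}" for m in self.metals}
        syms |= {f"SF_{m}" for m in self.carcinogens}
        if self.include_hi:
            syms |= {"AT_nc"}
            if "inhalation" in self.hi_pathways:
                syms |= {"InhRs", "PEF"}
            if "dermal" in self.hi_pathways:
                syms |= {"SA", "AF"}
        return syms

    def _fixed(self, name: str) -> float:
        p = self.params
        if hasattr(p, name):
            return float(getattr(p, name))
        if name.startswith("Cs_"):
            return float(self._means[name[3:]])
        if name.startswith("SF_"):
            return float(self.tox[name[3:]].SF_ing)
        raise ValidationError(f"unresolved model symbol: {name}")

    def evaluate(self, draws: Mapping[str, np.ndarray], n: int) -> dict[str, np.ndarray]:
        """Vectorised evaluation over ``n`` iterations."""
        def get(name: str):
            return draws[name] if name in draws else self._fixed(name)

        p = self.params
        IngRs, EF, ED, BW, AT_ca, CF = (get(s) for s in ("IngRs", "EF", "ED", "BW", "AT_ca", "CF"))
        out: dict[str, np.ndarray] = {}
        total = np.zeros(n)
        for m in self.carcinogens:
            cdi_ca = get(f"Cs_{m}") * IngRs * EF * ED * CF / (BW * AT_ca)
            risk = cdi_ca * get(f"SF_{m}")
            out[f"ILCR_{m}"] = np.broadcast_to(risk, (n,)).astype(float)
            total = total + risk
        out["ILCR_total"] = total
        if self.include_hi:
            AT_nc = get("AT_nc")
            hi = np.zeros(n)
            for m in self.metals:
                prof = self.tox.get(m)
                if prof is None:
                    continue
                Cs = get(f"Cs_{m}")
                for pw in self.hi_pathways:
                    rfd = prof.rfd(pw)
                    if rfd is None:
                        continue
                    if pw == "ingestion":
                        cdi = Cs * IngRs * EF * ED * CF / (BW * AT_nc)
                    elif pw == "inhalation":
                        cdi = Cs * get("InhRs") * EF * ED / (get("PEF") * BW * AT_nc)
                    else:
                        cdi = Cs * get("SA") * get("AF") * p.abs_for(m) * EF * ED * CF / (BW * AT_nc)
                    hi = hi + cdi / rfd
            out["HI"] = hi
        return out


@dataclass(frozen=True)
class SimulationResult:
    """Draws and summaries of one Monte Carlo run.

    ``outputs`` maps output name (``ILCR_<metal>``, ``ILCR_total``,
    optionally ``HI``) to its draw vector.  ``percentiles`` is an outputs x
    percentile frame; ``bands`` labels each percentile against the cancer
    acceptability band; ``exceedance`` gives P(output > 1e-6) and
    P(output > 1e-4).
    """

    n_iterations: int
    seed: int
    outputs: Mapping[str, np.ndarray]
    percentiles: pd.DataFrame
    means: pd.Series
    exceedance: pd.DataFrame
    bands: pd.DataFrame
    percentile_levels: tuple[float, ...] = (5.0, 50.0, 95.0)

    def to_report_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "percentiles": {
                out: {col: format_risk(v) for col, v in row.items()}
                for out, row in self.percentiles.iterrows()
            },
            "means": {k: format_risk(v) for k, v in self.means.items()},
            "exceedance": {
                out: {col: round(float(v), 4) for col, v in row.items()}
                for out, row in self.exceedance.iterrows()
            },
            "bands": {out: dict(row) for out, row in self.bands.iterrows()},
        }

    def to_report_frame(self) -> pd.DataFrame:
        return self.percentiles.map(format_risk)


def _band(value: float) -> str:
    if value < ILCR_NEGLIGIBLE:
        return "negligible"
    if value <= ILCR_HIGH:
        return "acceptable"
    return "high"


def summarize_simulation(
    outputs: Mapping[str, np.ndarray] | SimulationResult,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
    *,
    n_iterations: int | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Summarise raw output draws into a :class:`SimulationResult`.

    Quantiles use the linear-interpolation convention between order
    statistics (numpy's default), so results are bit-reproducible across
    runs with the same draws.
    """
    if isinstance(outputs, SimulationResult):
        n_iterations = outputs.n_iterations
        seed = outputs.seed
        outputs = outputs.outputs
    if not outputs:
        raise ValidationError("no output draws to summarise")
    levels = tuple(float(q) for q in percentiles)
    if any(not 0 <= q <= 100 for q in levels):
        raise ValidationError(f"percentiles must lie in [0, 100], got {levels}")
    names = list(outputs)
    first = np.asarray(outputs[names[0]])
    if first.size == 0:
        raise ValidationError("empty draws")
    n = n_iterations if n_iterations is not None else first.size
    cols = [f"p{q:g}" for q in levels]
    pct = pd.DataFrame(
        {c: [float(np.percentile(np.asarray(outputs[o]), q)) for o in names]
         for c, q in zip(cols, levels)},
        index=names,
    )
    means = pd.Series({o: float(np.mean(outputs[o])) for o in names})
    exceed = pd.DataFrame(
        {
            "P_gt_1e-6": [float(np.mean(np.asarray(outputs[o]) > ILCR_NEGLIGIBLE)) for o in names],
            "P_gt_1e-4": [float(np.mean(np.asarray(outputs[o]) > ILCR_HIGH)) for o in names],
        },
        index=names,
    )
    bands = pct.map(_band)
    return SimulationResult(
        n_iterations=n,
        seed=seed,
        outputs=dict(outputs),
        percentiles=pct,
        means=means,
        exceedance=exceed,
        bands=bands,
        percentile_levels=levels,
    )


def run_simulation(
    specs: Sequence[DistributionSpec],
    model: RiskModel,
    n_iterations: int = 10_000,
    seed: int = 0,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
) -> SimulationResult:
    """Plain Monte Carlo: draw every uncertain variable, evaluate the model.

    All variables are sampled independently; symbols without a spec stay
    fixed at their deterministic values.  A spec naming a symbol the model
    never reads is an error (caught before any sampling), as is a model
    symbol with no resolvable value.  Identical (specs, model, n, seed)
    give a bit-identical result.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    known = model.symbols()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate distribution specs")
    unknown = [nm for nm in names if nm not in known]
    if unknown:
        raise ValidationError(f"spec(s) for symbols the model does not read: {unknown}")
    for sym in known:  # fail fast on unresolvable symbols before sampling
        model._fixed(sym)
    rng = np.random.default_rng(seed)
    draws = {s.name: sample(s, n_iterations, rng) for s in specs}
    outputs = model.evaluate(draws, n_iterations)
    return summarize_simulation(outputs, percentiles, n_iterations=n_iterations, seed=seed)
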