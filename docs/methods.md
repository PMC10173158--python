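# Methods

## Scope and data model

The package analyses per-site concentration tables: one row per soil
sample, one column per metal, values in mg/kg dry weight. Input tables
carry no unit metadata, so **mg/kg is assumed throughout**; supplying data
on another scale rescales every downstream index accordingly. Tables are
validated on construction (finite, non-negative, no duplicate sample ids
or metal symbols).

## Descriptive statistics

Per metal: min, max, mean, standard error, median, SD, variance, excess
kurtosis, skewness, range, sum, count. Conventions:

- SD and variance use the n−1 denominator; skewness is the adjusted
  Fisher–Pearson coefficient and kurtosis the bias-corrected *excess*
  kurtosis — i.e. the spreadsheet SKEW/KURT formulas, the convention
  survey tables of this kind are almost always produced with.
- Derived statistics are computed from their defining identities
  (mean = sum/count, SE = SD/√n, variance = SD², range = max − min), so
  those identities hold to machine precision *before* rounding. Report
  rendering rounds each cell to two decimals independently, which is why
  printed variance cells in published tables can disagree slightly with
  the square of the printed SD — the package computes from unrounded
  values and only rounds at the report boundary.
- Shape statistics that are undefined (skewness below n = 3, kurtosis
  below n = 4, either for a constant column) are NaN plus a warning,
  never a silent zero.
- The symmetry screen labels a metal "approximately symmetric" iff
  |skewness| ≤ 1, the conventional band for treating a concentration
  distribution as near-symmetric.

## Correlation screening

Standard product-moment coefficients across metals, categorised by
magnitude only (no p-values by design — screening practice in this field
categorises |R|): strong ≥ 0.8, significant ≥ 0.5, weak ≥ 0.3, else
insignificant. The published tier bounds overlap at 0.5 and 0.8; the
package resolves each boundary into the stronger tier, the conservative
choice for flagging associations. Zero-variance columns yield explicitly
undefined entries with a warning.

## Deterministic risk model

Chronic daily intake (CDI, mg/(kg·day)) per metal and pathway:

- ingestion: `Cs·IngR·EF·ED·CF / (BW·AT)`
- inhalation: `Cs·InhR·EF·ED / (PEF·BW·AT)`
- dermal: `Cs·SA·AF·ABS·EF·ED·CF / (BW·AT)`

`CF = 10⁻⁶ kg/mg` appears in the ingestion and dermal routes so that a
soil concentration in mg/kg and intake rates in mg/day yield a dose in
mg/(kg·day); dimensional analysis requires it, and without it the intakes
are a factor 10⁶ too large to be meaningful. The inhalation route needs no
CF because the particle emission factor PEF (m³/kg) performs the
mass-to-air conversion. Two averaging times are kept: `AT_nc = ED·365` d
for non-carcinogenic indices and a fixed 70-year lifetime
(`AT_ca = 25550` d) for carcinogenic ones, per standard practice, so
`CDI_ca ≤ CDI_nc` always. A skin permeability constant plays no role in
this mass-balance dermal formulation and is not a parameter.

Hazard quotient HQ = CDI/RfD per metal and pathway; THQ sums HQ over
metals per pathway; HI sums the three THQs (exact additions, so HI
additivity is checkable to the last digit). ILCR = CDI_ca·SF per
carcinogenic metal on the ingestion route, summed to a site total.
Classification: HI > 1 elevated non-cancer risk; cancer risk < 10⁻⁶
negligible, 10⁻⁶–10⁻⁴ acceptable (boundaries inclusive), > 10⁻⁴ high.

Slope factors are in (mg/(kg·day))⁻¹ — the per-volume unit sometimes
printed for SF in the field literature is a typo for this soil-pathway
unit. Metals lacking an RfD for a pathway, or lacking a slope factor, are
excluded from the corresponding totals with explicit warnings.

### Default parameters

Adult-resident exposure defaults (all overridable): IngR 100 mg/d, InhR
20 m³/d, EF 350 d/yr, ED 30 yr, BW 70 kg, PEF 1.36×10⁹ m³/kg, SA
5700 cm², AF 0.07 mg/(cm²·d), ABS 0.001 (0.03 for As). These are standard
USEPA residential screening values. The RfD/SF table ships as an editable
YAML config (`data/toxicity.yaml`), IRIS-style screening values for the
ten study metals; Mg deliberately has none. Carcinogen flags cover As,
Cd, Cr, Ni and Pb — the metals with established oral slope factors among
the panel. **Absolute HI/ILCR magnitudes scale directly with these
choices**; published site assessments rarely print the parameter sets
behind their tables, so agreement with any particular published table can
only be expected at the order-of-magnitude level unless the same
parameters are supplied.

## Monte Carlo uncertainty propagation

Plain Monte Carlo (not Latin hypercube), 10,000 iterations by default,
with all uncertain variables drawn independently per iteration — no rank
correlation is imposed, since no dependence information is available for
the uncertain inputs. Default hypothesis set, all overridable as plain
`DistributionSpec` data:

- concentration per metal: lognormal matched to the column's sample mean
  and SD (a standard choice for non-negative, right-skewed concentration
  data), truncated at the observed [min, max]; zero-variance columns
  degrade to point masses with a warning;
- body weight: normal, mean 70 kg, CV 0.2, truncated to [40, 120] kg;
- soil ingestion rate: triangular(50, 100, 200) mg/day;
- slope factors: point masses at their configured values.

The simulated output is the ingestion-route cancer risk per carcinogenic
metal and its total; the hazard index can be co-simulated on request
(ingestion-only by default, all three pathways optionally). Percentile
summaries use the linear-interpolation empirical quantile convention
(numpy default) for bit-reproducibility; exceedance probabilities are
reported against the 10⁻⁶ and 10⁻⁴ thresholds. Sampling is inverse-CDF
throughout (uniforms restricted to [F(lo), F(hi)] for truncation), so a
fixed seed gives bit-identical results and degenerate (all-point)
hypothesis sets reproduce the deterministic pipeline exactly. Because the
model is convex in 1/BW, the simulated mean risk slightly exceeds the
deterministic risk at mean inputs (Jensen's inequality) — expected, not a
bug.

## Synthetic site generation

The generator emulates a site for which only summary statistics are
published: for each metal it draws a bounded marginal (truncated normal by
default — appropriate since the study metals' published skewness lies
within ±1 — or truncated lognormal), then applies an affine-with-clipping
correction, solving the shift and scale by bisection so the *sample* mean
and SD of the column equal the targets essentially exactly while every
value stays in [min, max]. Clipping matters for columns whose target SD
exceeds what any unclipped distribution of that shape can reach inside the
bounds (strongly platykurtic columns such as Pb or As at the gold site);
it concentrates some mass at the bounds, making the marginal near-bimodal
there. Targets with sd larger than the hard feasibility cap
√((mean−min)(max−mean)) are rejected.

Cross-metal dependence, when a target correlation matrix is given, comes
from a Gaussian copula (eigen-decomposition square root, so exactly
singular matrices — comonotone pairs — are supported; matrices with
eigenvalues below −10⁻⁸ are rejected naming the offending eigenvalue).
The per-column moment correction is monotone, so it preserves rank
structure; sample Pearson correlations land within ±0.15 of the copula
targets at n = 500. The shipped fixture specs for the two study sites
default to independence across metals, since the published correlation
matrices are dominated by |R| < 0.3 and the raw data's dependence
structure is unknowable from the summaries.

What the synthetic tables do **not** emulate: spatial autocorrelation,
higher moments (skewness/kurtosis are whatever the corrected truncated
marginal produces, not matched to published values), detection-limit
censoring, and inter-metal dependence at the fixture sites. Tests passing
on synthetic tables therefore validate the pipeline's arithmetic and
invariances, not distributional claims about the real sites.

## Numerical and design notes

- All generation and simulation take explicit integer seeds; there is no
  global random state anywhere.
- Report rounding: two decimals for descriptive statistics, three
  significant figures in scientific notation (`3.38E-1` style) for risk
  quantities; full float precision for table round trips.
- The deterministic ILCR total is accumulated in metal order with plain
  sequential summation, matching the Monte Carlo accumulation exactly so
  the point-mass equivalence holds bitwise.
- Published site-summary risk tables are read as metal-summed pathway
  values (the only reading under which pathway THQs add exactly to the
  printed HI); per-metal breakdowns are reported alongside.
- Problem sizes used by the shipped checks: 36 samples × 10 metals per
  site, 100-seed recovery sweeps, 10,000 Monte Carlo iterations (10⁵ for
  the convergence check) — comfortably interactive on one CPU.

## Known limitations

- Single receptor (adult resident); no child scenario, no dermal or
  inhalation cancer routes, no inhalation unit-risk conversion.
- Cancer risk is ingestion-led by default; if a site's risk is
  inhalation-dominated the simulated totals will understate it unless the
  hypothesis set is extended.
- No source apportionment, PCA or spatial statistics.
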