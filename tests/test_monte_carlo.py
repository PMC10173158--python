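"""Monte Carlo propagation: sampling, determinism, oracle equivalence."""

import math

import numpy as np
import pytest

import soilrisk as sr
from soilrisk.io_config import ValidationError
from soilrisk.monte_carlo import DistributionSpec, RiskModel, lognormal_from_moments

from conftest import make_table


@pytest.fixture(scope="module")
def p():
    return sr.load_exposure_parameters({})


@pytest.fixture(scope="module")
def tox():
    return sr.load_toxicity_profiles({})


@pytest.fixture(scope="module")
def as_table():
    rng = np.random.default_rng(99)
    return make_table(rng.uniform(10, 30, size=(36, 1)), ["As"], site_id="mono")


class TestSample:
    def test_point_mass(self):
        spec = DistributionSpec("x", "point", {"value": 7.0})
        np.testing.assert_array_equal(sr.sample(spec, 5, seed=0), np.full(5, 7.0))

    def test_lognormal_median_recovery(self):
        """Sample median within 2% of the closed-form lognormal median e^mu."""
        mu, sigma = 1.3, 0.6
        spec = DistributionSpec("x", "lognormal", {"mu": mu, "sigma": sigma})
        draws = sr.sample(spec, 100_000, seed=1)
        assert float(np.median(draws)) == pytest.approx(math.exp(mu), rel=0.02)

    def test_truncated_uniform_stays_inside(self):
        spec = DistributionSpec("x", "uniform", {"lower": 0.0, "upper": 1.0},
                                truncation=(0.4, 0.6))
        draws = sr.sample(spec, 1000, seed=2)
        assert draws.min() >= 0.4 and draws.max() <= 0.6

    def test_truncated_normal_moments(self):
        spec = DistributionSpec("bw", "normal", {"mean": 70.0, "sd": 14.0},
                                truncation=(40.0, 120.0))
        draws = sr.sample(spec, 50_000, seed=3)
        assert draws.min() >= 40.0 and draws.max() <= 120.0
        assert float(draws.mean()) == pytest.approx(70.0, rel=0.02)

    def test_triangular_support_and_mode_region(self):
        spec = DistributionSpec("ing", "triangular",
                                {"lower": 50.0, "mode": 100.0, "upper": 200.0})
        draws = sr.sample(spec, 50_000, seed=4)
        assert draws.min() >= 50.0 and draws.max() <= 200.0
        # closed-form triangular mean (a+b+c)/3
        assert float(draws.mean()) == pytest.approx((50 + 100 + 200) / 3, rel=0.02)

    def test_identical_seed_identical_draws(self):
        spec = DistributionSpec("x", "lognormal", {"mu": 0.0, "sigma": 1.0})
        np.testing.assert_array_equal(sr.sample(spec, 100, seed=5),
                                      sr.sample(spec, 100, seed=5))

    @pytest.mark.parametrize("family,params", [
        ("uniform", {"lower": 1.0, "upper": 1.0}),
        ("triangular", {"lower": 5.0, "mode": 1.0, "upper": 10.0}),
        ("normal", {"mean": 0.0, "sd": -1.0}),
        ("point", {"wrong": 1.0}),
    ])
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(ValidationError):
            DistributionSpec("x", family, params)


class TestBuildDefaultDistributions:
    def test_concentrations_lognormal_matched_and_truncated(self, moro_table, p, tox):
        specs = {s.name: s for s in sr.build_default_distributions(moro_table, p, tox)}
        x = moro_table.column("As")
        spec = specs["Cs_As"]
        assert spec.family == "lognormal"
        expected = lognormal_from_moments(float(x.mean()), float(x.std(ddof=1)))
        assert spec.params["mu"] == pytest.approx(expected["mu"])
        assert spec.params["sigma"] == pytest.approx(expected["sigma"])
        assert spec.truncation == (float(x.min()), float(x.max()))

    def test_body_weight_centred_on_70kg(self, moro_table, p, tox):
        specs = {s.name: s for s in sr.build_default_distributions(moro_table, p, tox)}
        assert specs["BW"].params["mean"] == 70.0
        assert specs["BW"].truncation == (40.0, 120.0)
        assert specs["IngRs"].family == "triangular"

    def test_constant_column_degrades_to_point(self, p, tox):
        table = make_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], ["As", "Cd"])
        with pytest.warns(UserWarning, match="zero-variance"):
            specs = {s.name: s for s in sr.build_default_distributions(table, p, tox)}
        assert specs["Cs_As"].family == "point"
        assert specs["Cs_As"].params["value"] == 5.0
        assert specs["Cs_Cd"].family == "lognormal"

    def test_slope_factors_are_point_masses(self, moro_table, p, tox):
        specs = {s.name: s for s in sr.build_default_distributions(moro_table, p, tox)}
        assert specs["SF_As"].family == "point"
        assert specs["SF_As"].params["value"] == tox["As"].SF_ing


class TestRunSimulation:
    def test_point_masses_reproduce_deterministic_pipeline_exactly(self, moro_table,
                                                                   p, tox):
        """Degenerate distributions collapse the simulation onto assess_site."""
        det = sr.assess_site(moro_table, p, tox)
        means = moro_table.means()
        specs = [DistributionSpec(f"Cs_{m}", "point", {"value": float(means[m])})
                 for m in moro_table.metals]
        specs += [DistributionSpec("BW", "point", {"value": p.BW}),
                  DistributionSpec("IngRs", "point", {"value": p.IngRs})]
        model = RiskModel(moro_table, p, tox)
        res = sr.run_simulation(specs, model, n_iterations=200, seed=0)
        for q in ("p5", "p50", "p95"):
            assert res.percentiles.loc["ILCR_total", q] == det.ilcr_total
        for m in det.ilcr_by_metal.index:
            assert res.percentiles.loc[f"ILCR_{m}", "p50"] == det.ilcr_by_metal[m]

    def test_scaled_lognormal_median_matches_closed_form(self, as_table, p, tox):
        """ILCR = Cs * k with Cs lognormal has median k * e^mu."""
        mu, sigma = 3.0, 0.4
        specs = [DistributionSpec("Cs_As", "lognormal", {"mu": mu, "sigma": sigma})]
        model = RiskModel(as_table, p, tox)
        res = sr.run_simulation(specs, model, n_iterations=20_000, seed=6)
        k = p.IngRs * p.EF * p.ED * p.CF / (p.BW * p.AT_ca) * tox["As"].SF_ing
        assert res.percentiles.loc["ILCR_total", "p50"] == pytest.approx(
            k * math.exp(mu), rel=0.03)

    def test_seed_determinism_bit_identical(self, moro_table, p, tox):
        model = RiskModel(moro_table, p, tox)
        specs = sr.build_default_distributions(moro_table, p, tox)
        a = sr.run_simulation(specs, model, n_iterations=2000, seed=13)
        b = sr.run_simulation(specs, model, n_iterations=2000, seed=13)
        assert a.percentiles.equals(b.percentiles)
        assert a.means.equals(b.means)
        for name in a.outputs:
            np.testing.assert_array_equal(a.outputs[name], b.outputs[name])

    def test_quantiles_monotone_and_outputs_nonnegative(self, moro_table, p, tox):
        model = RiskModel(moro_table, p, tox)
        specs = sr.build_default_distributions(moro_table, p, tox)
        res = sr.run_simulation(specs, model, n_iterations=2000, seed=1)
        for out, row in res.percentiles.iterrows():
            assert row["p5"] <= row["p50"] <= row["p95"]
            assert np.all(res.outputs[out] >= 0)
        assert ((res.exceedance >= 0) & (res.exceedance <= 1)).all().all()

    def test_median_converges_with_iterations(self, as_table, p, tox):
        specs = [DistributionSpec("Cs_As", "lognormal", {"mu": 3.0, "sigma": 0.4})]
        model = RiskModel(as_table, p, tox)
        small = sr.run_simulation(specs, model, n_iterations=10_000, seed=2)
        large = sr.run_simulation(specs, model, n_iterations=100_000, seed=3)
        assert small.percentiles.loc["ILCR_total", "p50"] == pytest.approx(
            large.percentiles.loc["ILCR_total", "p50"], rel=0.05)

    def test_jensen_gap_for_inverse_body_weight(self, as_table, p, tox):
        """With only BW uncertain, E[ILCR] exceeds the ILCR at the mean BW."""
        det = sr.assess_site(as_table, p, tox, pathways=("ingestion",))
        specs = [DistributionSpec("BW", "normal", {"mean": 70.0, "sd": 14.0},
                                  truncation=(20.0, 120.0))]
        model = RiskModel(as_table, p, tox)
        res = sr.run_simulation(specs, model, n_iterations=20_000, seed=4)
        assert res.means["ILCR_total"] > det.ilcr_total

    def test_spec_for_symbol_model_does_not_read_is_an_error(self, as_table, p, tox):
        model = RiskModel(as_table, p, tox)
        specs = [DistributionSpec("XYZ", "point", {"value": 1.0})]
        with pytest.raises(ValidationError, match="XYZ"):
            sr.run_simulation(specs, model, n_iterations=10, seed=0)

    def test_include_hi_adds_hazard_output(self, moro_table, p, tox):
        model = RiskModel(moro_table, p, tox, include_hi=True)
        res = sr.run_simulation([], model, n_iterations=50, seed=0)
        det = sr.assess_site(moro_table, p, tox, pathways=("ingestion",))
        assert res.percentiles.loc["HI", "p50"] == pytest.approx(det.hi, rel=1e-12)


class TestSummarizeSimulation:
    def test_order_statistics_oracle(self):
        draws = np.arange(1, 101, dtype=float) * 1e-6
        res = sr.summarize_simulation({"ILCR_total": draws})
        # numpy linear-interpolation median of 1..100 is 50.5
        assert res.percentiles.loc["ILCR_total", "p50"] == pytest.approx(5.05e-5)
        assert res.bands.loc["ILCR_total", "p50"] == "acceptable"

    def test_all_negligible_draws(self):
        res = sr.summarize_simulation({"ILCR_total": np.full(100, 5e-7)})
        assert (res.bands.loc["ILCR_total"] == "negligible").all()
        assert res.exceedance.loc["ILCR_total", "P_gt_1e-6"] == 0.0

    def test_requested_percentiles_are_ordered(self):
        rng = np.random.default_rng(0)
        res = sr.summarize_simulation({"x": rng.lognormal(size=1000)},
                                      percentiles=(5, 50, 95))
        row = res.percentiles.loc["x"]
        assert row["p5"] <= row["p50"] <= row["p95"]

    def test_empty_draws_rejected(self):
        with pytest.raises(ValidationError):
            sr.summarize_simulation({})
        with pytest.raises(ValidationError):
            sr.summarize_simulation({"x": np.array([])})
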