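import numpy as np
import pandas as pd
import pytest

import soilrisk as sr


@pytest.fixture(scope="session")
def moro_spec() -> sr.SiteSpec:
    return sr.load_site_spec("moro")


@pytest.fixture(scope="session")
def ifelodun_spec() -> sr.SiteSpec:
    return sr.load_site_spec("ifelodun")


@pytest.fixture(scope="session")
def moro_table(moro_spec) -> sr.ConcentrationTable:
    return sr.generate_site_samples(moro_spec, seed=7)


@pytest.fixture(scope="session")
def ifelodun_table(ifelodun_spec) -> sr.ConcentrationTable:
    return sr.generate_site_samples(ifelodun_spec, seed=7)


@pytest.fixture(scope="session")
def default_params() -> sr.ExposureParameters:
    return sr.load_exposure_parameters({})


@pytest.fixture(scope="session")
def default_tox():
    return sr.load_toxicity_profiles({})


def make_table(values, metals, site_id="test") -> sr.ConcentrationTable:
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, columns=metals,
                      index=[f"S{i+1}" for i in range(arr.shape[0])])
    return sr.ConcentrationTable(site_id=site_id, data=df)


@pytest.fixture(scope="session")
def random_tables():
    """A handful of seeded random tables for oracle comparisons."""
    rng = np.random.default_rng(2024)
    tables = []
    for k in range(5):
        n, m = rng.integers(5, 40), rng.integers(2, 8)
        vals = rng.lognormal(mean=2.0, sigma=0.8, size=(n, m))
        tables.append(make_table(vals, [f"M{j}" for j in range(m)], site_id=f"rand{k}"))
    return tables
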