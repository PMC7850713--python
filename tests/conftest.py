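import numpy as np
import pandas as pd
import pytest

from nutriscreen.classify import classify
from nutriscreen.cohort import prepare_cohort
from nutriscreen.synthetic import GeneratorConfig, make_synthetic_reference, simulate_dataset


@pytest.fixture(scope="session")
def refs():
    return make_synthetic_reference()


@pytest.fixture(scope="session")
def small_config():
    # two countries per region over three regions, three surveys each:
    # small enough for fast tests, deep enough to exercise every stratum level
    return GeneratorConfig(seed=11, n_surveys=3, clusters_per_survey=8, children_per_cluster=15)


@pytest.fixture(scope="session")
def small_dataset(small_config, refs):
    return simulate_dataset(small_config, refs)


@pytest.fixture(scope="session")
def small_cohort(small_dataset, refs, small_config):
    records, surveys = small_dataset
    children, report, retained = prepare_cohort(
        records, refs, min_surveys=1, surveys=surveys
    )
    return children, report, surveys


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    children, _, surveys = small_cohort
    return classify(children), surveys


def random_profiles(seed: int, n: int, countries=("A", "B")) -> pd.DataFrame:
    """Random case-profile input (scores drawn directly, not via anthropometry).

    Used by oracle-equivalence tests where classification and metric
    arithmetic are under test, not the scoring chain.
    """
    rng = np.random.default_rng(seed)
    children = pd.DataFrame(
        {
            "survey_id": rng.choice([f"{c}-S{i}" for c in countries for i in (1, 2)], n),
            "cluster_id": rng.integers(1, 10, n),
            "year": 2010,
            "sex": rng.choice(["f", "m"], n),
            "age_months": rng.uniform(6, 60, n),
            "muac_mm": rng.uniform(95, 170, n),
            "oedema": rng.random(n) < 0.01,
            "whz": rng.normal(-0.9, 1.2, n),
            "haz": rng.normal(-1.3, 1.2, n),
            "waz": rng.normal(-1.3, 1.2, n),
        }
    )
    children["country"] = children["survey_id"].str.slice(0, 1)
    return children
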