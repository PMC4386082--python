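from pathlib import Path

import pytest

from phenoseverity.epsi import compute_epsi
from phenoseverity.forest import feature_matrix, fit_unsupervised_forest
from phenoseverity.measures import build_profiles
from phenoseverity.synthetic import GeneratorConfig, generate_cohort, worked_fixture

DATA = Path(__file__).parent / "data"

# a reduced cohort for unit tests: same structure as the default study
# conditions, scaled down so the whole suite stays fast
SMALL = GeneratorConfig(n_patients=400, n_phenotypes=80, seed=11)


@pytest.fixture(scope="session")
def fixture_cohort():
    return worked_fixture()


@pytest.fixture(scope="session")
def golden_profiles_path():
    return DATA / "golden_severity_profiles.csv"


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return build_profiles(
        small_cohort.tables, codes=small_cohort.truth["phenotype_code"]
    )


@pytest.fixture(scope="session")
def small_features(small_cohort, small_profiles):
    scores = compute_epsi(small_profiles)
    return feature_matrix(small_profiles, scores)


@pytest.fixture(scope="session")
def small_model(small_features):
    return fit_unsupervised_forest(small_features, n_trees=200, seed=11)
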