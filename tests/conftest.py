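import pytest

from endovalid.cohort_io import RunConfig
from endovalid.claims_processing import test_labels as derive_test_labels
from endovalid.surgical_typology import reference_labels
from endovalid.synthetic_cohort import generate_fixture_small


@pytest.fixture(scope="session")
def fixture_cohort():
    return generate_fixture_small()


@pytest.fixture()
def config():
    return RunConfig(rng_seed=20240001)


@pytest.fixture(scope="session")
def fixture_labels(fixture_cohort):
    records, claims = fixture_cohort
    surgery_dates = {r.participant_id: r.surgery_date for r in records}
    cfg = RunConfig(rng_seed=20240001)
    return reference_labels(records), derive_test_labels(claims, surgery_dates, cfg)
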