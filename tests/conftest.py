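import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cvwtp
from cvwtp.survey_io import Certainty

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_record(
    rid="r1",
    participates=1,
    grid=(5, 5, 4, 3, 2, 1, 1, 1, 1),
    **overrides,
):
    """Minimal valid respondent for I/O tests."""
    items = {c: 3 for c in cvwtp.survey_io.ITEM_COLUMNS}
    items.update(overrides.pop("items", {}))
    fields = dict(
        seen=0,
        age=40.0,
        gender=1,
        education=0,
        income=15.0,
        consumptive=1,
        nonconsumptive=2,
    )
    fields.update(overrides)
    return cvwtp.RespondentRecord(
        id=rid,
        participates=participates,
        certainty_grid=(
            tuple(Certainty(c) for c in grid)
            if participates and grid is not None
            else None
        ),
        items=items,
        **fields,
    )


@pytest.fixture(scope="session")
def survey500():
    """One default synthetic survey at the study's sample size."""
    config = cvwtp.SimulationConfig(n=500, seed=42)
    records, covariates, truth = cvwtp.simulate_survey(config)
    return config, records, covariates, truth


@pytest.fixture(scope="session")
def pipeline_report_2000():
    """Full end-to-end run on a large synthetic survey with known truth."""
    config = cvwtp.PipelineConfig(
        simulation=cvwtp.SimulationConfig(n=2000, seed=7),
        bootstrap_b=120,
        seed=3,
    )
    return config, cvwtp.run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
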