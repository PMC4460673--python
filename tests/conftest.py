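import warnings

import pytest

import methtriage as mt

# the tissue-contrast fallback warning is exercised deliberately in tests
warnings.filterwarnings("ignore", message="gene .*: no direction")


@pytest.fixture(scope="session")
def paper_scenario():
    return mt.paper_like_scenario(seed=0)


@pytest.fixture(scope="session")
def paper_cohort(paper_scenario):
    return mt.simulate.simulate_cohort(paper_scenario)


@pytest.fixture(scope="session")
def paper_report(paper_cohort):
    return mt.run_pipeline_frames(paper_cohort.to_pipeline_inputs(), seed=0)
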