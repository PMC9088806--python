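import pytest

from mevsim import sim_engine


@pytest.fixture(scope="session")
def wc_scenario():
    return sim_engine.worst_case_scenario()


@pytest.fixture(scope="session")
def wc_result(wc_scenario):
    return sim_engine.run(wc_scenario)


@pytest.fixture(scope="session")
def wc_summary(wc_result):
    return sim_engine.summarize(wc_result)
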