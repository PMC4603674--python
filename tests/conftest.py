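import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def share_table():
    from cogtrend.fixtures import paper_share_table

    return paper_share_table()


@pytest.fixture(scope="session")
def optimistic_models():
    from cogtrend.fixtures import OPTIMISTIC, paper_models

    return paper_models(OPTIMISTIC)


@pytest.fixture(scope="session")
def pessimistic_models():
    from cogtrend.fixtures import PESSIMISTIC, paper_models

    return paper_models(PESSIMISTIC)
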