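import pytest

from ontoppi.fixtures import FixtureSpec, generate_fixture, worked_example_fixture
from ontoppi.pipeline import run_pipeline


@pytest.fixture(scope="session")
def worked_bundle(tmp_path_factory):
    return worked_example_fixture(tmp_path_factory.mktemp("worked"))


@pytest.fixture(scope="session")
def worked_result(worked_bundle):
    return run_pipeline(worked_bundle.directory)


def make_random_bundle(tmp_path, seed, **overrides):
    spec = FixtureSpec(seed=seed, **overrides)
    return spec, generate_fixture(spec, tmp_path / f"bundle_{seed}")


@pytest.fixture(scope="session")
def random_bundle(tmp_path_factory):
    """One medium two-source-overlap bundle shared across read-only tests."""
    spec = FixtureSpec(seed=7, shared_publication_rate=0.5)
    return spec, generate_fixture(spec, tmp_path_factory.mktemp("rand") / "b7")


@pytest.fixture(scope="session")
def random_result(random_bundle):
    _, bundle = random_bundle
    return run_pipeline(bundle.directory)
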