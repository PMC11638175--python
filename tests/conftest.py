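import pytest

from scbroker import broker, faang, fixtures


@pytest.fixture(scope="session")
def rules():
    return faang.default_ruleset()


@pytest.fixture(scope="session")
def spec():
    return fixtures.FixtureSpec()


@pytest.fixture()
def submission(spec):
    return fixtures.make_submission(spec)


@pytest.fixture()
def toy_submission():
    """Minimal submission: 1 organism, 1 specimen, 1 experiment, 2 fastq files."""
    sub, project = fixtures.make_submission(fixtures.FixtureSpec(n_donors=1))
    return sub, project


@pytest.fixture()
def fixture_graph(submission, rules):
    sub, project = submission
    return broker.convert(sub, rules, project).graph


@pytest.fixture()
def toy_graph(toy_submission, rules):
    sub, project = toy_submission
    return broker.convert(sub, rules, project).graph


@pytest.fixture(scope="session")
def expression(spec):
    return fixtures.make_expression(spec)


@pytest.fixture(scope="session")
def annotation(spec):
    return fixtures.make_annotation(spec)
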