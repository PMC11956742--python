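import pytest

from sixframe import synthfix
from sixframe.sample_genome import apply_variants


@pytest.fixture(scope="session")
def funnel_fixture():
    return synthfix.build_scenario("funnel", seed=1)


@pytest.fixture(scope="session")
def funnel_sample(funnel_fixture):
    passing = [v for v in funnel_fixture.variants if v.p_value < funnel_fixture.p_threshold]
    return apply_variants(funnel_fixture.reference, passing)


@pytest.fixture(scope="session")
def basic_fixture():
    return synthfix.build_scenario("basic", seed=7)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path
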