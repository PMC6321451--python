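import pytest

from premotif.fixtures import FixtureSpec, build_fixture
from premotif.structure_regions import annotate_regions


@pytest.fixture(scope="session")
def planted_loop_fixture():
    """6 stem-loops, GGAG planted into the terminal loop of the first 2."""
    return build_fixture(
        FixtureSpec(n_precursors=6, planted_motif="GGAG", planted_fraction=1 / 3, seed=7)
    )


@pytest.fixture(scope="session")
def planted_loop_annotations(planted_loop_fixture):
    return annotate_regions(planted_loop_fixture.db)


@pytest.fixture(scope="session")
def plain_fixture():
    """10 clean two-arm stem-loops with no planted motif."""
    return build_fixture(FixtureSpec(n_precursors=10, seed=21))


@pytest.fixture(scope="session")
def plain_annotations(plain_fixture):
    return annotate_regions(plain_fixture.db)
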