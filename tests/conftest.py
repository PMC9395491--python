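import pytest

from callocations import Repertoire, build_paper_dataset, tabulate_bigrams


@pytest.fixture(scope="session")
def se_table():
    """Count table of the small exclusive benchmark corpus (16 pairs)."""
    return tabulate_bigrams(build_paper_dataset("SE"))


@pytest.fixture(scope="session")
def le_table():
    """Count table of the large exclusive benchmark corpus (160 pairs)."""
    return tabulate_bigrams(build_paper_dataset("LE"))


@pytest.fixture
def small_repertoire():
    return Repertoire(("A", "B", "C", "D"))
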