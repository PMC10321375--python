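import pytest

from guidecraft.fixtures import random_genome
from guidecraft.genome_index import build_index
from guidecraft.offtarget import table_for_model
from guidecraft.pam_models import get_model, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def spcas9():
    return get_model("SpCas9-NGG")


@pytest.fixture(scope="session")
def cas12a():
    return get_model("Cas12a-TTTV")


@pytest.fixture(scope="session")
def penalty_table(spcas9):
    return table_for_model(spcas9)


@pytest.fixture(scope="session")
def small_genome():
    """20-kb single-record random genome shared by cheap tests."""
    return random_genome(1, [20_000], gc=0.45, seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome, spcas9):
    return build_index(small_genome, spcas9)


def pick_edit(spacer: str, pos: int) -> tuple[int, str]:
    """A deterministic base change at 1-based ``pos`` of the spacer."""
    cur = spacer[pos - 1]
    return pos, "A" if cur != "A" else "C"
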