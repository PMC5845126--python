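import numpy as np
import pytest

from rxngrow.fixtures import (
    POCKET_LIBRARY_IDS,
    make_block_library,
    make_pocket,
    make_reaction_set,
)
from rxngrow.rule_extraction import build_rule_db


@pytest.fixture(scope="session")
def reaction_set():
    return make_reaction_set()


@pytest.fixture(scope="session")
def library():
    return make_block_library()


@pytest.fixture(scope="session")
def rule_db(reaction_set, library):
    db = build_rule_db(reaction_set)
    db.build_block_index(library)
    return db


@pytest.fixture(scope="session")
def pocket():
    # uniqueness verification is exercised separately (acceptance suite)
    return make_pocket(seed=0, verify=False)


@pytest.fixture(scope="session")
def pocket_library(library):
    return [b for b in library if b.id in POCKET_LIBRARY_IDS]


@pytest.fixture(scope="session")
def pocket_db(reaction_set, pocket_library):
    db = build_rule_db(reaction_set)
    db.build_block_index(pocket_library)
    return db


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
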