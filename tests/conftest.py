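"""Shared fixtures: session-cached model collections and ordinations.

Building a model compiles sympy expressions; caching the fixture
collections keeps the suite fast without changing any test semantics.
"""

import pytest

from morphosurf import assemble_table, fixture_collection, ordinate


@pytest.fixture(scope="session")
def mollusk_collection():
    return fixture_collection("mollusk_echinoid")


@pytest.fixture(scope="session")
def mollusk_table(mollusk_collection):
    return assemble_table(mollusk_collection.models)


@pytest.fixture(scope="session")
def mollusk_space(mollusk_table):
    return ordinate(mollusk_table)
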