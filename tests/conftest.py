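import pytest

from biorgroup import GenericMolecule, ingest_library
from biorgroup.fixtures import FixtureSpec, fig2a_fixture, generate_fixture


@pytest.fixture(scope="session")
def fig2a():
    return fig2a_fixture(seed=1)


@pytest.fixture(scope="session")
def fig2a_store(fig2a):
    store, _ = ingest_library(fig2a.library)
    return store


@pytest.fixture(scope="session")
def fig2a_query(fig2a):
    ident, smiles = fig2a.queries[0]
    return GenericMolecule.from_smiles(smiles, [ident])


@pytest.fixture(scope="session")
def mixed_fixture():
    """Three single-site scaffolds with every candidate category planted."""
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def mixed_store(mixed_fixture):
    store, _ = ingest_library(mixed_fixture.library)
    return store


def pairs_with_truth(fixture_set):
    """(query, candidate smiles, expected label) triples from ground truth."""
    library = dict(fixture_set.library)
    queries = {
        smiles: GenericMolecule.from_smiles(smiles, [ident])
        for ident, smiles in fixture_set.queries
    }
    for (query_smiles, cid), label in sorted(fixture_set.ground_truth.labels.items()):
        yield queries[query_smiles], library[cid], label
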