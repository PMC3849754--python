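import pytest

from molvault import FixtureSpec, NormalizationPolicy, generate_corpus, import_file
from molvault.store import open_store


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Shared synthetic corpus: 300 entries, 30% duplicates, 10% salts."""
    out = tmp_path_factory.mktemp("corpus")
    spec = FixtureSpec(n_molecules=300, duplicate_rate=0.3, salt_rate=0.1,
                       seed=11)
    return generate_corpus(spec, out)


@pytest.fixture(scope="session")
def populated(tmp_path_factory, corpus):
    """Store with the shared corpus imported from both file formats.

    Tests may add sets (unique names) but must not delete molecules.
    """
    db = tmp_path_factory.mktemp("db") / "shared.db"
    store = open_store(db)
    smi_report = import_file(store, corpus.smiles_path, "smiles",
                             NormalizationPolicy())
    sdf_report = import_file(store, corpus.sdf_path, "sdf",
                             NormalizationPolicy())
    store.create_set("all", [r[0] for r in
                             store.db.execute("SELECT mol_key FROM molecule")])
    yield store, corpus, smi_report, sdf_report
    store.close()


@pytest.fixture
def fresh_store(tmp_path):
    store = open_store(tmp_path / "fresh.db")
    yield store
    store.close()
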