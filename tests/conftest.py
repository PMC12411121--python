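import pytest

from faersnorm.fixtures import generate_vocabulary
from faersnorm.vocab import load_vocab


@pytest.fixture(scope="session")
def vocab_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("vocab")
    generate_vocabulary(path, seed=1)
    return path


@pytest.fixture(scope="session")
def ledger(tmp_path_factory):
    path = tmp_path_factory.mktemp("vocab_ledger")
    return generate_vocabulary(path, seed=1)


@pytest.fixture(scope="session")
def index(vocab_dir):
    return load_vocab(vocab_dir)


def concept_by_name(index, name):
    """The unique concept matched by a (preferred or synonym) name."""
    hits = index.lookup_exact(name)
    assert len(hits) == 1, f"{name!r} matched {len(hits)} concepts"
    return next(iter(hits))
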