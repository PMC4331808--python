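import pytest

from fpe.io_prep import CleanSequence
from fpe.mining import MiningParams
from fpe.testdata import reconstruct_example_block


@pytest.fixture(scope="session")
def example_block():
    """The 20-base worked-example block (ATGGTGCATCTGACTCCTGA)."""
    return reconstruct_example_block()


@pytest.fixture(scope="session")
def mining_params_22():
    return MiningParams(s_min=2, l_min=2)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, body) pairs; returns the path."""

    def _write(records, name="test.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, body in records:
                fh.write(f">{rec_id}\n{body}\n")
        return path

    return _write


@pytest.fixture
def clean_seq():
    def _make(bases, seq_id="s"):
        return CleanSequence(id=seq_id, bases=bases)

    return _make
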