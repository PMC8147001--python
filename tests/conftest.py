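import numpy as np
import pytest

from evorate.simulate import make_paper_like_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated study dataset shared across tests (seed fixed)."""
    return make_paper_like_dataset(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def write_fasta_text(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


@pytest.fixture()
def fasta_writer(tmp_path):
    def _write(records, name="locus.fasta"):
        path = tmp_path / name
        write_fasta_text(path, records)
        return path

    return _write
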