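import numpy as np
import pytest

from dpicdf import generate_synthetic_dataset, synthesize_pssms


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, sequence) pairs."""

    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{i}\n{s}\n" for i, s in entries))
        return path

    return _write


@pytest.fixture(scope="session")
def small_dataset():
    """20 + 20 synthetic sequences with the default class composition bias."""
    return generate_synthetic_dataset(20, 20, (40, 120), seed=101)


@pytest.fixture(scope="session")
def small_pssms(small_dataset):
    return synthesize_pssms(small_dataset, seed=101)
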