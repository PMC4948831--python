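import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from qirnaforest.seqio import SequenceRecord, SequenceSet, from_strings
from qirnaforest.synthetic import GeneratorSpec, generate, generate_pool


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def small_set():
    return from_strings(["UUAGGCAUCGAUCGAUACGA", "ACGUACGUACGUACGUACGU"], label="positive")


@pytest.fixture(scope="session")
def default_data():
    """155+155 synthetic sequences with the default positional signal."""
    return generate(GeneratorSpec(seed=7))


@pytest.fixture(scope="session")
def background_pool():
    return generate_pool(n_sequences=10, length=600, seed=3)
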