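import numpy as np
import pytest

from homolarray.fixtures import random_dna, toy_transcripts
from homolarray.sequence_io import TranscriptRecord


@pytest.fixture(scope="session")
def toy_sets():
    """The packaged deterministic 5 + 3 gene toy dataset."""
    return toy_transcripts(seed=0)


@pytest.fixture(scope="session")
def random_gene_set():
    """50 unrelated random transcripts, 300-700 bp, fixed seed."""
    rng = np.random.default_rng(42)
    return [
        TranscriptRecord(f"g{i:03d}", "A", random_dna(rng, int(rng.integers(300, 700))))
        for i in range(50)
    ]
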