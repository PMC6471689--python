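import random

import pytest

from kmerflow.fixtures import FixtureSpec, generate_records
from kmerflow.seq_io import write_fasta


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def uniform_fasta(tmp_path):
    """A small uniform-random FASTA file on disk; returns (path, records)."""
    spec = FixtureSpec(n_records=40, length=(60, 140), ambiguity_rate=0.01, seed=11)
    records = generate_records(spec)
    path = tmp_path / "uniform.fa"
    write_fasta(records, path)
    return path, records
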