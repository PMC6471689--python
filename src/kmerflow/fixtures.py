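"""Deterministic synthetic FASTA/FASTQ inputs for tests and benchmarks.

Two generators: uniform i.i.d. reads (with a GC dial and optional N
injection) for oracle-equivalence checks, and motif-skewed reads in which a
fraction of each read is tandem copies of one motif. Repeated substrings
share a signature, so the skewed fixture reproduces the "big bins" workload
imbalance that the LPT partitioner exists to fix. Generation is a pure
function of the spec (same spec, same bytes).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ParameterError
from .seq_io import SequenceRecord, write_fasta, write_fastq


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic read set.

    length is a fixed read length or an inclusive (min, max) range;
    gc is the expected G+C fraction; skew_fraction of each read's bases
    come from tandem copies of skew_motif; ambiguity_rate replaces bases
    with N after composition is drawn.
    """

    n_records: int
    length: int | tuple[int, int]
    gc: float = 0.5
    skew_motif: str | None = None
    skew_fraction: float = 0.0
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = self.length if isinstance(self.length, int) else self.length[0]
        if self.n_records < 0 or lo < 1:
            raise ParameterError("need n_records >= 0 and lengths >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise ParameterError("gc must be in [0, 1]")
        if not 0.0 <= self.skew_fraction < 1.0:
            raise ParameterError("skew_fraction must be in [0, 1)")
        if not 0.0 <= self.ambiguity_rate < 1.0:
            raise ParameterError("ambiguity_rate must be in [0, 1)")
        if self.skew_motif is not None and set(self.skew_motif) - set("ACGT"):
            raise ParameterError("skew_motif must be over ACGT")


def _read_length(spec: FixtureSpec, rng: random.Random) -> int:
    if isinstance(spec.length, int):
        return spec.length
    return rng.randint(spec.length[0], spec.length[1])


def _uniform_bases(n: int, gc: float, rng: random.Random) -> list[str]:
    bases = []
    for _ in range(n):
        if rng.random() < gc:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "T")
    return bases


def _inject_ns(bases: list[str], rate: float, rng: random.Random) -> None:
    if rate > 0.0:
        for i in range(len(bases)):
            if rng.random() < rate:
                bases[i] = "N"


def generate_records(spec: FixtureSpec) -> list[SequenceRecord]:
    """Materialize the read set described by a FixtureSpec."""
    rng = random.Random(spec.seed)
    records = []
    for idx in range(spec.n_records):
        n = _read_length(spec, rng)
        bases = _uniform_bases(n, spec.gc, rng)
        if spec.skew_motif is not None and spec.skew_fraction > 0.0:
            # overwrite a contiguous block with tandem motif copies at a
            # random phase and position, so minimizer skew arises from
            # repeated substrings rather than duplicated reads
            span = round(spec.skew_fraction * n)
            if span > 0:
                start = rng.randint(0, n - span)
                phase = rng.randrange(len(spec.skew_motif))
                motif = spec.skew_motif
                for j in range(span):
                    bases[start + j] = motif[(phase + j) % len(motif)]
        _inject_ns(bases, spec.ambiguity_rate, rng)
        records.append(SequenceRecord(id=f"read{idx}", seq="".join(bases)))
    return records


def generate_uniform(spec: FixtureSpec, path) -> None:
    """Write a uniform-random FASTA fixture (spec must carry no motif)."""
    if spec.skew_motif is not None:
        raise ParameterError("uniform fixture must not carry a skew motif")
    write_fasta(generate_records(spec), path)


def generate_skewed(spec: FixtureSpec, path) -> None:
    """Write a motif-skewed FASTA fixture reproducing signature skew."""
    if spec.skew_motif is None:
        raise ParameterError("skewed fixture needs a skew_motif")
    write_fasta(generate_records(spec), path)


def generate_fastq(spec: FixtureSpec, path) -> None:
    """Write the fixture as 4-line FASTQ (placeholder qualities)."""
    write_fastq(generate_records(spec), path)
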