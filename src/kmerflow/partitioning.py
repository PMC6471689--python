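"""Job-to-partition mapping: hash baseline and LPT scheduling.

Routing all superkmers of one signature to one partition makes counting
embarrassingly parallel, but signature workloads are highly skewed; treating
each job (a signature, or a hashed bin of signatures) as a task with
processing time equal to its k-mer count turns placement into multiprocessor
scheduling (MPS). MPS is NP-hard, so the longest-processing-time (LPT)
greedy is used: sort jobs by size descending, always assign to the
least-loaded machine; its makespan is at most (4/3 - 1/(3t)) times optimal.
Job sizes are estimated from a Bernoulli sample of the input (default 1%).
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ParameterError
from .superkmer import Signature, clean_fragments, split_superkmers

_MASK64 = (1 << 64) - 1

#: Number of hashed signature bins when granularity="bin".
DEFAULT_BINS = 8192
#: Default fraction of input records sampled to estimate job sizes.
DEFAULT_SAMPLE_FRACTION = 0.01


def mix64(x: int) -> int:
    """64-bit shift/multiply integer finalizer (splitmix64 constants).

    Bijective on 64-bit integers, with strong avalanche; used both to
    scatter signatures into bins and as the baseline hash partitioner.
    """
    z = x & _MASK64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _MASK64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return z


def job_key_to_partition_hash(sig: Signature, B: int) -> int:
    """Map a signature to one of B bins via mix64 of its packed value."""
    if B < 1:
        raise ParameterError("B must be >= 1")
    return mix64(sig.value()) % B


def job_key(sig: Signature, granularity: str, B: int = DEFAULT_BINS):
    """The scheduling job key for a signature: the m-mer string at signature
    granularity, or its hashed bin id at bin granularity."""
    if granularity == "signature":
        return sig.mmer
    if granularity == "bin":
        return job_key_to_partition_hash(sig, B)
    raise ParameterError(f"unknown granularity: {granularity!r}")


def _key_to_int(key) -> int:
    if isinstance(key, int):
        return key
    from .encoding import pack_value

    return pack_value(key)


@dataclass
class JobSizeMap:
    """Estimated k-mer count per job (signature or bin id)."""

    sizes: dict
    granularity: str

    def total(self) -> float:
        return sum(self.sizes.values())


@dataclass
class Schedule:
    """A job -> partition assignment over t partitions.

    Jobs never seen when the schedule was built fall back to the hash
    partitioner modulo t, so every possible key has a partition.
    """

    assignment: dict
    t: int
    makespan: float = 0.0
    loads: list = field(default_factory=list)

    def partition_of(self, key) -> int:
        p = self.assignment.get(key)
        if p is None:
            p = mix64(_key_to_int(key)) % self.t
        return p

    def write_tsv(self, path) -> None:
        with open(path, "w") as out:
            for key in sorted(self.assignment):
                out.write(f"{key}\t{self.assignment[key]}\n")


def hash_schedule(keys: Iterable, t: int) -> Schedule:
    """The baseline size-oblivious partitioner: mix64(key) mod t."""
    if t < 1:
        raise ParameterError("t must be >= 1")
    return Schedule(
        assignment={key: mix64(_key_to_int(key)) % t for key in keys}, t=t
    )


def estimate_job_sizes(
    records,
    fraction: float,
    seed: int,
    k: int,
    m: int,
    granularity: str = "signature",
    B: int = DEFAULT_BINS,
) -> JobSizeMap:
    """Estimate per-job k-mer counts from a Bernoulli record sample.

    Each record is kept independently with probability ``fraction`` under
    a seeded generator; kept records are cleaned, split into superkmers,
    and each job accumulates its carried k-mer count. Accumulated counts
    are scaled by 1/fraction, giving an unbiased estimate of the full-data
    job sizes. ``fraction=1.0`` is an exact census.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("sample fraction must be in (0, 1]")
    rng = random.Random(seed)
    sizes: dict = {}
    for rec in records:
        if fraction < 1.0 and rng.random() >= fraction:
            continue
        for frag in clean_fragments(rec.seq):
            for sk in split_superkmers(frag, k, m):
                key = job_key(sk.signature, granularity, B)
                sizes[key] = sizes.get(key, 0) + sk.n_kmers
    if fraction < 1.0:
        sizes = {key: cnt / fraction for key, cnt in sizes.items()}
    return JobSizeMap(sizes=sizes, granularity=granularity)


def lpt_schedule(sizes: JobSizeMap | Mapping, t: int) -> Schedule:
    """Longest-processing-time schedule of jobs onto t partitions.

    Jobs are sorted by size descending (ties by ascending key, for
    determinism) and each is placed on the currently least-loaded
    partition, lowest index winning ties.
    """
    if t < 1:
        raise ParameterError("t must be >= 1")
    mapping = sizes.sizes if isinstance(sizes, JobSizeMap) else sizes
    order = sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))
    heap = [(0.0, p) for p in range(t)]  # already heap-ordered
    assignment = {}
    for key, size in order:
        load, p = heapq.heappop(heap)
        assignment[key] = p
        heapq.heappush(heap, (load + size, p))
    loads = [0.0] * t
    for key, size in mapping.items():
        loads[assignment[key]] += size
    return Schedule(
        assignment=assignment, t=t, makespan=max(loads, default=0.0), loads=loads
    )


def brute_force_opt(sizes: list, t: int) -> float:
    """Exact minimum makespan by pruned exhaustive search (test oracle).

    Refuses instances beyond 14 jobs or 4 machines: MPS is NP-hard and the
    search is exponential.
    """
    n = len(sizes)
    if n > 14 or t > 4:
        raise ParameterError("instance too large for exhaustive search")
    if t < 1:
        raise ParameterError("t must be >= 1")
    if n == 0:
        return 0.0
    jobs = sorted(sizes, reverse=True)
    best = sum(jobs)  # single-machine upper bound
    loads = [0.0] * t

    def dfs(i: int) -> None:
        nonlocal best
        if i == n:
            best = min(best, max(loads))
            return
        seen = set()
        for p in range(t):
            if loads[p] in seen:  # identical loads are symmetric
                continue
            seen.add(loads[p])
            if loads[p] + jobs[i] >= best:
                continue
            loads[p] += jobs[i]
            dfs(i + 1)
            loads[p] -= jobs[i]

    dfs(0)
    return best
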