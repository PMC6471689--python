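"""Hash binning, sampled job-size estimation, LPT scheduling."""

import math
import random

import pytest
from scipy import stats

from kmerflow.errors import ParameterError
from kmerflow.fixtures import FixtureSpec, generate_records
from kmerflow.partitioning import (
    JobSizeMap,
    brute_force_opt,
    estimate_job_sizes,
    hash_schedule,
    job_key_to_partition_hash,
    lpt_schedule,
    mix64,
)
from kmerflow.superkmer import Signature, clean_fragments


class TestMix64:
    def test_zero_is_fixed_point(self):
        assert mix64(0) == 0

    def test_regression_constant(self):
        # frozen from a one-time evaluation of the xor-shift/multiply chain
        assert mix64(1) == 6238072747940578789

    def test_uniform_over_64_buckets(self):
        """Bucketed hashes of consecutive integers pass a chi-square
        uniformity test at alpha = 0.01."""
        n, buckets = 100_000, 64
        observed = [0] * buckets
        for x in range(n):
            observed[mix64(x) % buckets] += 1
        _, pvalue = stats.chisquare(observed)
        assert pvalue > 0.01


class TestSignatureBinning:
    def test_deterministic_and_in_range(self):
        sig = Signature(mmer="CGTGCGTGCG", allowed=True)
        assert job_key_to_partition_hash(sig, 1) == 0
        b1 = job_key_to_partition_hash(sig, 8192)
        assert b1 == job_key_to_partition_hash(sig, 8192)
        assert 0 <= b1 < 8192
        with pytest.raises(ParameterError):
            job_key_to_partition_hash(sig, 0)

    def test_bin_loads_near_uniform(self):
        """Random signatures over B=8192 bins land near-uniformly: at mean
        occupancy ~12 the max/mean load ratio stays below 3 (the
        balls-in-bins maximum concentrates once bins are well filled)."""
        rng = random.Random(23)
        B, n = 8192, 100_000
        loads = [0] * B
        for _ in range(n):
            sig = Signature(
                mmer="".join(rng.choice("ACGT") for _ in range(10)), allowed=True
            )
            loads[job_key_to_partition_hash(sig, B)] += 1
        assert max(loads) / (n / B) < 3


class TestEstimator:
    def test_full_fraction_is_exact_census(self, uniform_fasta):
        _, records = uniform_fasta
        full = estimate_job_sizes(records, 1.0, seed=0, k=15, m=5)
        again = estimate_job_sizes(records, 1.0, seed=99, k=15, m=5)
        assert full.sizes == again.sizes  # census ignores the seed
        assert full.total() == sum(
            max(len(f) - 15 + 1, 0)
            for r in records
            for f in clean_fragments(r.seq)
        )

    def test_empty_input_empty_map(self):
        assert estimate_job_sizes([], 0.5, seed=1, k=15, m=5).sizes == {}

    def test_bad_fraction_rejected(self):
        for frac in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                estimate_job_sizes([], frac, seed=1, k=15, m=5)

    def test_subsample_estimate_unbiased(self):
        """Mean estimated total over many seeds at 10% sampling is within
        2% of the true total k-mer count."""
        spec = FixtureSpec(n_records=1000, length=100, seed=42)
        records = generate_records(spec)
        truth = estimate_job_sizes(records, 1.0, seed=0, k=28, m=10).total()
        estimates = [
            estimate_job_sizes(records, 0.1, seed=s, k=28, m=10).total()
            for s in range(100)
        ]
        mean = sum(estimates) / len(estimates)
        assert abs(mean - truth) / truth < 0.02


class TestLPT:
    def test_classic_gap_instance(self):
        """[5,4,3,3,3] on 2 machines: LPT makespan 10 vs optimum 9; the
        ratio 10/9 respects the (4/3 - 1/(3t)) bound."""
        sizes = dict(enumerate([5, 4, 3, 3, 3]))
        sched = lpt_schedule(sizes, 2)
        assert sched.makespan == 10
        assert brute_force_opt([5, 4, 3, 3, 3], 2) == 9
        assert 10 / 9 <= 4 / 3 - 1 / 6

    def test_single_machine_and_few_jobs(self):
        assert lpt_schedule({0: 3, 1: 7, 2: 2}, 1).makespan == 12
        assert lpt_schedule({0: 4, 1: 4}, 4).makespan == 4

    def test_deterministic_tie_break(self):
        a = lpt_schedule({"x": 5, "y": 5, "z": 5}, 2).assignment
        b = lpt_schedule({"x": 5, "y": 5, "z": 5}, 2).assignment
        assert a == b

    def test_schedule_totality_and_lower_bound(self):
        rng = random.Random(3)
        for _ in range(50):
            sizes = {i: rng.randint(1, 100) for i in range(rng.randint(1, 20))}
            t = rng.randint(1, 6)
            sched = lpt_schedule(sizes, t)
            assert set(sched.assignment) == set(sizes)
            assert all(0 <= p < t for p in sched.assignment.values())
            assert sum(sched.loads) == sum(sizes.values())
            assert sched.makespan >= max(
                max(sizes.values()), math.ceil(sum(sizes.values()) / t)
            )

    def test_lpt_within_bound_of_optimum(self):
        """Random small instances: LPT makespan <= (4/3 - 1/(3t)) * OPT."""
        rng = random.Random(8)
        for _ in range(300):
            n, t = rng.randint(1, 12), rng.randint(1, 4)
            sizes = [rng.randint(1, 100) for _ in range(n)]
            opt = brute_force_opt(sizes, t)
            lpt = lpt_schedule(dict(enumerate(sizes)), t).makespan
            assert opt <= lpt <= (4 / 3 - 1 / (3 * t)) * opt + 1e-9

    def test_brute_force_guard_and_trivia(self):
        assert brute_force_opt([7], 3) == 7
        assert brute_force_opt([5] * 6, 3) == 10
        with pytest.raises(ParameterError):
            brute_force_opt(list(range(20)), 2)
        with pytest.raises(ParameterError):
            brute_force_opt([1, 2], 5)


def test_lpt_beats_hash_on_skewed_jobs():
    """With one job holding 30% of the mass, size-aware LPT placement
    yields a makespan no worse than the size-oblivious hash partitioner."""
    rng = random.Random(12)
    total = 10_000
    sizes = {0: int(0.3 * total)}
    rest = total - sizes[0]
    for i in range(1, 60):
        sizes[i] = rest // 59
    for t in (2, 4, 8):
        lpt = lpt_schedule(sizes, t).makespan
        hashed = hash_schedule(sizes, t)
        loads = [0] * t
        for key, size in sizes.items():
            loads[hashed.partition_of(key)] += size
        assert lpt <= max(loads)


def test_job_size_map_invariants():
    m = JobSizeMap(sizes={"ACG": 4, "CGT": 0.5}, granularity="signature")
    assert m.total() == 4.5
    assert all(v >= 0 for v in m.sizes.values())
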