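# kmerflow

Load-balanced, two-stage k-mer counting for DNA sequence collections
(reads or genome fragments in FASTA/FASTQ), built around signature-based
superkmer partitioning and a multiprocessor-scheduling partitioner.

## The problem and the method

A sequence of length *n* contains *n − k + 1* overlapping k-mers; counting
them window by window materializes (*n − k + 1*)·*k* symbols, an almost
k-fold redundancy that dominates memory and shuffle traffic in any
partitioned counter. kmerflow avoids it in the standard way and then fixes
the load-imbalance this creates:

1. **Superkmers.** Every k-mer's *signature* is its lexicographically
   smallest canonical m-mer (default m = 10) restricted to an allowed set:
   m-mers starting with `AAA` or `ACA`, or containing `AA` past the first
   position, are excluded, which flattens the extreme skew of plain
   minimizers. Runs of consecutive k-mers sharing a signature are merged
   into one *superkmer* (a variant of minimum substring partitioning) and
   packed at 2 bits/symbol into 64-bit words (31 symbols per word, sign bit
   reserved) — a 75 % space saving over 8-bit text.
2. **Partitioning.** All superkmers of one signature must land in one
   partition so per-partition hash-table counting is exact and merge-free.
   The baseline routes a job (a signature, or one of B = 8192 hashed bins
   of signatures) by a 64-bit mix hash. Signature workloads are heavily
   skewed, so the default instead treats placement as multiprocessor
   scheduling: job sizes (k-mer counts) are estimated from a Bernoulli
   sample of the input (default 1 %), and the *longest-processing-time*
   (LPT) greedy assigns jobs, largest first, to the least-loaded of the
   *t* = p partitions. LPT's makespan is at most (4/3 − 1/(3t))·OPT.
3. **Counting.** Each partition expands its superkmers into a hash table
   keyed by packed k-mer (canonical mode collapses a k-mer with its reverse
   complement; forward mode counts literal windows). Partition tables are
   disjoint by construction and merge into a sorted, bit-reproducible TSV.

## Worked example

```sh
python - <<'EOF'
from kmerflow import FixtureSpec, generate_uniform
generate_uniform(FixtureSpec(n_records=50, length=120, seed=7), "reads.fa")
EOF
kmerflow count -i reads.fa -k 28 -m 10 -p 4 --partitioner lpt -o counts.tsv
```

prints

```
distinct	4650
total	4650
```

meaning the 50×120 bp read set contains 4650 canonical 28-mer occurrences
(total, = 50·(120−28+1)), every one of them a unique species (distinct) —
on random sequence a 28-mer virtually never repeats. `counts.tsv` holds one
`KMER<TAB>COUNT` line per canonical 28-mer, sorted A<C<G<T, identical for
any worker count and either partitioner:

```
$ head -2 counts.tsv
AAAAAATTCGTGAGCCCTATAGACCACT	1
AAAAACCAGAGCAATTTGCACGATTGAG	1
```

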