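# Methods

## Model and procedure

kmerflow computes the cumulative k-mer statistics of a collection of DNA
sequences over {A,C,G,T}: for each k-mer (by default each *canonical*
k-mer, the lexicographic minimum of a window and its reverse complement),
how many times it occurs. The computation is organized as a two-stage,
partition-parallel pipeline:

* **Stage 0 (LPT partitioner only).** A Bernoulli sample of input records
  is scanned and, for each job key, the number of k-mers it carries is
  accumulated and scaled by the inverse sampling fraction — an unbiased
  estimate of the full-data job sizes. The longest-processing-time greedy
  then assigns jobs to the p partitions, largest first, each to the
  currently least-loaded partition.
* **Stage 1.** Input records are uppercased, split at any non-ACGT
  character, and each clean fragment is decomposed into superkmers: maximal
  runs of consecutive k-mers sharing one signature, stored 2-bit-packed
  together with that signature. Each superkmer is routed to the partition
  of its job key.
* **Shuffle.** Superkmer buckets are regrouped by partition index. In this
  local implementation the "shuffle" is an in-memory regrouping; the
  contract is only group-by-partition-key, independent of mechanism.
* **Stage 2.** Each partition independently expands its superkmers window
  by window into a hash table keyed by the packed (canonicalized) k-mer.
  Since all instances of a k-mer share a signature, partition key sets are
  disjoint; overlap at merge time is reported as a routing defect, never
  silently summed. The merged table is written as TSV sorted A<C<G<T,
  making the output byte-identical for every worker count and partitioner.

### Signatures

The signature of a k-mer is the smallest canonical m-mer among its
k−m+1 windows, restricted to an *allowed* set: m-mers starting with `AAA`
or `ACA`, or containing `AA` anywhere past their first position, are
excluded. The filter removes the lexicographically small, extremely
frequent m-mers that dominate plain minimizer schemes and would otherwise
concentrate a large share of all superkmers on a handful of partition
keys. When a window contains no allowed m-mer (e.g. poly-A runs), the
smallest canonical m-mer is used anyway and flagged; counting correctness
only requires the choice to be deterministic, and the flagging keeps the
fallback observable. Signatures are computed on canonical m-mers while
scanning only the forward fragment, so a k-mer and its reverse complement
always receive the same signature.

### Encoding

A = 0, C = 1, G = 2, T = 3 — two bits per symbol, chosen so that packed
integer comparison equals lexicographic string comparison. Symbols are
packed 31 per 64-bit word (the most significant bit stays clear, keeping
words in signed-64-bit range), first symbol in the highest occupied bit
pair, last word left-padded with zeros with the symbol count stored
alongside. k = 28 therefore fits one word and k = 55 needs two, exercising
the multi-word path. Counts are arbitrary-precision integers: no
saturation at any dataset scale.

## Parameters

| parameter | default | meaning and rationale |
|---|---|---|
| k | required (≥ 4) | window size; ≤ 31 is single-word, larger is multi-word |
| m | 10 | signature length; small m compresses more but skews partition sizes, m → k gives no compression |
| p (workers) | 1 | worker pool size = number of partitions = LPT machines |
| granularity | signature | scheduling job = signature; `bin` hashes signatures into B bins first |
| B | 8192 | bin count at bin granularity |
| partitioner | lpt | `hash` is the size-oblivious baseline |
| sample_fraction | 0.01 | Bernoulli record-sampling rate for job-size estimation |
| mode | canonical | strand convention of the final counts; `forward` counts literal windows |
| chunk_bases | 10^6 | target bases per stage-1 work unit; records are never split |

The hash is the splitmix64 finalizer (xor-shift/multiply chain with
published constants), fixed bit-exactly so bin assignment and hash
partitioning are reproducible everywhere. Jobs unseen during sampling are
routed by this hash modulo p — a sample cannot observe every signature,
and the fallback keeps routing total and deterministic.

## Synthetic data

The fixture generator emulates desk-scale read sets as i.i.d. bases with a
GC dial, optional N injection, and optional *motif skew*: a fraction of
each read overwritten with tandem copies of one motif at a random phase
and offset. Tandem repeats share signatures, so the skewed fixture
reproduces the "big bins" imbalance that motivates LPT placement, which is
what the load-balancing tests need; duplicated whole reads would inflate
counts without concentrating signature mass in the same way. Defaults used
in tests (tens of reads of 60–180 bp for correctness; 10^5 bases for
estimator calibration; 80×150 bp at 50 % motif mass for skew) keep every
suite fast while leaving all code paths — multi-word k-mers, ambiguity
splitting, multi-chunk scheduling, 8-way pools — exercised. What the
fixtures do **not** model: sequencing error profiles, quality-score
structure, coverage biases, or real genomic repeat families; passing tests
demonstrate algorithmic correctness and directional load-balancing
behaviour, not wall-clock performance on production metagenomes.

## Numerical and design choices

* **Oracle.** The naive sliding-window counter is implemented separately
  from the pipeline and every end-to-end test compares full sorted TSVs
  byte for byte, not just summaries.
* **LPT ties** are broken by ascending job key (jobs) and lowest index
  (machines) so schedules are deterministic. The brute-force optimum used
  to verify the (4/3 − 1/(3t)) bound is a pruned DFS that refuses more
  than 14 jobs or 4 machines.
* **Degenerate inputs.** Fragments shorter than k yield no superkmers;
  empty files yield empty tables and empty output; an empty job-size map
  schedules nothing and routing falls back to the hash.
* **Estimator.** Per-record Bernoulli sampling (rather than a fixed-count
  subsample) keeps estimation streamable and unbiased; job size is the
  carried k-mer count only, not superkmer I/O volume.
* **Equating LPT machines with partitions with p partitions** keeps the
  scheduling model aligned with the worker pool; guidance from parallel
  tuning practice is 2–4 tasks per core if oversubscribing.

## Limitations

* In-memory shuffle: partitions live in RAM, so the local implementation
  targets desk-scale data, not the distributed deployments the design
  descends from.
* Counting throughput is interpreter-bound; the package's value is the
  partitioning/balancing algorithm and its verifiable correctness, not raw
  speed against compiled counters.
* No minimum-count filtering, approximate sketches, or (k,x)-mer
  compaction.
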