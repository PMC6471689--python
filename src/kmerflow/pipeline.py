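"""Two-stage counting pipeline over a local worker pool, plus the CLI.

Stage 0 (LPT partitioner only): estimate job sizes from a sample of the
input and compute the schedule. Stage 1: split input chunks into superkmers
and bucket them by assigned partition. Shuffle: regroup buckets by
partition. Stage 2: count each partition independently, merge the disjoint
tables, write the sorted TSV. The output is bit-identical for any worker
count and either partitioner — balancing changes placement, never counts.

Workers are realized as a fork-based multiprocessing pool when p > 1; the
number of LPT machines equals the number of partitions equals p.
"""

from __future__ import annotations

import logging
import multiprocessing
import sys
import time
from dataclasses import dataclass, field

import click

from . import seq_io
from .counting import CountTable, count_partition, merge_tables, summarize
from .errors import ParameterError
from .partitioning import (
    DEFAULT_BINS,
    DEFAULT_SAMPLE_FRACTION,
    Schedule,
    estimate_job_sizes,
    hash_schedule,
    job_key,
    lpt_schedule,
)
from .superkmer import Superkmer, clean_fragments, split_superkmers

log = logging.getLogger("kmerflow")


@dataclass
class PipelineConfig:
    k: int
    m: int = 10
    workers: int = 1
    granularity: str = "signature"
    B: int = DEFAULT_BINS
    partitioner: str = "lpt"
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION
    seed: int = 0
    mode: str = "canonical"
    chunk_bases: int = 1_000_000

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ParameterError("k must be >= 4")
        if not 3 <= self.m <= self.k:
            raise ParameterError("need 3 <= m <= k")
        if self.workers < 1:
            raise ParameterError("workers must be >= 1")
        if self.B < 1:
            raise ParameterError("B must be >= 1")
        if self.granularity not in ("signature", "bin"):
            raise ParameterError(f"unknown granularity: {self.granularity!r}")
        if self.partitioner not in ("lpt", "hash"):
            raise ParameterError(f"unknown partitioner: {self.partitioner!r}")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ParameterError("sample fraction must be in (0, 1]")
        if self.mode not in ("canonical", "forward"):
            raise ParameterError(f"unknown mode: {self.mode!r}")
        if self.chunk_bases < 1:
            raise ParameterError("chunk_bases must be >= 1")


def _extract_chunk(args) -> dict[int, list[Superkmer]]:
    """Stage-1 worker: superkmers of one chunk, bucketed by partition."""
    chunk, cfg, schedule = args
    buckets: dict[int, list[Superkmer]] = {}
    for rec in chunk:
        for frag in clean_fragments(rec.seq):
            for sk in split_superkmers(frag, cfg.k, cfg.m):
                key = job_key(sk.signature, cfg.granularity, cfg.B)
                buckets.setdefault(schedule.partition_of(key), []).append(sk)
    return buckets


def _count_one(args) -> CountTable:
    superkmers, k, mode = args
    return count_partition(superkmers, k, mode)


def _map(pool, fn, items):
    return pool.map(fn, items) if pool is not None else [fn(it) for it in items]


def run(config: PipelineConfig, input_paths, output_path=None) -> dict:
    """Run the full pipeline; returns summary, per-partition loads and
    per-stage timings. Writes the sorted count TSV if output_path given."""
    if isinstance(input_paths, (str, bytes)) or hasattr(input_paths, "__fspath__"):
        input_paths = [input_paths]
    p = config.workers
    timings: dict[str, float] = {}

    def records():
        for path in input_paths:
            yield from seq_io.read_any(path)

    t0 = time.perf_counter()
    if config.partitioner == "lpt":
        sizes = estimate_job_sizes(
            records(),
            config.sample_fraction,
            config.seed,
            config.k,
            config.m,
            config.granularity,
            config.B,
        )
        schedule = lpt_schedule(sizes, p)
        log.info(
            "estimated %d jobs from %.1f%% sample; LPT makespan estimate %.0f",
            len(sizes.sizes),
            100 * config.sample_fraction,
            schedule.makespan,
        )
    else:
        schedule = Schedule(assignment={}, t=p)  # pure hash fallback routing
    timings["estimate"] = time.perf_counter() - t0

    pool = None
    try:
        if p > 1:
            pool = multiprocessing.get_context("fork").Pool(p)

        t0 = time.perf_counter()
        chunk_args = [
            (chunk, config, schedule)
            for chunk in seq_io.chunk_records(records(), config.chunk_bases)
        ]
        partitions: dict[int, list[Superkmer]] = {}
        for buckets in _map(pool, _extract_chunk, chunk_args):
            for part, sks in buckets.items():
                partitions.setdefault(part, []).extend(sks)
        timings["stage1"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        parts = sorted(partitions)
        tables = _map(
            pool, _count_one, [(partitions[q], config.k, config.mode) for q in parts]
        )
        timings["stage2"] = time.perf_counter() - t0
    finally:
        if pool is not None:
            pool.close()
            pool.join()

    t0 = time.perf_counter()
    merged = (
        merge_tables(tables)
        if tables
        else CountTable(counts={}, k=config.k, mode=config.mode)
    )
    if output_path is not None:
        seq_io.write_counts(merged, output_path)
    timings["merge_write"] = time.perf_counter() - t0

    loads = [0] * p
    for part, sks in partitions.items():
        loads[part] += sum(sk.n_kmers for sk in sks)
    log.info("per-partition k-mer loads: %s", loads)
    for stage, dt in timings.items():
        log.info("stage %-11s %.3fs", stage, dt)

    out = summarize(merged)
    out["partition_loads"] = loads
    out["timings"] = timings
    out["table"] = merged
    return out


@click.group()
def cli() -> None:
    """Signature-partitioned, load-balanced k-mer counting."""


@cli.command("count")
@click.option("-i", "--input", "inputs", multiple=True, required=True,
              type=click.Path(exists=True, dir_okay=False), help="FASTA/FASTQ file(s).")
@click.option("-k", "kay", type=int, required=True, help="k-mer length (>= 4).")
@click.option("-m", "em", type=int, default=10, show_default=True,
              help="Signature length.")
@click.option("-p", "--workers", type=int, default=1, show_default=True,
              help="Workers = partitions = LPT machines.")
@click.option("--granularity", type=click.Choice(["signature", "bin"]),
              default="signature", show_default=True)
@click.option("-B", "bins", type=int, default=DEFAULT_BINS, show_default=True,
              help="Number of bins (bin granularity only).")
@click.option("--partitioner", type=click.Choice(["lpt", "hash"]),
              default="lpt", show_default=True)
@click.option("--sample", type=float, default=DEFAULT_SAMPLE_FRACTION,
              show_default=True, help="Job-size sampling fraction.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--mode", type=click.Choice(["canonical", "forward"]),
              default="canonical", show_default=True)
@click.option("-o", "--output", required=True, type=click.Path(dir_okay=False),
              help="Output TSV path.")
@click.option("-v", "--verbose", is_flag=True, help="Log stage timings/loads.")
def count_cmd(inputs, kay, em, workers, granularity, bins, partitioner,
              sample, seed, mode, output, verbose):
    """Count k-mers in FASTA/FASTQ inputs and write a sorted TSV."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
        stream=sys.stderr,
    )
    try:
        config = PipelineConfig(
            k=kay, m=em, workers=workers, granularity=granularity, B=bins,
            partitioner=partitioner, sample_fraction=sample, seed=seed, mode=mode,
        )
    except ParameterError as exc:
        raise click.UsageError(str(exc)) from exc
    result = run(config, list(inputs), output)
    click.echo(f"distinct\t{result['distinct']}")
    click.echo(f"total\t{result['total']}")


def main() -> int:  # pragma: no cover
    return cli(standalone_mode=True)
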