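"""Shotgun read simulation and exact-coverage subsampling.

Reads are fixed-length single-end sequences drawn uniformly over the genome
(chromosomes weighted by length, strand uniform), with independent per-base
substitution errors. The number of reads in a 1x sample is
round(genome_size / read_length), the paper-style definition of one-fold
coverage used by the read-mapping copy-number estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from Bio import SeqIO

from ._seq import BASES, revcomp_array, to_array, to_string


class Read(NamedTuple):
    read_id: str
    sequence: str
    origin: tuple[str, int, str] | None  # (chromosome, start, strand) or None


@dataclass
class ReadSet:
    reads: list[Read]
    read_length: int
    source_genome_size: int

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


def reads_for_1x(genome_size: float, read_length: int) -> int:
    """Number of reads whose total bases equal the genome size (1x coverage)."""
    if genome_size <= 0 or read_length <= 0:
        raise ValueError("genome_size and read_length must be positive")
    return int(round(genome_size / read_length))


def simulate_reads(
    genome: dict[str, str],
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Simulate ``round(coverage * genome_size / read_length)`` error-prone reads."""
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    names = list(genome)
    arrays = {name: to_array(genome[name]) for name in names}
    for name, arr in arrays.items():
        if arr.size < read_length:
            raise ValueError(
                f"chromosome {name} ({arr.size} bp) is shorter than the "
                f"read length ({read_length} bp)"
            )
    genome_size = sum(arr.size for arr in arrays.values())
    n_reads = int(round(coverage * genome_size / read_length))
    rng = np.random.default_rng(seed)

    lengths = np.array([arrays[n].size for n in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_reads, p=lengths / lengths.sum())
    strands = rng.random(n_reads) < 0.5  # True -> forward

    reads: list[Read] = []
    for i in range(n_reads):
        name = names[int(chrom_idx[i])]
        arr = arrays[name]
        start = int(rng.integers(0, arr.size - read_length + 1))
        frag = arr[start:start + read_length]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            frag = revcomp_array(frag)
        frag = frag.copy()
        if error_rate > 0:
            hit = np.nonzero(rng.random(read_length) < error_rate)[0]
            if hit.size:
                idx = np.searchsorted(BASES, frag[hit])
                frag[hit] = BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
        reads.append(Read(f"read{i:07d}", to_string(frag), (name, start, strand)))
    return ReadSet(reads=reads, read_length=read_length, source_genome_size=genome_size)


def subsample(readset: ReadSet, n: int, seed: int = 0) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement (original order kept)."""
    if n > len(readset.reads):
        raise ValueError(f"cannot subsample {n} reads from {len(readset.reads)}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(readset.reads), size=n, replace=False))
    return ReadSet(
        reads=[readset.reads[int(i)] for i in keep],
        read_length=readset.read_length,
        source_genome_size=readset.source_genome_size,
    )


def write_fastq(readset: ReadSet, path: str | Path, encode_origin: bool = True) -> None:
    """Write reads as FASTQ with constant Q30 qualities.

    With ``encode_origin`` the read id carries the true origin as
    ``chrom:start:strand`` (for oracle tests); without it, ids are opaque so
    that no downstream stage can depend on the truth.
    """
    qual = "?"  # Phred+33 Q30
    with open(path, "w") as fh:
        for read in readset.reads:
            rid = read.read_id
            if encode_origin and read.origin is not None:
                chrom, start, strand = read.origin
                rid = f"{read.read_id}|{chrom}:{start}:{strand}"
            fh.write(f"@{rid}\n{read.sequence}\n+\n{qual * len(read.sequence)}\n")


def read_fastq(path: str | Path) -> ReadSet:
    reads: list[Read] = []
    length = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        origin = None
        rid = rec.id
        if "|" in rid:
            rid, loc = rid.split("|", 1)
            chrom, start, strand = loc.rsplit(":", 2)
            origin = (chrom, int(start), strand)
        seq = str(rec.seq).upper()
        length = max(length, len(seq))
        reads.append(Read(rid, seq, origin))
    return ReadSet(reads=reads, read_length=length, source_genome_size=0)
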