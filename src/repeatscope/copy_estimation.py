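"""Copy-number estimation from alignment depth — the pipeline's core statistic.

A repeat contig's copy number is measured two independent ways:

* ``assembly_copy_number`` — align the contig to a genome assembly, keep hits
  with identity > 70% and query coverage > 70%, and divide the total aligned
  length by the contig length;
* ``read_copy_number`` — map a 1x-coverage read sample to the contig under
  the same filters and divide the total aligned read length by the contig
  length.

Because an assembly collapses tandem arrays while raw reads sample the genome
uniformly, the ratio of the two estimates (``fold_change``) measures how many
fold an assembly under-represents a repeat.

The alignment model is gapless local alignment evaluated per diagonal: the
synthetic data generator introduces substitutions only, so every true local
alignment lies on a single diagonal and identity = matches / aligned columns.
The engine seeds candidate diagonals with shared k-mers (default k=12) and
scores each candidate exactly; on small instances its filtered hit set is
checkable against an exhaustive all-diagonal scan.

By default overlapping hits are NOT merged before summing aligned length —
the literal reading of total-aligned-length/contig-length — which, for a
query of k tandem monomers against an array of M monomers, yields ~M (one
full-query hit per monomer phase). The ``merge_overlaps`` option instead
counts each base once (interval union on the side being accumulated:
target-side for contig→assembly, per-read query-side for read→contig), which
is the variant used for parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from ._seq import KmerIndex, revcomp_array, to_array
from .read_sim import ReadSet

DEFAULT_MIN_IDENTITY = 0.7
DEFAULT_MIN_COVERAGE = 0.7
DEFAULT_SEED_K = 12


class AlignmentHit(NamedTuple):
    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float
    strand: str

    @property
    def aligned_length(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class CopyEstimate:
    contig_id: str
    method: str  # "assembly" or "read_1x"
    total_aligned_length: int
    contig_length: int
    copies: float
    params: tuple[float, float]
    merged: bool = False


def tandem_reference(monomer: str, read_length: int = 150) -> str:
    """Concatenate a tandem monomer until every read phase fits wholly inside.

    Read-mapping a monomer shorter than the read length systematically loses
    boundary-spanning reads; a reference of ceil((read_length + m - 1) / m)
    head-to-tail monomer copies removes that artifact. Estimated copies are in
    units of this reference; multiply by (reference length / monomer length)
    to convert back to monomer copies.
    """
    m = len(monomer)
    n = -(-(read_length + m - 1) // m)
    return monomer * n


MISMATCH_PENALTY = 2  # match +1, mismatch -2: segments stay above ~67% identity


def _segment_from_prefix(prefix: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring segment from a per-column score prefix sum.

    Deterministic rule: smallest end index maximizing (prefix - running
    minimum), then the earliest index attaining that minimum. Returns
    (start, end, matches); (0, 0, 0) when no positive-scoring segment
    exists.
    """
    runmin = np.minimum.accumulate(prefix)
    gain = prefix - runmin
    be = int(np.argmax(gain))
    g = int(gain[be])
    if g <= 0:
        return 0, 0, 0
    target = prefix[be] - g
    bs = int(np.argmax(prefix[: be + 1] == target))
    aligned = be - bs
    matches = (g + MISMATCH_PENALTY * aligned) // (MISMATCH_PENALTY + 1)
    return bs, be, matches


def _evaluate_diagonals(qarr, tarr, diags, min_identity, min_coverage):
    """Score gapless local alignments on the given diagonals.

    Each diagonal's overlap is trimmed to its maximal-scoring segment
    (Kadane with match +1, mismatch -MISMATCH_PENALTY), mirroring how a
    local aligner clips mismatching flanks; filters then apply to the
    trimmed segment. Returns passing hits as (diag, query_start,
    query_end, identity) tuples; at most one hit per diagonal and strand.
    """
    Q, T = qarr.size, tarr.size
    out = []
    diags = np.asarray(diags, dtype=np.int64)
    if diags.size == 0:
        return out
    full = diags[(diags >= 0) & (diags <= T - Q)] if T >= Q else diags[:0]
    partial = diags[(diags < 0) | (diags > T - Q)] if T >= Q else diags

    if full.size:
        chunk = max(1, 4_000_000 // max(Q, 1))
        offsets = np.arange(Q, dtype=np.int64)
        for i in range(0, full.size, chunk):
            block = full[i:i + chunk]
            eq = tarr[block[:, None] + offsets[None, :]] == qarr[None, :]
            score = np.where(eq, 1, -MISMATCH_PENALTY)
            prefix = np.zeros((block.size, Q + 1), dtype=np.int64)
            np.cumsum(score, axis=1, out=prefix[:, 1:])
            runmin = np.minimum.accumulate(prefix, axis=1)
            gain = prefix - runmin
            be = gain.argmax(axis=1)
            rows = np.arange(block.size)
            g = gain[rows, be]
            target = prefix[rows, be] - g
            att = (prefix == target[:, None]) & (np.arange(Q + 1)[None, :] <= be[:, None])
            bs = att.argmax(axis=1)
            aligned = be - bs
            matches = (g + MISMATCH_PENALTY * aligned) // (MISMATCH_PENALTY + 1)
            ok = (g > 0) & (aligned > min_coverage * Q)
            with np.errstate(invalid="ignore", divide="ignore"):
                ident = np.where(aligned > 0, matches / np.maximum(aligned, 1), 0.0)
            ok &= ident > min_identity
            for j in np.nonzero(ok)[0]:
                out.append((int(block[j]), int(bs[j]), int(be[j]), float(ident[j])))

    for d in partial.tolist():
        qs = max(0, -d)
        qe = min(Q, T - d)
        if qe - qs <= min_coverage * Q:
            continue
        eq = qarr[qs:qe] == tarr[qs + d:qe + d]
        prefix = np.zeros(qe - qs + 1, dtype=np.int64)
        np.cumsum(np.where(eq, 1, -MISMATCH_PENALTY), out=prefix[1:])
        bs, be, matches = _segment_from_prefix(prefix)
        aligned = be - bs
        if aligned <= min_coverage * Q:
            continue
        ident = matches / aligned
        if ident > min_identity:
            out.append((d, qs + bs, qs + be, ident))
    return out


#: below this diagonal-space size the engine scores every diagonal instead
#: of seeding — exact on the small instances where exactness is checkable
EXHAUSTIVE_CELL_LIMIT = 20_000_000


def local_align(
    query: str,
    target: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    seed_k: int = DEFAULT_SEED_K,
    query_id: str = "query",
    target_id: str = "target",
    target_index: KmerIndex | None = None,
    exhaustive: bool | None = None,
) -> list[AlignmentHit]:
    """Gapless local alignment of ``query`` against both strands of
    ``target``; hits filtered at strict identity/coverage thresholds and
    sorted by target position.

    Small instances (diagonal space up to ``EXHAUSTIVE_CELL_LIMIT`` cells)
    are scored on every diagonal; larger targets are k-mer seeded, which can
    in principle miss a borderline-identity segment containing no exact
    ``seed_k``-mer. ``exhaustive`` forces either mode.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    qarr = to_array(query)
    tarr = to_array(target)
    Q, T = qarr.size, tarr.size
    if exhaustive is None:
        exhaustive = (T + Q) * Q <= EXHAUSTIVE_CELL_LIMIT
    index = None
    if not exhaustive:
        index = target_index if target_index is not None else KmerIndex(tarr, seed_k)
    hits: list[AlignmentHit] = []
    for strand, q in (("+", qarr), ("-", revcomp_array(qarr))):
        if exhaustive:
            diags = np.arange(-(Q - 1), T, dtype=np.int64)
        else:
            diags = index.diagonals(q)
        for d, qs, qe, ident in _evaluate_diagonals(
            q, tarr, diags, min_identity, min_coverage
        ):
            if strand == "-":
                q0, q1 = Q - qe, Q - qs
            else:
                q0, q1 = qs, qe
            hits.append(
                AlignmentHit(query_id, target_id, q0, q1, qs + d, qe + d, ident, strand)
            )
    hits.sort(key=lambda h: (h.target_start, h.target_end, h.strand))
    return hits


def align_to_genome(
    query: str,
    genome: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    seed_k: int = DEFAULT_SEED_K,
    query_id: str = "query",
    indexes: dict[str, KmerIndex] | None = None,
) -> list[AlignmentHit]:
    """local_align against every chromosome of a genome/assembly dict."""
    hits: list[AlignmentHit] = []
    for name in genome:
        idx = indexes.get(name) if indexes else None
        hits.extend(
            local_align(
                query, genome[name], min_identity, min_coverage, seed_k,
                query_id=query_id, target_id=name, target_index=idx,
            )
        )
    return hits


def build_genome_indexes(genome: dict[str, str], seed_k: int = DEFAULT_SEED_K):
    """Precompute per-chromosome k-mer indexes for repeated queries."""
    return {name: KmerIndex(to_array(seq), seed_k) for name, seq in genome.items()}


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, prev_end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return total


def assembly_copy_number(
    contig: str,
    assembly: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    contig_id: str = "contig",
    merge_overlaps: bool = False,
    seed_k: int = DEFAULT_SEED_K,
    indexes: dict[str, KmerIndex] | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> CopyEstimate:
    """Copies of ``contig`` in ``assembly`` = total aligned length / contig length."""
    if len(contig) == 0:
        raise ValueError("contig must be non-empty")
    if hits is None:
        hits = align_to_genome(
            contig, assembly, min_identity, min_coverage, seed_k,
            query_id=contig_id, indexes=indexes,
        )
    if merge_overlaps:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for h in hits:
            per_chrom.setdefault(h.target_id, []).append((h.target_start, h.target_end))
        total = sum(_union_length(ivs) for ivs in per_chrom.values())
    else:
        total = sum(h.aligned_length for h in hits)
    return CopyEstimate(
        contig_id, "assembly", total, len(contig), total / len(contig),
        (min_identity, min_coverage), merge_overlaps,
    )


def read_copy_number(
    contig: str,
    reads_1x: ReadSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    contig_id: str = "contig",
    merge_overlaps: bool = False,
    seed_k: int = DEFAULT_SEED_K,
) -> CopyEstimate:
    """Copies of ``contig`` from a 1x read sample = total aligned read length /
    contig length. Reads map to either strand of the contig."""
    if len(contig) == 0:
        raise ValueError("contig must be non-empty")
    tarr = to_array(contig)
    index = KmerIndex(tarr, seed_k)
    total = 0
    if reads_1x.reads:
        total = _batch_read_alignment(
            tarr, index, reads_1x, min_identity, min_coverage, seed_k, merge_overlaps
        )
    return CopyEstimate(
        contig_id, "read_1x", total, len(contig), total / len(contig),
        (min_identity, min_coverage), merge_overlaps,
    )


def _batch_read_alignment(tarr, index, readset, min_identity, min_coverage,
                          seed_k, merge_overlaps) -> int:
    """Sum of passing aligned read lengths; vectorized candidate screening."""
    contig_codes = np.unique(
        np.concatenate([
            _codes_or_empty(tarr, seed_k),
            _codes_or_empty(revcomp_array(tarr), seed_k),
        ])
    )
    total = 0
    for read in readset.reads:
        qarr = to_array(read.sequence)
        if qarr.size < seed_k:
            continue
        codes = _codes_or_empty(qarr, seed_k)
        pos = np.searchsorted(contig_codes, codes)
        pos[pos >= contig_codes.size] = contig_codes.size - 1 if contig_codes.size else 0
        if contig_codes.size == 0 or not np.any(contig_codes[pos] == codes):
            continue
        Q = qarr.size
        intervals: list[tuple[int, int]] = []
        for strand, q in (("+", qarr), ("-", revcomp_array(qarr))):
            for d, qs, qe, _ident in _evaluate_diagonals(
                q, tarr, index.diagonals(q), min_identity, min_coverage
            ):
                if strand == "-":
                    intervals.append((Q - qe, Q - qs))
                else:
                    intervals.append((qs, qe))
        if not intervals:
            continue
        if merge_overlaps:
            total += _union_length(intervals)
        else:
            total += sum(e - s for s, e in intervals)
    return total


def _codes_or_empty(arr, k):
    from ._seq import kmer_codes

    return kmer_codes(arr, k)


class AbsentFromAssemblyError(ValueError):
    """The repeat has zero assembly copies; no fold change is defined."""


def fold_change(read_est: CopyEstimate | float, assembly_est: CopyEstimate | float) -> float:
    """Read-based copies / assembly-based copies (the collapse factor signal)."""
    if isinstance(read_est, CopyEstimate) and isinstance(assembly_est, CopyEstimate):
        if read_est.contig_id != assembly_est.contig_id:
            raise ValueError(
                f"estimates are for different contigs: {read_est.contig_id!r} "
                f"vs {assembly_est.contig_id!r}"
            )
        read_copies = read_est.copies
        assembly_copies = assembly_est.copies
    else:
        read_copies = float(read_est)
        assembly_copies = float(assembly_est)
    if assembly_copies == 0:
        raise AbsentFromAssemblyError("repeat is absent from the assembly")
    return read_copies / assembly_copies


def write_hits_outfmt6(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Tab-separated hits in BLAST outfmt-6 column order (1-based inclusive
    coordinates; minus-strand hits have sstart > send; e-value and bit-score
    columns are placeholders)."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.aligned_length
            mismatch = int(round(length * (1.0 - h.identity)))
            if h.strand == "+":
                ss, se = h.target_start + 1, h.target_end
            else:
                ss, se = h.target_end, h.target_start + 1
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.identity * 100:.2f}\t{length}\t"
                f"{mismatch}\t0\t{h.query_start + 1}\t{h.query_end}\t{ss}\t{se}\t"
                f"0.0\t0.0\n"
            )


def read_hits_outfmt6(path: str | Path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ss, se = int(f[8]), int(f[9])
            strand = "+" if ss <= se else "-"
            ts, te = (ss - 1, se) if strand == "+" else (se - 1, ss)
            hits.append(
                AlignmentHit(
                    f[0], f[1], int(f[6]) - 1, int(f[7]), ts, te,
                    float(f[2]) / 100.0, strand,
                )
            )
    return hits
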