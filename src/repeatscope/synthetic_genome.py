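"""Synthetic genomes with planted repeat families and collapsible assemblies.

This module builds toy genomes whose repeat landscape mimics a large,
repeat-rich plant genome at desk scale: tandem satellite arrays (centromeric
satellite-like, rDNA-like, telomeric), dispersed LTR-retrotransposon-like
elements with terminal repeats scattered genome-wide, and random background
sequence. Every planted copy is recorded in a ground-truth table so that
downstream discovery, annotation, copy-number and distribution estimates can
be scored against known parameters. A "collapsed assembly" variant removes a
known fraction of the copies of selected tandem arrays, emulating the
under-representation of highly repeated sequences in de novo assemblies.

Conventions: coordinates are 0-based half-open (BED-compatible); divergence is
a per-base substitution probability applied independently to each planted
copy (no indels, so copy lengths and hence copy-number arithmetic are exact);
dispersed copies land on either strand with probability 0.5, tandem arrays on
the forward strand only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, revcomp, to_array, to_string

TANDEM_KINDS = frozenset({"tandem_satellite", "rdna_array", "telomeric_array"})
ALL_KINDS = TANDEM_KINDS | {"dispersed_element"}
PLACEMENTS = frozenset(
    {"single_locus", "per_chromosome_locus", "terminal", "uniform_scatter"}
)

TELOMERE_MOTIF = "TTTAGGG"

#: Default structural parameters, within the ranges typical of each class:
#: ~140-bp centromeric satellite monomers, multi-kb rDNA units, the 7-bp plant
#: telomere motif, and ~5-kb LTR elements flanked by ~300-bp terminal repeats.
DEFAULT_SATELLITE_MONOMER_BP = 140
DEFAULT_RDNA_UNIT_BP = 3000
DEFAULT_ELEMENT_BP = 5000
DEFAULT_TERMINAL_REPEAT_BP = 300


class CapacityError(ValueError):
    """Planted repeats exceed the capacity of a chromosome."""


class TruthInterval(NamedTuple):
    chromosome: str
    start: int
    end: int
    family: str
    copy_index: int
    strand: str


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One planted repeat family.

    ``monomer_or_element`` is either an explicit DNA string or an integer
    length to be drawn randomly at build time (dispersed elements drawn this
    way get ``terminal_repeat_bp`` identical terminal repeats).
    """

    name: str
    kind: str
    monomer_or_element: str | int
    copy_number: int
    divergence: float = 0.05
    placement: str = "single_locus"
    chromosomes: tuple[str, ...] = ()
    terminal_repeat_bp: int = DEFAULT_TERMINAL_REPEAT_BP

    def __post_init__(self):
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown repeat kind {self.kind!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.kind == "telomeric_array" and self.placement != "terminal":
            raise ValueError("telomeric_array placement must be 'terminal'")
        if self.kind == "dispersed_element" and self.placement != "uniform_scatter":
            raise ValueError("dispersed_element placement must be 'uniform_scatter'")
        if self.kind in TANDEM_KINDS and self.placement == "uniform_scatter":
            raise ValueError("tandem kinds require a locus placement")


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic genome.

    ``spacer_bp`` is the minimum background gap enforced between planted
    loci (default: one read length) so that no single read can span two
    families — without it, abutting families merge into one read-graph
    component and the planted family structure is ill-defined.
    """

    chromosome_lengths: dict[str, int]
    families: tuple[RepeatFamilySpec, ...]
    background_gc: float = 0.44
    seed: int = 0
    spacer_bp: int = 150

    def __post_init__(self):
        if len(set(self.chromosome_lengths)) != len(self.chromosome_lengths):
            raise ValueError("chromosome identifiers must be unique")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        object.__setattr__(self, "families", tuple(self.families))


@dataclass
class GroundTruth:
    """Planted-copy intervals plus the family -> kind map (the recovery oracle)."""

    intervals: list[TruthInterval] = field(default_factory=list)
    kinds: dict[str, str] = field(default_factory=dict)
    consensi: dict[str, str] = field(default_factory=dict)

    def family_intervals(self, family: str) -> list[TruthInterval]:
        return [iv for iv in self.intervals if iv.family == family]

    def copy_count(self, family: str) -> int:
        return sum(1 for iv in self.intervals if iv.family == family)

    def family_bp(self, family: str) -> int:
        return sum(iv.end - iv.start for iv in self.intervals if iv.family == family)

    def family_loci(self, family: str) -> list[tuple[str, int, int]]:
        """Merged contiguous spans of a family's copies (tandem array extents)."""
        ivs = sorted(self.family_intervals(family), key=lambda iv: (iv.chromosome, iv.start))
        loci: list[tuple[str, int, int]] = []
        for iv in ivs:
            if loci and loci[-1][0] == iv.chromosome and loci[-1][2] == iv.start:
                loci[-1] = (iv.chromosome, loci[-1][1], iv.end)
            else:
                loci.append((iv.chromosome, iv.start, iv.end))
        return loci

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(
                    f"{iv.chromosome}\t{iv.start}\t{iv.end}\t"
                    f"{iv.family}:{iv.copy_index}\t0\t{iv.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "GroundTruth":
        truth = cls()
        with open(path) as fh:
            for line in fh:
                chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
                family, copy_index = name.rsplit(":", 1)
                truth.intervals.append(
                    TruthInterval(chrom, int(start), int(end), family, int(copy_index), strand)
                )
        return truth


def mutate_copy(template: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation: each base flips to a *different* base with
    probability ``divergence``, so E[Hamming distance] = divergence * length."""
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    arr = to_array(template).copy()
    if divergence == 0.0 or arr.size == 0:
        return template
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    if hit.size:
        # shift each hit base by 1..3 positions around the ACGT wheel
        idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return to_string(arr)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.44) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return to_string(rng.choice(BASES, size=length, p=p))


def make_element(rng: np.random.Generator, length: int = DEFAULT_ELEMENT_BP,
                 terminal_repeat_bp: int = DEFAULT_TERMINAL_REPEAT_BP) -> str:
    """An LTR-retrotransposon-like template: identical terminal repeats
    flanking a random internal body."""
    if length < 2 * terminal_repeat_bp + 1:
        raise ValueError("element length must exceed twice the terminal repeat")
    tr = random_sequence(rng, terminal_repeat_bp)
    body = random_sequence(rng, length - 2 * terminal_repeat_bp)
    return tr + body + tr


class _Occupied:
    """Per-chromosome sorted non-overlapping interval book-keeping with a
    minimum inter-locus spacer."""

    def __init__(self, spacer: int = 0):
        self._spacer = spacer
        self._starts: list[int] = []
        self._ends: list[int] = []

    def overlaps(self, start: int, end: int) -> bool:
        start -= self._spacer
        end += self._spacer
        i = bisect.bisect_right(self._starts, start)
        if i > 0 and self._ends[i - 1] > start:
            return True
        return i < len(self._starts) and self._starts[i] < end

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_right(self._starts, start)
        self._starts.insert(i, start)
        self._ends.insert(i, end)


def _resolve_template(fam: RepeatFamilySpec, rng: np.random.Generator) -> str:
    if isinstance(fam.monomer_or_element, str):
        return fam.monomer_or_element.upper()
    length = int(fam.monomer_or_element)
    if fam.kind == "dispersed_element":
        return make_element(rng, length, fam.terminal_repeat_bp)
    return random_sequence(rng, length)


def _split_copies(total: int, n_parts: int) -> list[int]:
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def build_genome(spec: GenomeSpec) -> tuple[dict[str, str], GroundTruth]:
    """Build the genome described by ``spec``.

    Returns the chromosome sequences and the ground truth. Deterministic for a
    fixed spec (including its seed). Background is i.i.d. random DNA at
    ``background_gc``; planted copies overwrite background at non-overlapping
    positions, so genome length = background bases + sum of planted copy
    lengths.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = {
        name: to_array(random_sequence(rng, length, spec.background_gc)).copy()
        for name, length in spec.chromosome_lengths.items()
    }
    occupied = {name: _Occupied(spec.spacer_bp) for name in chroms}
    truth = GroundTruth()

    templates: dict[str, str] = {}
    for fam in spec.families:
        templates[fam.name] = _resolve_template(fam, rng)
        truth.kinds[fam.name] = fam.kind
        truth.consensi[fam.name] = templates[fam.name]

    # capacity pre-check per chromosome (upper bound: families restricted there)
    load: dict[str, int] = {name: 0 for name in chroms}
    for fam in spec.families:
        targets = fam.chromosomes or tuple(chroms)
        planted = len(templates[fam.name]) * fam.copy_number
        if fam.placement in ("single_locus", "uniform_scatter"):
            if len(targets) == 1:
                load[targets[0]] += planted
        else:
            per = planted // len(targets)
            for t in targets:
                load[t] += per
    for name, used in load.items():
        if used >= spec.chromosome_lengths[name]:
            raise CapacityError(
                f"planted repeats ({used} bp) exceed capacity of chromosome "
                f"{name} ({spec.chromosome_lengths[name]} bp)"
            )

    # placement priority: pinned terminal arrays first, then free tandem loci,
    # then scattered copies (which can fill any remaining space)
    def _priority(fam: RepeatFamilySpec) -> int:
        if fam.placement == "terminal":
            return 0
        return 2 if fam.placement == "uniform_scatter" else 1

    order = sorted(range(len(spec.families)), key=lambda i: (_priority(spec.families[i]), i))
    for fam_idx in order:
        fam = spec.families[fam_idx]
        template = templates[fam.name]
        targets = list(fam.chromosomes) if fam.chromosomes else list(chroms)
        for t in targets:
            if t not in chroms:
                raise ValueError(f"family {fam.name} targets unknown chromosome {t}")
        if fam.kind == "dispersed_element":
            _plant_dispersed(fam, template, chroms, occupied, truth, rng, targets)
        else:
            _plant_tandem(fam, template, chroms, occupied, truth, rng, targets)

    truth.intervals.sort(key=lambda iv: (iv.chromosome, iv.start, iv.family))
    return {name: to_string(arr) for name, arr in chroms.items()}, truth


def _place_locus(length: int, chrom_len: int, occ: _Occupied,
                 rng: np.random.Generator, chrom_name: str,
                 fixed_start: int | None = None) -> int:
    if length > chrom_len:
        raise CapacityError(
            f"locus of {length} bp does not fit on chromosome {chrom_name}"
        )
    if fixed_start is not None:
        if occ.overlaps(fixed_start, fixed_start + length):
            raise CapacityError(
                f"terminal locus collides with existing repeat on {chrom_name}"
            )
        occ.add(fixed_start, fixed_start + length)
        return fixed_start
    for _ in range(2000):
        start = int(rng.integers(0, chrom_len - length + 1))
        if not occ.overlaps(start, start + length):
            occ.add(start, start + length)
            return start
    raise CapacityError(f"could not place {length} bp locus on chromosome {chrom_name}")


def _plant_tandem(fam, template, chroms, occupied, truth, rng, targets):
    unit = len(template)
    if fam.placement == "single_locus":
        loci = [(targets[int(rng.integers(len(targets)))], fam.copy_number, None)]
    elif fam.placement == "per_chromosome_locus":
        loci = [
            (t, n, None)
            for t, n in zip(targets, _split_copies(fam.copy_number, len(targets)))
            if n > 0
        ]
    elif fam.placement == "terminal":
        ends = [(t, side) for t in targets for side in ("left", "right")]
        loci = []
        for (t, side), n in zip(ends, _split_copies(fam.copy_number, len(ends))):
            if n > 0:
                fixed = 0 if side == "left" else len(chroms[t]) - n * unit
                loci.append((t, n, fixed))
    else:  # pragma: no cover - excluded by RepeatFamilySpec validation
        raise ValueError(fam.placement)

    copy_index = 0
    for chrom_name, n_copies, fixed_start in loci:
        arr = chroms[chrom_name]
        start = _place_locus(n_copies * unit, arr.size, occupied[chrom_name], rng,
                             chrom_name, fixed_start)
        pos = start
        for _ in range(n_copies):
            copy_seq = mutate_copy(template, fam.divergence, rng)
            arr[pos:pos + unit] = to_array(copy_seq)
            truth.intervals.append(
                TruthInterval(chrom_name, pos, pos + unit, fam.name, copy_index, "+")
            )
            copy_index += 1
            pos += unit


def _plant_dispersed(fam, template, chroms, occupied, truth, rng, targets):
    unit = len(template)
    weights = np.array([len(chroms[t]) for t in targets], dtype=float)
    weights /= weights.sum()
    for copy_index in range(fam.copy_number):
        placed = False
        for _ in range(2000):
            chrom_name = targets[int(rng.choice(len(targets), p=weights))]
            arr = chroms[chrom_name]
            if arr.size < unit:
                continue
            start = int(rng.integers(0, arr.size - unit + 1))
            if occupied[chrom_name].overlaps(start, start + unit):
                continue
            occupied[chrom_name].add(start, start + unit)
            strand = "+" if rng.random() < 0.5 else "-"
            copy_seq = mutate_copy(template, fam.divergence, rng)
            if strand == "-":
                copy_seq = revcomp(copy_seq)
            arr[start:start + unit] = to_array(copy_seq)
            truth.intervals.append(
                TruthInterval(chrom_name, start, start + unit, fam.name, copy_index, strand)
            )
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not scatter copy {copy_index} of {fam.name}: no free space"
            )


def collapse_assembly(
    genome: dict[str, str],
    truth: GroundTruth,
    collapse_factors: dict[str, float],
) -> tuple[dict[str, str], GroundTruth]:
    """Collapse tandem arrays by known factors, emulating assembly loss.

    Each tandem locus of family *f* retains ``ceil(copies / factor_f)``
    consecutive copies (the leading ones); flanking sequence is rejoined and
    all ground-truth coordinates are remapped. Factor 1 is the identity.
    """
    for name, factor in collapse_factors.items():
        if name not in truth.kinds:
            raise KeyError(f"unknown family {name!r}")
        if factor < 1:
            raise ValueError(f"collapse factor for {name} must be >= 1, got {factor}")
        if truth.kinds[name] not in TANDEM_KINDS:
            raise ValueError(
                f"collapse of dispersed family {name!r} is unsupported "
                "(factors apply only to tandem kinds)"
            )

    # deletion spans: per locus, everything after the first ceil(n/factor) copies
    deletions: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    removed: set[tuple[str, int]] = set()
    for fam_name, factor in collapse_factors.items():
        ivs = sorted(truth.family_intervals(fam_name), key=lambda iv: (iv.chromosome, iv.start))
        # group into contiguous loci
        loci: list[list[TruthInterval]] = []
        for iv in ivs:
            if loci and loci[-1][-1].chromosome == iv.chromosome and loci[-1][-1].end == iv.start:
                loci[-1].append(iv)
            else:
                loci.append([iv])
        for locus in loci:
            keep = int(np.ceil(len(locus) / factor))
            for iv in locus[keep:]:
                deletions[iv.chromosome].append((iv.start, iv.end))
                removed.add((fam_name, iv.copy_index))

    new_genome: dict[str, str] = {}
    shifts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in genome.items():
        dels = sorted(deletions[chrom])
        # merge adjacent deletion spans
        merged: list[list[int]] = []
        for s, e in dels:
            if merged and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        if not merged:
            new_genome[chrom] = seq
            shifts[chrom] = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            continue
        pieces, prev = [], 0
        for s, e in merged:
            pieces.append(seq[prev:s])
            prev = e
        pieces.append(seq[prev:])
        new_genome[chrom] = "".join(pieces)
        starts = np.array([s for s, _ in merged], dtype=np.int64)
        cum = np.cumsum([e - s for s, e in merged]).astype(np.int64)
        shifts[chrom] = (starts, cum)

    new_truth = GroundTruth(kinds=dict(truth.kinds), consensi=dict(truth.consensi))
    for iv in truth.intervals:
        if (iv.family, iv.copy_index) in removed:
            continue
        starts, cum = shifts[iv.chromosome]
        shift = int(cum[np.searchsorted(starts, iv.start, side="right") - 1]) \
            if starts.size and iv.start >= starts[0] else 0
        new_truth.intervals.append(
            iv._replace(start=iv.start - shift, end=iv.end - shift)
        )
    return new_genome, new_truth


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
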