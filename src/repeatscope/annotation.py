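"""Repeat-class annotation of representative contigs.

A contig is assigned exactly one label, by precedence:

1. ``telomeric`` — at least 10 consecutive plant telomere motif (TTTAGGG)
   units on either strand;
2. ``rdna_like`` / ``library_match`` — similarity to a user or bundled
   reference library entry at explicit identity/coverage thresholds
   (entries whose id mentions rDNA map to ``rdna_like``);
3. ``Simple/Sat`` — tandem periodicity detected by self-alignment at
   increasing diagonal offsets (the smallest qualifying offset is the
   monomer length);
4. ``LTR_like`` — a long terminal repeat: a prefix of at least ``min_len``
   bases matching the suffix of the same length at >= 80% identity;
5. ``Unknown``.

Periodicity out-ranks terminal-repeat detection because a tandem array
trivially contains prefix/suffix matches at array-period offsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ._seq import revcomp, to_array
from .copy_estimation import local_align
from .synthetic_genome import TELOMERE_MOTIF

LABELS = ("Simple/Sat", "LTR_like", "library_match", "telomeric", "rdna_like", "Unknown")


@dataclass(frozen=True)
class RepeatAnnotation:
    contig_id: str
    label: str
    detail: str = ""
    match_identity: float | None = None
    match_coverage: float | None = None


def detect_tandem_periodicity(
    contig: str, min_monomer: int = 5, min_identity: float = 0.8
) -> int | None:
    """Smallest offset p <= L/2 at which the contig matches itself shifted by
    p at >= ``min_identity``; None when no offset qualifies."""
    arr = to_array(contig)
    L = arr.size
    if L < 2 * min_monomer:
        raise ValueError(f"contig ({L} bp) shorter than twice the minimum monomer")
    for p in range(min_monomer, L // 2 + 1):
        matches = int(np.count_nonzero(arr[: L - p] == arr[p:]))
        if matches / (L - p) >= min_identity:
            return p
    return None


def detect_terminal_repeat(
    contig: str, min_len: int = 100, min_identity: float = 0.8
) -> int | None:
    """Length of the longest prefix (>= min_len, non-overlapping with the
    suffix) matching the equally long suffix at >= ``min_identity``."""
    arr = to_array(contig)
    L = arr.size
    if L < 2 * min_len:
        return None
    for t in range(L // 2, min_len - 1, -1):
        matches = int(np.count_nonzero(arr[:t] == arr[L - t:]))
        if matches / t >= min_identity:
            return t
    return None


def match_library(
    contig: str,
    library: dict[str, str],
    min_identity: float = 0.9,
    min_coverage: float = 0.6,
    min_hit_bp: int = 100,
) -> tuple[str, float, float] | None:
    """Best library entry covering the contig at the given thresholds.

    Coverage is the fraction of the contig covered by the union of hits to
    one entry that individually pass the identity threshold and span at
    least ``min_hit_bp`` aligned bases (a single local alignment cannot
    cover a tandem contig spanning several copies of a one-unit entry, while
    the length floor keeps short chance segments from faking coverage);
    identity is the length-weighted mean over those hits. Returns
    (entry_id, identity, coverage) of the entry maximising coverage x
    identity among entries passing both thresholds, or None.
    """
    if not library:
        raise ValueError("library is empty")
    best = None
    for entry_id in sorted(library):
        entry = library[entry_id]
        k = max(4, min(12, len(entry) // 2, len(contig) // 2))
        hit_floor = min(min_hit_bp, max(20, min(len(contig), len(entry)) // 2))
        hits = local_align(
            contig, entry, min_identity=min_identity,
            min_coverage=hit_floor / len(contig), seed_k=k,
            query_id="contig", target_id=entry_id,
        )
        if not hits:
            continue
        covered = np.zeros(len(contig), dtype=bool)
        weighted = 0.0
        for h in hits:
            covered[h.query_start:h.query_end] = True
            weighted += h.identity * h.aligned_length
        coverage = float(covered.mean())
        identity = weighted / sum(h.aligned_length for h in hits)
        if coverage >= min_coverage and identity >= min_identity:
            score = coverage * identity
            if best is None or score > best[0]:
                best = (score, entry_id, identity, coverage)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _telomere_run(contig: str, motif: str = TELOMERE_MOTIF, min_units: int = 10):
    """Longest run of consecutive motif units on either strand."""
    best = 0
    for seq in (contig, revcomp(contig)):
        for m in re.finditer(f"(?:{motif})+", seq):
            best = max(best, (m.end() - m.start()) // len(motif))
    return best if best >= min_units else 0


def classify(
    contig,
    library: dict[str, str] | None = None,
    min_monomer: int = 5,
    terminal_min_len: int = 100,
    structure_min_identity: float = 0.8,
    library_min_identity: float = 0.9,
    library_min_coverage: float = 0.6,
) -> RepeatAnnotation:
    """Assign a single repeat-class label to a contig (see module docstring
    for the precedence order). ``contig`` is a RepresentativeContig or a
    (contig_id, sequence) pair or a bare sequence string."""
    if hasattr(contig, "sequence"):
        contig_id, seq = contig.contig_id, contig.sequence
    elif isinstance(contig, tuple):
        contig_id, seq = contig
    else:
        contig_id, seq = "contig", contig

    units = _telomere_run(seq)
    if units:
        covered = units * len(TELOMERE_MOTIF) / len(seq)
        return RepeatAnnotation(
            contig_id, "telomeric", f"{TELOMERE_MOTIF}x{units}", 1.0, round(covered, 4)
        )

    if library:
        match = match_library(seq, library, library_min_identity, library_min_coverage)
        if match is not None:
            entry_id, identity, coverage = match
            label = "rdna_like" if "rdna" in entry_id.lower() else "library_match"
            return RepeatAnnotation(
                contig_id, label, entry_id, round(identity, 4), round(coverage, 4)
            )

    if len(seq) >= 2 * min_monomer:
        period = detect_tandem_periodicity(seq, min_monomer, structure_min_identity)
        if period is not None:
            return RepeatAnnotation(contig_id, "Simple/Sat", f"monomer={period}")

    tr = detect_terminal_repeat(seq, terminal_min_len, structure_min_identity)
    if tr is not None:
        return RepeatAnnotation(contig_id, "LTR_like", f"terminal_repeat={tr}")

    return RepeatAnnotation(contig_id, "Unknown")


def bundled_library() -> dict[str, str]:
    """The small synthetic fixture library shipped with the package
    (telomere motif array, a 140-bp satellite consensus, an rDNA-unit
    stand-in; all generated sequences, nothing downloaded)."""
    path = resources.files("repeatscope").joinpath("data/library.fasta")
    from .synthetic_genome import read_fasta

    return read_fasta(Path(str(path)))


def write_annotations(annotations, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlabel\tdetail\tmatch_identity\tmatch_coverage\n")
        for a in annotations:
            ident = "" if a.match_identity is None else f"{a.match_identity}"
            cov = "" if a.match_coverage is None else f"{a.match_coverage}"
            fh.write(f"{a.contig_id}\t{a.label}\t{a.detail}\t{ident}\t{cov}\n")
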