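"""Comparative presence/absence survey of repeats across samples.

The computational analog of a comparative cytological survey: a repeat's
abundance in each sample is its read-mapping copy number from that sample's
1x read set, presence is abundance above a copy threshold (detectability
implies many copies), and each repeat's presence row across an outgroup, a
reference sample and several ingroup samples is classified into one of four
patterns:

* type1 — present in the outgroup and in every ingroup sample (ancestral,
  shared);
* type2 — present in every ingroup sample but absent from the outgroup
  (arose/amplified after the split);
* type3 — present in a proper nonempty subset of the ingroup (dynamic
  within the ingroup; the outgroup may be either);
* type4 — absent from every sample except possibly the reference itself
  (reference-specific);
* other — any remaining combination.

Precedence is type1 > type2 > type3 > type4 > other; every boolean row
receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .copy_estimation import read_copy_number
from .read_sim import ReadSet

PATTERN_LABELS = ("type1", "type2", "type3", "type4", "other")


@dataclass
class PresenceMatrix:
    families: list[str]
    samples: list[str]
    copies: np.ndarray  # shape (n_families, n_samples)
    present: np.ndarray | None = None
    presence_threshold: float | None = None
    pattern_type: dict[str, str] = field(default_factory=dict)

    def row(self, family: str) -> dict[str, float]:
        i = self.families.index(family)
        return dict(zip(self.samples, self.copies[i].tolist()))

    def present_row(self, family: str) -> dict[str, bool]:
        if self.present is None:
            raise ValueError("presence not called yet; run call_presence first")
        i = self.families.index(family)
        return dict(zip(self.samples, self.present[i].tolist()))


def abundance_matrix(
    contigs: Mapping[str, str],
    samples: list[tuple[str, ReadSet, int]],
    min_identity: float = 0.7,
    min_coverage: float = 0.7,
    merge_overlaps: bool = False,
) -> PresenceMatrix:
    """Read-based copy estimates for every (repeat contig, sample) pair.

    Each sample's read set must be a 1x sample of its own genome so that
    copy estimates are comparable across samples.
    """
    families = list(contigs)
    sample_ids = [s[0] for s in samples]
    copies = np.zeros((len(families), len(samples)))
    for i, fam in enumerate(families):
        for j, (_sid, readset, _gsize) in enumerate(samples):
            est = read_copy_number(
                contigs[fam], readset, min_identity, min_coverage,
                contig_id=fam, merge_overlaps=merge_overlaps,
            )
            copies[i, j] = est.copies
    return PresenceMatrix(families, sample_ids, copies)


def call_presence(matrix: PresenceMatrix, min_copies: float = 10.0) -> PresenceMatrix:
    """Present iff copies >= ``min_copies`` (inclusive)."""
    matrix.present = matrix.copies >= min_copies
    matrix.presence_threshold = min_copies
    return matrix


def classify_pattern(
    present_row: Mapping[str, bool],
    reference_sample_id: str,
    outgroup_sample_id: str,
) -> str:
    """Label one repeat's presence row (see module docstring)."""
    if reference_sample_id not in present_row or outgroup_sample_id not in present_row:
        raise ValueError("row must cover the reference and outgroup samples")
    ingroup = [s for s in present_row if s not in (reference_sample_id, outgroup_sample_id)]
    if len(ingroup) < 2:
        raise ValueError("row must cover at least two ingroup samples")
    out = bool(present_row[outgroup_sample_id])
    n_in = sum(bool(present_row[s]) for s in ingroup)
    if out and n_in == len(ingroup):
        return "type1"
    if not out and n_in == len(ingroup):
        return "type2"
    if 0 < n_in < len(ingroup):
        return "type3"
    if not out and n_in == 0:
        return "type4"
    return "other"


def classify_patterns(
    matrix: PresenceMatrix, reference_sample_id: str, outgroup_sample_id: str
) -> PresenceMatrix:
    for fam in matrix.families:
        matrix.pattern_type[fam] = classify_pattern(
            matrix.present_row(fam), reference_sample_id, outgroup_sample_id
        )
    return matrix


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(matrix.samples) + "\tpattern\n")
        for i, fam in enumerate(matrix.families):
            vals = "\t".join(f"{v:.1f}" for v in matrix.copies[i])
            fh.write(f"{fam}\t{vals}\t{matrix.pattern_type.get(fam, '')}\n")
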