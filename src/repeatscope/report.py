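"""Summary-table assembly: one row per repeat contig.

The end report mirrors the layout of a repeat-survey summary table:
classification, genomic distribution, localization notes, the two
copy-number estimates, and their fold change (read-based / assembly-based,
one decimal; "NA" with an absent-from-assembly flag when the repeat has no
assembly copies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .annotation import RepeatAnnotation
from .copy_estimation import CopyEstimate
from .distribution import DistributionProfile

logger = logging.getLogger(__name__)


def per_chromosome_copy_threshold(n_chromosomes: int, copies_per_chromosome: int = 4) -> int:
    """Minimum-copy cutoff equivalent to an average of ``copies_per_chromosome``
    copies on each chromosome (e.g. 4 x 80 = 320, 4 x 64 = 256)."""
    if n_chromosomes < 1 or copies_per_chromosome < 1:
        raise ValueError("chromosome and copy counts must be positive")
    return n_chromosomes * copies_per_chromosome


@dataclass
class RepeatReportRow:
    repeat_id: str
    cluster_id: str
    classification: str
    distribution: str
    localization: str
    assembly_copies: float | None
    read_copies: float | None
    fold_change: str  # one decimal, or "NA"
    params: str


def format_fold_change(read_copies: float | None, assembly_copies: float | None) -> str:
    if read_copies is None or assembly_copies is None or assembly_copies == 0:
        return "NA"
    return f"{read_copies / assembly_copies:.1f}"


def build_report(
    estimates: dict[str, tuple[CopyEstimate | None, CopyEstimate | None]],
    annotations: dict[str, RepeatAnnotation],
    profiles: dict[str, DistributionProfile],
    cluster_ids: dict[str, str] | None = None,
) -> list[RepeatReportRow]:
    """One row per contig appearing in any input, ordered by descending
    read-based copies. Missing upstream records yield explicit "NA" fields
    and a warning."""
    contig_ids = sorted(set(estimates) | set(annotations) | set(profiles))
    rows = []
    for cid in contig_ids:
        read_est, assembly_est = estimates.get(cid, (None, None))
        ann = annotations.get(cid)
        prof = profiles.get(cid)
        missing = [
            name
            for name, item in (
                ("read estimate", read_est),
                ("assembly estimate", assembly_est),
                ("annotation", ann),
                ("profile", prof),
            )
            if item is None
        ]
        if missing:
            logger.warning("contig %s missing upstream records: %s", cid, ", ".join(missing))
        read_copies = read_est.copies if read_est else None
        assembly_copies = assembly_est.copies if assembly_est else None
        fold = format_fold_change(read_copies, assembly_copies)
        localization = []
        if assembly_copies == 0:
            localization.append("absent-from-assembly")
        if prof is not None and prof.terminal_enriched:
            localization.append("terminal")
        params = ""
        if read_est is not None:
            mi, mc = read_est.params
            params = f"id>{mi};cov>{mc};merge={'on' if read_est.merged else 'off'}"
        rows.append(
            RepeatReportRow(
                repeat_id=cid,
                cluster_id=(cluster_ids or {}).get(cid, "NA"),
                classification=ann.label if ann else "NA",
                distribution=(prof.dispersion_class or "NA") if prof else "NA",
                localization=";".join(localization),
                assembly_copies=assembly_copies,
                read_copies=read_copies,
                fold_change=fold,
                params=params,
            )
        )
    rows.sort(key=lambda r: (-(r.read_copies if r.read_copies is not None else -1), r.repeat_id))
    return rows


_COLUMNS = (
    "repeat_id", "cluster_id", "classification", "distribution", "localization",
    "assembly_copies", "read_copies", "fold_change", "params",
)


def write_report_tsv(rows: list[RepeatReportRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.repeat_id,
                        r.cluster_id,
                        r.classification,
                        r.distribution,
                        r.localization,
                        "NA" if r.assembly_copies is None else repr(r.assembly_copies),
                        "NA" if r.read_copies is None else repr(r.read_copies),
                        r.fold_change,
                        r.params,
                    ]
                )
                + "\n"
            )


def read_report_tsv(path: str | Path) -> list[RepeatReportRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected report header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                RepeatReportRow(
                    repeat_id=f[0],
                    cluster_id=f[1],
                    classification=f[2],
                    distribution=f[3],
                    localization=f[4],
                    assembly_copies=None if f[5] == "NA" else float(f[5]),
                    read_copies=None if f[6] == "NA" else float(f[6]),
                    fold_change=f[7],
                    params=f[8],
                )
            )
    return rows
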