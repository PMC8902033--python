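"""The standard synthetic study cohort and its analysis configuration.

These are the fixed conditions under which the pipeline's parameter recovery
is evaluated throughout the test suite and the acceptance script: a 2-Mb
four-chromosome genome carrying

* ``SAT140``  — a 140-bp centromeric-satellite-like monomer, 1000 tandem
  copies at a single locus;
* ``RDNA3K``  — a 3-kb rDNA-unit-like monomer, 50 tandem copies at a single
  locus;
* ``LTR5K``   — a 5-kb LTR-element-like sequence (300-bp terminal repeats),
  100 copies scattered uniformly on both strands;
* ``TEL7``    — the plant telomere motif TTTAGGG, 9600 copies split across
  the eight chromosome ends (8.4 kb per telomere);

all planted at 5% intra-family divergence over a GC 0.44 background (~43%
of the genome is repeat-derived, echoing the repeat-rich genomes this
pipeline is aimed at). The satellite and rDNA consensus sequences are the
same synthetic sequences shipped in the bundled annotation library, so
library matching can be exercised without any downloaded data.

Consensus sequences are generated from fixed private seeds and are therefore
identical across installations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .copy_estimation import read_copy_number, tandem_reference
from .read_sim import ReadSet
from .synthetic_genome import (
    DEFAULT_ELEMENT_BP,
    DEFAULT_RDNA_UNIT_BP,
    DEFAULT_SATELLITE_MONOMER_BP,
    DEFAULT_TERMINAL_REPEAT_BP,
    TELOMERE_MOTIF,
    GenomeSpec,
    RepeatFamilySpec,
    build_genome,
    make_element,
    random_sequence,
)

_SATELLITE_SEED = 914_140
_RDNA_SEED = 914_300
_ELEMENT_SEED = 914_500

CHROMOSOMES = {"chr1": 500_000, "chr2": 500_000, "chr3": 500_000, "chr4": 500_000}
READ_LENGTH = 150
DIVERGENCE = 0.05

#: Analysis parameters used with this cohort. The dispersion rule's window
#: budget is scaled to toy genomes: a planted array here spans up to ~7% of
#: the 2-Mb sequence (vs a vanishing fraction of a multi-Gb genome), so the
#: qualifying-window span is set to 5% of the genome.
ANALYSIS = {
    "window_bp": 10_000,
    "concentration_fraction": 0.5,
    "span_fraction": 0.05,
    "terminal_bp": 50_000,
    "terminal_fraction": 0.5,
    "min_identity": 0.7,
    "min_coverage": 0.7,
    "merge_overlaps": True,
}

#: Expected annotation label for each planted family kind.
KIND_TO_LABEL = {
    "tandem_satellite": "Simple/Sat",
    "dispersed_element": "LTR_like",
    "rdna_array": "rdna_like",
    "telomeric_array": "telomeric",
}


@lru_cache(maxsize=None)
def satellite_consensus() -> str:
    return random_sequence(np.random.default_rng(_SATELLITE_SEED), DEFAULT_SATELLITE_MONOMER_BP)


@lru_cache(maxsize=None)
def rdna_consensus() -> str:
    return random_sequence(np.random.default_rng(_RDNA_SEED), DEFAULT_RDNA_UNIT_BP)


@lru_cache(maxsize=None)
def element_consensus() -> str:
    return make_element(
        np.random.default_rng(_ELEMENT_SEED), DEFAULT_ELEMENT_BP, DEFAULT_TERMINAL_REPEAT_BP
    )


def standard_families() -> tuple[RepeatFamilySpec, ...]:
    chroms = tuple(CHROMOSOMES)
    return (
        RepeatFamilySpec(
            "SAT140", "tandem_satellite", satellite_consensus(), 1000,
            DIVERGENCE, "single_locus", ("chr1",),
        ),
        RepeatFamilySpec(
            "RDNA3K", "rdna_array", rdna_consensus(), 50,
            DIVERGENCE, "single_locus", ("chr2",),
        ),
        RepeatFamilySpec(
            "LTR5K", "dispersed_element", element_consensus(), 100,
            DIVERGENCE, "uniform_scatter", chroms,
        ),
        RepeatFamilySpec(
            "TEL7", "telomeric_array", TELOMERE_MOTIF, 9600,
            DIVERGENCE, "terminal", chroms,
        ),
    )


def standard_cohort_spec(seed: int = 0) -> GenomeSpec:
    return GenomeSpec(
        chromosome_lengths=dict(CHROMOSOMES),
        families=standard_families(),
        background_gc=0.44,
        seed=seed,
    )


def build_standard_cohort(seed: int = 0):
    """(genome, truth) for the standard cohort at the given seed."""
    return build_genome(standard_cohort_spec(seed))


def recovery_reference(family: str) -> tuple[str, float]:
    """(reference sequence, units per reference) for planted-copy recovery.

    Tandem monomers shorter than a read are concatenated head-to-tail until
    any read phase fits inside (see ``tandem_reference``); the returned unit
    factor converts reference-copy estimates back to planted-monomer copies.
    """
    consensi = {
        "SAT140": satellite_consensus(),
        "RDNA3K": rdna_consensus(),
        "LTR5K": element_consensus(),
        "TEL7": TELOMERE_MOTIF,
    }
    monomer = consensi[family]
    if family == "LTR5K":
        return monomer, 1.0
    ref = tandem_reference(monomer, READ_LENGTH)
    return ref, len(ref) / len(monomer)


def estimate_planted_copies(family: str, reads_1x: ReadSet) -> float:
    """Read-mapping estimate of a planted family's monomer copy number."""
    ref, units = recovery_reference(family)
    est = read_copy_number(
        ref, reads_1x,
        min_identity=ANALYSIS["min_identity"],
        min_coverage=ANALYSIS["min_coverage"],
        contig_id=family,
        merge_overlaps=ANALYSIS["merge_overlaps"],
    )
    return est.copies * units


PLANTED_COPIES = {"SAT140": 1000, "RDNA3K": 50, "LTR5K": 100, "TEL7": 9600}


# ---------------------------------------------------------------------------
# comparative-survey cohorts

COMPARATIVE_PATTERNS = {
    "type1": {"REF": True, "OUT": True, "ING1": True, "ING2": True, "ING3": True},
    "type2": {"REF": True, "OUT": False, "ING1": True, "ING2": True, "ING3": True},
    "type3": {"REF": True, "OUT": True, "ING1": True, "ING2": True, "ING3": False},
    "type4": {"REF": True, "OUT": False, "ING1": False, "ING2": False, "ING3": False},
}


def comparative_cohort_spec(present: bool, seed: int) -> GenomeSpec:
    """A small single-sample genome for the comparative survey: a 150-kb
    genome that either carries 200 tandem copies of the standard satellite
    or none at all."""
    families = []
    if present:
        families.append(
            RepeatFamilySpec(
                "SAT140", "tandem_satellite", satellite_consensus(), 200,
                DIVERGENCE, "single_locus", ("c1",),
            )
        )
    return GenomeSpec({"c1": 80_000, "c2": 70_000}, tuple(families), 0.44, seed)
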