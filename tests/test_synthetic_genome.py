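"""Synthetic genome generator: planted truth, mutation model, collapse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatscope.synthetic_genome import (
    CapacityError,
    GenomeSpec,
    GroundTruth,
    RepeatFamilySpec,
    build_genome,
    collapse_assembly,
    mutate_copy,
    random_sequence,
    read_fasta,
    write_fasta,
)

RNG = np.random.default_rng


def _spec(families, lengths=None, seed=0, **kw):
    return GenomeSpec(lengths or {"chr1": 100_000}, tuple(families), seed=seed, **kw)


class TestBuildGenome:
    def test_zero_divergence_satellite_locus_is_exact_monomer_array(self):
        monomer = random_sequence(RNG(1), 140)
        fam = RepeatFamilySpec("SAT", "tandem_satellite", monomer, 100, 0.0,
                               "single_locus", ("chr1",))
        genome, truth = build_genome(_spec([fam]))
        ivs = truth.family_intervals("SAT")
        assert len(ivs) == 100
        assert all(iv.end - iv.start == 140 for iv in ivs)
        # contiguous head-to-tail
        ivs = sorted(ivs, key=lambda iv: iv.start)
        assert all(a.end == b.start for a, b in zip(ivs, ivs[1:]))
        locus = genome["chr1"][ivs[0].start: ivs[-1].end]
        assert locus == monomer * 100

    def test_dispersed_copies_are_non_overlapping_and_counted(self):
        lengths = {f"chr{i}": 200_000 for i in range(1, 6)}
        fam = RepeatFamilySpec("ELT", "dispersed_element", 400, 500, 0.05,
                               "uniform_scatter", tuple(lengths),
                               terminal_repeat_bp=50)
        genome, truth = build_genome(_spec([fam], lengths))
        ivs = truth.family_intervals("ELT")
        assert len(ivs) == 500
        per_chrom = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
        assert sum(len(v) for v in per_chrom.values()) == 500
        for spans in per_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_telomeric_arrays_touch_chromosome_ends(self):
        lengths = {"chr1": 60_000, "chr2": 60_000}
        fam = RepeatFamilySpec("TEL", "telomeric_array", "TTTAGGG", 400, 0.0,
                               "terminal", ("chr1", "chr2"))
        _genome, truth = build_genome(_spec([fam], lengths))
        loci = truth.family_loci("TEL")
        assert len(loci) == 4
        for chrom, start, end in loci:
            assert start == 0 or end == lengths[chrom]

    def test_capacity_error_names_the_chromosome(self):
        fam = RepeatFamilySpec("SAT", "tandem_satellite", 1000, 200, 0.0,
                               "single_locus", ("chr1",))
        with pytest.raises(CapacityError, match="chr1"):
            build_genome(_spec([fam], {"chr1": 50_000}))

    def test_deterministic_for_fixed_seed(self, tmp_path):
        fam = RepeatFamilySpec("SAT", "tandem_satellite", 140, 50, 0.05,
                               "single_locus", ("chr1",))
        g1, t1 = build_genome(_spec([fam], seed=42))
        g2, t2 = build_genome(_spec([fam], seed=42))
        assert g1 == g2 and t1.intervals == t2.intervals
        # byte-identical FASTA/BED
        for g, t, tag in ((g1, t1, "a"), (g2, t2, "b")):
            write_fasta(g, tmp_path / f"{tag}.fasta")
            t.to_bed(tmp_path / f"{tag}.bed")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_conservation_and_bounds(self):
        fams = [
            RepeatFamilySpec("SAT", "tandem_satellite", 140, 100, 0.05,
                             "single_locus", ("chr1",)),
            RepeatFamilySpec("ELT", "dispersed_element", 2000, 10, 0.05,
                             "uniform_scatter", ("chr1", "chr2")),
        ]
        lengths = {"chr1": 100_000, "chr2": 80_000}
        genome, truth = build_genome(_spec(fams, lengths))
        assert {k: len(v) for k, v in genome.items()} == lengths
        planted = sum(iv.end - iv.start for iv in truth.intervals)
        assert planted == 100 * 140 + 10 * 2000
        for iv in truth.intervals:
            assert 0 <= iv.start < iv.end <= lengths[iv.chromosome]

    def test_bed_round_trip(self, tmp_path):
        fam = RepeatFamilySpec("SAT", "tandem_satellite", 140, 20, 0.05,
                               "single_locus", ("chr1",))
        _genome, truth = build_genome(_spec([fam]))
        truth.to_bed(tmp_path / "t.bed")
        back = GroundTruth.from_bed(tmp_path / "t.bed")
        assert back.intervals == truth.intervals


class TestMutateCopy:
    def test_identity_at_zero_divergence(self):
        assert mutate_copy("ACGT", 0.0, RNG(0)) == "ACGT"

    def test_hamming_distance_matches_binomial(self):
        template = "A" * 10_000
        out = mutate_copy(template, 0.1, RNG(7))
        dist = sum(a != b for a, b in zip(template, out))
        sigma = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(dist - 1000) <= 3 * sigma

    def test_half_divergence_identity_near_half(self):
        template = random_sequence(RNG(3), 20_000)
        out = mutate_copy(template, 0.5, RNG(4))
        ident = sum(a == b for a, b in zip(template, out)) / 20_000
        # substitutions always change the base, so E[identity] = 0.5
        assert abs(ident - 0.5) <= 3 * np.sqrt(0.25 / 20_000)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300),
           st.floats(min_value=0.0, max_value=0.5),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_substitution_only(self, template, divergence, seed):
        out = mutate_copy(template, divergence, RNG(seed))
        assert len(out) == len(template)
        assert set(out) <= set("ACGT")


class TestCollapseAssembly:
    def _tandem_genome(self, copies=1000, seed=5):
        monomer = random_sequence(RNG(11), 140)
        fam = RepeatFamilySpec("SAT", "tandem_satellite", monomer, copies, 0.05,
                               "single_locus", ("chr1",))
        return build_genome(_spec([fam], {"chr1": 300_000}, seed=seed))

    def test_factor_one_is_identity(self):
        genome, truth = self._tandem_genome(copies=100)
        assembly, atruth = collapse_assembly(genome, truth, {"SAT": 1})
        assert assembly == genome
        assert atruth.intervals == truth.intervals

    def test_factor_ten_keeps_a_tenth_and_shortens(self):
        genome, truth = self._tandem_genome(copies=1000)
        assembly, atruth = collapse_assembly(genome, truth, {"SAT": 10})
        assert atruth.copy_count("SAT") == 100
        assert len(assembly["chr1"]) == len(genome["chr1"]) - 900 * 140
        # remaining copies are still contiguous and carry correct sequence
        loci = atruth.family_loci("SAT")
        assert len(loci) == 1 and loci[0][2] - loci[0][1] == 100 * 140

    def test_two_loci_collapsed_independently(self):
        monomer = random_sequence(RNG(12), 100)
        fam = RepeatFamilySpec("SAT", "tandem_satellite", monomer, 80, 0.0,
                               "per_chromosome_locus", ("chr1", "chr2"))
        genome, truth = build_genome(
            _spec([fam], {"chr1": 50_000, "chr2": 50_000}))
        assembly, atruth = collapse_assembly(genome, truth, {"SAT": 4})
        loci = atruth.family_loci("SAT")
        assert sorted(l[2] - l[1] for l in loci) == [10 * 100, 10 * 100]

    def test_other_families_coordinates_remapped(self):
        monomer = random_sequence(RNG(13), 140)
        fams = [
            RepeatFamilySpec("SAT", "tandem_satellite", monomer, 200, 0.0,
                             "single_locus", ("chr1",)),
            RepeatFamilySpec("ELT", "dispersed_element", 1000, 5, 0.0,
                             "uniform_scatter", ("chr1",), terminal_repeat_bp=100),
        ]
        genome, truth = build_genome(_spec(fams, {"chr1": 200_000}, seed=9))
        assembly, atruth = collapse_assembly(genome, truth, {"SAT": 5})
        originals = {iv.copy_index: iv for iv in truth.family_intervals("ELT")}
        for iv in atruth.family_intervals("ELT"):
            orig = originals[iv.copy_index]
            assert assembly[iv.chromosome][iv.start:iv.end] == \
                genome[orig.chromosome][orig.start:orig.end]

    def test_invalid_factors_rejected(self):
        genome, truth = self._tandem_genome(copies=50)
        with pytest.raises(ValueError, match=">= 1"):
            collapse_assembly(genome, truth, {"SAT": 0.5})
        fams = [RepeatFamilySpec("ELT", "dispersed_element", 500, 5, 0.0,
                                 "uniform_scatter", ("chr1",),
                                 terminal_repeat_bp=100)]
        g2, t2 = build_genome(_spec(fams, {"chr1": 100_000}))
        with pytest.raises(ValueError, match="unsupported|dispersed"):
            collapse_assembly(g2, t2, {"ELT": 2})


class TestSpecValidation:
    def test_telomeric_requires_terminal_placement(self):
        with pytest.raises(ValueError, match="terminal"):
            RepeatFamilySpec("T", "telomeric_array", "TTTAGGG", 10, 0.0,
                             "single_locus", ("chr1",))

    def test_divergence_bounds(self):
        with pytest.raises(ValueError, match="divergence"):
            RepeatFamilySpec("S", "tandem_satellite", 140, 10, 0.6,
                             "single_locus", ("chr1",))

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 50, "b": "TTTAGGG" * 30}
        write_fasta(seqs, tmp_path / "x.fasta")
        assert read_fasta(tmp_path / "x.fasta") == seqs
        # 60-column wrapping
        lines = (tmp_path / "x.fasta").read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60
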