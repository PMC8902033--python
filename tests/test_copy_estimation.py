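"""Alignment engine and copy-number estimators, checked against an
independent exhaustive oracle.

The oracle enumerates *every* diagonal of the gapless alignment space on
both strands and applies the identity/coverage filters directly — no
seeding, no shared code path with the engine beyond byte comparison.
"""

import numpy as np
import pytest

from repeatscope._seq import revcomp
from repeatscope.copy_estimation import (
    AbsentFromAssemblyError,
    assembly_copy_number,
    fold_change,
    local_align,
    read_copy_number,
    read_hits_outfmt6,
    tandem_reference,
    write_hits_outfmt6,
)
from repeatscope.read_sim import Read, ReadSet, simulate_reads
from repeatscope.synthetic_genome import mutate_copy, random_sequence

RNG = np.random.default_rng


from alignment_oracle import engine_hit_set, oracle_hits, random_instance


def _reads_from(seqs, read_length=150):
    reads = [Read(f"r{i}", s, None) for i, s in enumerate(seqs)]
    return ReadSet(reads, read_length, sum(len(s) for s in seqs))


class TestLocalAlign:
    def test_substring_gives_single_perfect_hit(self):
        target = random_sequence(RNG(1), 2000)
        query = target[500:900]
        hits = local_align(query, target, 0.7, 0.7)
        exact = [h for h in hits if h.identity == 1.0 and h.strand == "+"]
        assert any(h.target_start == 500 and h.target_end == 900 and
                   h.query_start == 0 and h.query_end == 400 for h in exact)

    def test_reverse_complement_hit_on_minus_strand(self):
        target = random_sequence(RNG(2), 2000)
        query = revcomp(target[300:700])
        hits = [h for h in local_align(query, target, 0.7, 0.7) if h.identity == 1.0]
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-" and (h.target_start, h.target_end) == (300, 700)

    def test_heavily_diverged_copy_yields_no_hits(self):
        # expected identity 0.55 — even the best trimmed segment stays far
        # below the 70% identity filter
        target = random_sequence(RNG(3), 3000)
        copy = mutate_copy(target[1000:1400], 0.45, RNG(4))
        assert local_align(copy, target, 0.7, 0.7) == []
        assert oracle_hits(copy, target, 0.7, 0.7) == set()

    def test_rejects_empty_sequences(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_oracle_equivalence_on_randomized_instances(self):
        """Engine hit set == exhaustive-oracle hit set on planted instances
        with full, truncated and reverse-strand copies plus below-threshold
        decoys (the full 200-instance battery runs in the acceptance suite)."""
        rng = RNG(20_260_101)
        for trial in range(40):
            query, target = random_instance(rng)
            assert engine_hit_set(query, target) == oracle_hits(query, target, 0.7, 0.7), \
                f"hit sets differ on trial {trial}"

    def test_seeded_path_finds_all_planted_copies_in_large_target(self):
        """On a target big enough to engage k-mer seeding, every planted
        copy at realistic divergence is recovered."""
        rng = RNG(77)
        target = list(random_sequence(rng, 150_000))
        query = random_sequence(rng, 400)
        positions = []
        for i in range(20):
            copy = mutate_copy(query, float(rng.uniform(0, 0.10)), rng)
            if i % 3 == 0:
                copy = revcomp(copy)
            pos = 1000 + i * 7000  # disjoint slots so copies stay intact
            target[pos:pos + 400] = copy
            positions.append(pos)
        target = "".join(target)
        hits = local_align(query, target, 0.7, 0.7)
        for pos in positions:
            # trimming may clip a mutated first/last base, so require a hit
            # spanning at least 90% of the planted interval
            assert any(min(h.target_end, pos + 400) - max(h.target_start, pos) >= 360
                       for h in hits), pos

    def test_filter_monotonicity(self):
        rng = RNG(55)
        target = list(random_sequence(rng, 4000))
        query = random_sequence(rng, 300)
        for div in (0.05, 0.15, 0.25):
            copy = mutate_copy(query, div, rng)
            pos = int(rng.integers(0, 4000 - 300))
            target[pos:pos + 300] = copy
        target = "".join(target)
        prev = None
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            est = assembly_copy_number(query, {"c": target}, thr, thr)
            if prev is not None:
                assert est.copies <= prev + 1e-12
            prev = est.copies


class TestAssemblyCopyNumber:
    def test_hundred_planted_copies_recovered(self):
        rng = RNG(8)
        monomer = random_sequence(rng, 140)
        chrom = random_sequence(rng, 10_000) + monomer * 100 + random_sequence(rng, 10_000)
        ref = tandem_reference(monomer, 150)
        est = assembly_copy_number(ref, {"chr1": chrom}, merge_overlaps=True)
        monomer_copies = est.copies * len(ref) / len(monomer)
        assert 99 <= monomer_copies <= 101

    def test_absent_contig_zero(self):
        est = assembly_copy_number(random_sequence(RNG(9), 300),
                                   {"c": random_sequence(RNG(10), 5000)})
        assert est.copies == 0.0

    def test_contig_equal_to_assembly_is_one_copy(self):
        seq = random_sequence(RNG(11), 2000)
        est = assembly_copy_number(seq, {"c": seq})
        assert est.copies == pytest.approx(1.0)

    def test_copies_equals_total_over_length(self):
        seq = random_sequence(RNG(12), 1500)
        est = assembly_copy_number(seq[:400], {"c": seq})
        assert est.copies == est.total_aligned_length / est.contig_length


class TestReadCopyNumber:
    def test_reads_tiling_contig_give_one_copy(self):
        contig = random_sequence(RNG(13), 1500)
        seqs = [contig[i:i + 150] for i in range(0, 1500, 150)]
        est = read_copy_number(contig, _reads_from(seqs))
        assert est.copies == pytest.approx(1.0)

    def test_unrelated_reads_give_zero(self):
        contig = random_sequence(RNG(14), 600)
        seqs = [random_sequence(RNG(100 + i), 150) for i in range(50)]
        assert read_copy_number(contig, _reads_from(seqs)).copies == 0.0

    def test_empty_read_set_gives_zero(self):
        contig = random_sequence(RNG(15), 600)
        assert read_copy_number(contig, ReadSet([], 150, 0)).copies == 0.0

    def test_matches_per_read_local_align_on_small_instance(self):
        """Dual route: the batched read estimator equals summing seeded
        local_align aligned lengths read by read."""
        rng = RNG(16)
        genome = {"c": random_sequence(rng, 5_000) +
                  random_sequence(rng, 900) * 3 + random_sequence(rng, 5_000)}
        contig = genome["c"][5000:5900] * 1  # one planted unit
        reads = simulate_reads(genome, 1.0, 150, 0.0, seed=17)
        est = read_copy_number(contig, reads)
        total = 0
        for r in reads.reads:
            total += sum(h.aligned_length
                         for h in local_align(r.sequence, contig, 0.7, 0.7))
        assert est.total_aligned_length == total

    def test_merge_overlaps_counts_each_base_once(self):
        # periodic contig: an interior read matches at several phases
        monomer = random_sequence(RNG(18), 100)
        contig = monomer * 5
        read = (monomer * 3)[25:175]
        unmerged = read_copy_number(contig, _reads_from([read]))
        merged = read_copy_number(contig, _reads_from([read]), merge_overlaps=True)
        assert merged.total_aligned_length == 150
        assert unmerged.total_aligned_length > 150


class TestFoldChange:
    @pytest.mark.parametrize(
        "read_copies, assembly_copies, printed",
        [(44408, 18174, 2.4), (71582, 35043, 2.0), (64493, 2927, 22.0)],
    )
    def test_worked_examples_round_to_printed_ratio(self, read_copies,
                                                    assembly_copies, printed):
        assert round(fold_change(read_copies, assembly_copies), 1) == printed

    def test_equal_estimates_give_one(self):
        assert fold_change(123.0, 123.0) == pytest.approx(1.0)

    def test_absent_from_assembly_flagged(self):
        with pytest.raises(AbsentFromAssemblyError):
            fold_change(100.0, 0.0)

    def test_mismatched_contigs_rejected(self):
        a = assembly_copy_number("ACGT" * 100, {"c": "ACGT" * 100}, contig_id="x")
        b = assembly_copy_number("ACGT" * 100, {"c": "ACGT" * 100}, contig_id="y")
        with pytest.raises(ValueError, match="different contigs"):
            fold_change(a, b)


class TestHitsIO:
    def test_outfmt6_round_trip(self, tmp_path):
        target = random_sequence(RNG(19), 2000)
        query = revcomp(target[250:650])
        hits = local_align(query, target, 0.7, 0.7, query_id="q", target_id="t")
        write_hits_outfmt6(hits, tmp_path / "hits.tsv")
        back = read_hits_outfmt6(tmp_path / "hits.tsv")
        assert [(h.query_id, h.target_id, h.query_start, h.query_end,
                 h.target_start, h.target_end, h.strand) for h in back] == \
               [(h.query_id, h.target_id, h.query_start, h.query_end,
                 h.target_start, h.target_end, h.strand) for h in hits]
        # 12 BLAST-style columns
        line = (tmp_path / "hits.tsv").read_text().splitlines()[0]
        assert len(line.split("\t")) == 12
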