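"""End-to-end pipeline driver: simulate -> reads -> cluster -> annotate ->
estimate -> profile -> report, with a reproducibility manifest.

The pipeline is configured from a small YAML document (see
``data/demo_config.yaml`` for the documented schema) and writes every
intermediate artifact to the output directory as plain text (FASTA, FASTQ,
BED, bedGraph, outfmt-6-style hit TSV, report TSV, JSON manifest). Re-running
with an identical configuration reproduces every output byte for byte; the
manifest records the configuration, all seeds and parameters, and the SHA-256
of each output, plus an overall manifest hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .annotation import bundled_library, classify, write_annotations
from .copy_estimation import (
    align_to_genome,
    assembly_copy_number,
    build_genome_indexes,
    read_copy_number,
    write_hits_outfmt6,
)
from .distribution import classify_dispersion, profile, terminal_enrichment, write_bedgraph
from .read_sim import reads_for_1x, simulate_reads, subsample, write_fastq
from .repeat_discovery import (
    build_representative_contig,
    cluster_reads,
    enriched_clusters,
    write_cluster_members,
    write_cluster_table,
)
from .report import build_report, write_report_tsv
from .synthetic_genome import (
    GenomeSpec,
    RepeatFamilySpec,
    build_genome,
    collapse_assembly,
    write_fasta,
)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def genome_spec_from_config(config: dict, seed: int) -> GenomeSpec:
    g = config["genome"]
    families = []
    for f in g.get("families", []):
        monomer = f.get("monomer", f.get("monomer_bp"))
        if monomer is None:
            raise ValueError(f"family {f.get('name')} needs 'monomer' or 'monomer_bp'")
        families.append(
            RepeatFamilySpec(
                name=f["name"],
                kind=f["kind"],
                monomer_or_element=monomer,
                copy_number=int(f["copies"]),
                divergence=float(f.get("divergence", 0.05)),
                placement=f["placement"],
                chromosomes=tuple(f.get("chromosomes", ())),
                terminal_repeat_bp=int(f.get("terminal_repeat_bp", 300)),
            )
        )
    return GenomeSpec(
        chromosome_lengths={k: int(v) for k, v in g["chromosomes"].items()},
        families=tuple(families),
        background_gc=float(g.get("background_gc", 0.44)),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the full pipeline described by ``config``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    # 1. synthetic genome + collapsed assembly
    spec = genome_spec_from_config(config, seed)
    genome, truth = build_genome(spec)
    collapse = {k: float(v) for k, v in (config.get("collapse") or {}).items()}
    assembly, assembly_truth = collapse_assembly(genome, truth, collapse)
    write_fasta(genome, outdir / "genome.fasta")
    truth.to_bed(outdir / "truth.bed")
    write_fasta(assembly, outdir / "assembly.fasta")
    assembly_truth.to_bed(outdir / "assembly_truth.bed")

    # 2. reads: full simulation, then an exact-1x subsample for estimation
    rcfg = config.get("reads", {})
    coverage = float(rcfg.get("coverage", 1.0))
    read_length = int(rcfg.get("read_length", 150))
    error_rate = float(rcfg.get("error_rate", 0.001))
    reads = simulate_reads(genome, coverage, read_length, error_rate, seed=seed + 1)
    genome_size = sum(len(s) for s in genome.values())
    n1x = min(reads_for_1x(genome_size, read_length), len(reads.reads))
    reads_1x = subsample(reads, n1x, seed=seed + 2)
    write_fastq(reads_1x, outdir / "reads_1x.fastq",
                encode_origin=bool(rcfg.get("encode_origin", True)))

    # 3. cluster a read sample into repeat families
    ccfg = config.get("cluster", {})
    sample_n = min(int(ccfg.get("sample_reads", 2000)), len(reads.reads))
    sample = subsample(reads, sample_n, seed=seed + 3)
    clusters = cluster_reads(
        sample,
        similarity_threshold=float(ccfg.get("similarity_threshold", 0.2)),
        min_cluster_size=int(ccfg.get("min_cluster_size", 10)),
        k=int(ccfg.get("k", 10)),
    )
    enriched = enriched_clusters(clusters, float(ccfg.get("min_proportion", 0.0001)))
    write_cluster_table(enriched, outdir / "clusters.tsv")
    write_cluster_members(enriched, outdir / "cluster_members.tsv")
    contigs = [build_representative_contig(c, sample) for c in enriched]
    write_fasta({c.contig_id: c.sequence for c in contigs}, outdir / "contigs.fasta")

    # 4. annotate representative contigs
    acfg = config.get("annotate", {})
    library_name = acfg.get("library", "bundled-rdna")
    if library_name == "bundled":
        library = bundled_library()
    elif library_name == "bundled-rdna":
        library = {k: v for k, v in bundled_library().items() if "rdna" in k.lower()}
    elif library_name:
        from .synthetic_genome import read_fasta

        library = read_fasta(library_name)
    else:
        library = None
    annotations = {c.contig_id: classify(c, library) for c in contigs}
    write_annotations([annotations[c.contig_id] for c in contigs],
                      outdir / "annotations.tsv")

    # 5. copy-number estimation both ways + genomic distribution
    ecfg = config.get("estimate", {})
    min_identity = float(ecfg.get("min_identity", 0.7))
    min_coverage = float(ecfg.get("min_coverage", 0.7))
    merge = bool(ecfg.get("merge_overlaps", True))
    dcfg = config.get("distribution", {})
    window_bp = int(dcfg.get("window_bp", 10_000))
    chrom_lengths = {k: len(v) for k, v in assembly.items()}
    indexes = build_genome_indexes(assembly)

    estimates, profiles, all_hits = {}, {}, []
    for c in contigs:
        hits = align_to_genome(
            c.sequence, assembly, min_identity, min_coverage,
            query_id=c.contig_id, indexes=indexes,
        )
        all_hits.extend(hits)
        assembly_est = assembly_copy_number(
            c.sequence, assembly, min_identity, min_coverage,
            contig_id=c.contig_id, merge_overlaps=merge, hits=hits,
        )
        read_est = read_copy_number(
            c.sequence, reads_1x, min_identity, min_coverage,
            contig_id=c.contig_id, merge_overlaps=merge,
        )
        estimates[c.contig_id] = (read_est, assembly_est)
        prof = profile(hits, chrom_lengths, window_bp, contig_id=c.contig_id)
        if prof.n_hits:
            classify_dispersion(
                prof,
                concentration_fraction=float(dcfg.get("concentration_fraction", 0.5)),
                span_fraction=float(dcfg.get("span_fraction", 0.01)),
            )
            terminal_enrichment(
                prof,
                terminal_bp=int(dcfg.get("terminal_bp", 50_000)),
                min_fraction=float(dcfg.get("terminal_fraction", 0.5)),
            )
        profiles[c.contig_id] = prof
        write_bedgraph(prof, outdir / f"profile_{c.contig_id}.bedgraph")
    write_hits_outfmt6(all_hits, outdir / "hits.tsv")

    # 6. summary report
    cluster_ids = {c.contig_id: str(c.source_cluster_id) for c in contigs}
    rows = build_report(estimates, annotations, profiles, cluster_ids)
    write_report_tsv(rows, outdir / "report.tsv")

    # 7. manifest
    outputs = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "repeatscope",
        "version": __version__,
        "seed": seed,
        "config": config,
        "parameters": {
            "min_identity": min_identity,
            "min_coverage": min_coverage,
            "merge_overlaps": merge,
            "window_bp": window_bp,
            "read_length": read_length,
            "coverage": coverage,
            "error_rate": error_rate,
        },
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    canonical = json.dumps(manifest, sort_keys=True, separators=(",", ":"))
    manifest["manifest_sha256"] = hashlib.sha256(canonical.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
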