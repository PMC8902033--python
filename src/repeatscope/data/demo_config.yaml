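# repeatscope pipeline configuration (demo).
#
# Schema
# ------
# seed: integer            master seed; stage seeds are derived from it
# genome:
#   chromosomes:           map chromosome-id -> length (bp)
#   background_gc:         GC fraction of the random background (default 0.44)
#   families:              list of planted repeat families; each entry:
#     name:                family identifier
#     kind:                tandem_satellite | dispersed_element | rdna_array | telomeric_array
#     monomer: or monomer_bp:  explicit monomer/element DNA, or a length to draw randomly
#     copies:              total planted copies
#     divergence:          per-base substitution rate applied per copy (default 0.05)
#     placement:           single_locus | per_chromosome_locus | terminal | uniform_scatter
#     chromosomes:         target chromosome ids (default: all)
#     terminal_repeat_bp:  terminal-repeat length for drawn dispersed elements (default 300)
# collapse:                map family -> factor; tandem loci keep ceil(copies/factor) copies
# reads:                   coverage, read_length, error_rate, encode_origin
# cluster:                 sample_reads, k, similarity_threshold, min_cluster_size, min_proportion
# annotate:                library: bundled | bundled-rdna | <fasta path> | null
# estimate:                min_identity, min_coverage, merge_overlaps
# distribution:            window_bp, concentration_fraction, span_fraction,
#                          terminal_bp, terminal_fraction

seed: 7

genome:
  chromosomes: {chr1: 120000, chr2: 120000, chr3: 120000}
  background_gc: 0.44
  families:
    - name: DEMO_SAT
      kind: tandem_satellite
      monomer_bp: 140
      copies: 300
      divergence: 0.05
      placement: single_locus
      chromosomes: [chr1]
    - name: DEMO_LTR
      kind: dispersed_element
      monomer_bp: 5000
      copies: 25
      divergence: 0.05
      placement: uniform_scatter
      chromosomes: [chr1, chr2, chr3]
    - name: DEMO_TEL
      kind: telomeric_array
      monomer: TTTAGGG
      copies: 1800
      divergence: 0.05
      placement: terminal
      chromosomes: [chr1, chr2, chr3]

collapse: {DEMO_SAT: 8}

reads:
  coverage: 1.5
  read_length: 150
  error_rate: 0.001

# The cluster sample here is ~1x of the toy genome (far denser relative to
# genome size than a real survey sample), so chance overlap chains among
# single-copy background reads can reach a dozen reads; min_cluster_size is
# raised accordingly for the demo.
cluster:
  sample_reads: 2400
  k: 10
  similarity_threshold: 0.2
  min_cluster_size: 20
  min_proportion: 0.0001

annotate:
  library: bundled-rdna

estimate:
  min_identity: 0.7
  min_coverage: 0.7
  merge_overlaps: true

distribution:
  window_bp: 5000
  concentration_fraction: 0.5
  span_fraction: 0.08
  terminal_bp: 10000
  terminal_fraction: 0.5
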