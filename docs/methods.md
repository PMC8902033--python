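# Methods

This note documents the models and algorithmic choices behind `repeatscope`:
what each stage assumes, which parameters matter, what the synthetic data
bench does and does not emulate, and where the design was genuinely open.

## The synthetic genome model

A genome is a set of chromosomes of i.i.d. random background DNA at a given
GC fraction into which repeat families are planted:

* **tandem kinds** (`tandem_satellite`, `rdna_array`, `telomeric_array`)
  place copies head-to-tail at one locus, one locus per chromosome, or
  pinned to chromosome ends (telomeres are terminal by definition);
* **`dispersed_element`** copies are scattered at uniform random positions,
  on either strand with probability 0.5; drawn elements have identical
  terminal repeats (default 300 bp) flanking a random body, the structural
  signature of an LTR retrotransposon.

Each planted copy is independently mutated by **substitutions only**: every
base flips to a different base with probability `divergence`
(E[Hamming distance] = divergence × length). With no indels, every copy has
exactly the template length, so planted copy numbers translate exactly into
planted base counts and the total-aligned-length arithmetic of the copy
estimators has an unambiguous oracle. The default divergence of 5% is a
modelling choice within the range typical of young repeat families and is
exposed as a parameter.

Coordinates are 0-based half-open (BED-compatible) throughout. Placement is
rejection-sampled against previously planted loci with a **spacer** of one
read length (`GenomeSpec.spacer_bp`, default 150) between loci: without it,
a scattered element can land flush against another family and
junction-spanning reads merge the two families into one read-graph
component — the planted "one family = one cluster" truth would be
ill-defined rather than mis-measured.

`collapse_assembly` removes all but the first ceil(n/factor) copies from
each tandem locus and remaps every ground-truth coordinate, emulating the
collapse of high-copy tandem arrays in de novo assemblies; factor 1 is the
identity, and collapse of dispersed families is rejected (assembly collapse
is an array phenomenon).

**What the bench does not emulate:** indels and structural variation within
families, nested/fragmented insertions, segmental duplication, sequencing
quality gradients, paired-end structure, or any real genome's sequence
content. Passing recovery tests therefore demonstrates the estimators'
correctness under a substitution-only repeat landscape, not robustness to
assembly-grade sequence pathology.

## Read simulation

Fixed-length single-end reads (default 150 bp) with uniform start positions
(chromosomes weighted by length), uniform strand, and independent per-base
substitution errors (default 0.001, matching high-quality filtered short
reads). A **1× sample** contains round(genome_size / read_length) reads, so
expected per-base depth is 1; `subsample` draws uniformly without
replacement. Read identifiers can carry the true origin
(`chrom:start:strand`) for oracle tests, and a flag suppresses this so that
no downstream stage can depend on it. Pair information is not simulated:
no downstream statistic here uses it.

## Clustering kernel and its calibration

Two reads are compared by the orientation-maximised **overlap coefficient**
of their distinct k-mer sets, |K(a) ∩ K(b′)| / min(|K(a)|, |K(b′)|) over
b′ ∈ {b, revcomp(b)} — symmetric, bounded in [0, 1], and exactly 1 for
identical or reverse-complementary reads. Edges join pairs at or above a
threshold; repeat clusters are connected components (networkx) with at
least `min_cluster_size` (default 10) members. Genome proportions divide by
*all* sampled reads, including unclustered ones.

Defaults **k = 10, threshold 0.2** are set by calibration arithmetic at the
bench's study condition: copies diverge 5% from their family consensus, so
two reads from different copies disagree at ≈ 10% of aligned positions and
their expected shared-k-mer fraction over a full overlap is ≈ 0.9^10 ≈ 0.36;
a threshold of 0.2 then links reads overlapping by roughly 60% or more,
while two random reads share < 1% of 10-mers and unrelated families (≥ 30%
mutual divergence, shared fraction ≈ 0.7^10 ≈ 0.03) stay unlinked. Larger k
(e.g. 15) with a high threshold isolates nearly every read at this
divergence and is appropriate only for near-identical families; both
parameters are exposed.

Candidate pairs are pruned to reads sharing a canonical-k-mer **minimizer**
(window 11), which avoids the quadratic all-pairs comparison; the pruned
edge set is checked against the exhaustive one on small instances.

Because these are connected components, two caveats are inherent: a read
sample that is dense relative to the genome (≈ 1× or more) lets single-copy
background reads chain into spurious small components (the demo raises
`min_cluster_size` for exactly this reason — real survey samples are ≪ 1× of
their genome), and any genomic adjacency of two families would merge them
(prevented in the bench by the placement spacer).

## Representative contigs

A cluster's consensus is built by a greedy, **verified** overlap-layout:

* the **seed** is the read of *median* positive degree. The highest-degree
  read — the natural first choice — sits preferentially inside internally
  duplicated sequence (an LTR element's two identical terminal repeats have
  doubled read depth and hence doubled degree), and seeding there
  linearizes the element's circular overlap graph at the wrong point. A
  median-degree read lies in single-copy body sequence, so unique context
  is laid down before any duplication is reached.
* reads are placed in order of best edge similarity; a read's candidate
  offsets come from the modal k-mer offsets to all already-placed
  neighbours, the candidate matching the most consensus columns wins, and a
  placement is accepted only at ≥ 75% agreement with covered columns
  (columns covered by ≥ 2 reads carry a stable consensus and are preferred).
* the consensus is the per-column plurality base with leftmost-alphabetical
  tie-break; flanks and interior stretches with depth < 2 or agreement
  < 60% (reads running off the repeat into unrelated flanking sequence) are
  trimmed, and among the surviving runs the one with the highest mean read
  depth is returned (ties: longer, then leftmost).
* **ring re-linearization**: an element flanked by identical terminal
  repeats has a circular overlap graph, so the layout can still linearize
  it at an arbitrary point, collapsing both terminal-repeat copies onto one
  doubled-depth arc inside the contig. When a contig lacks a prefix/suffix
  terminal match but shows both ring closure (its head re-occurring near
  its tail) and such an arc, it is cut at the arc and the arc is appended
  again at the end, restoring the terminal-repeat-flanked linear form.
  Tandem rings (e.g. rDNA) also close but have flat depth profiles and are
  never touched.

Layout quality degrades below roughly 15× within-family read depth (gaps in
the overlap graph fragment the layout); the standard cohort provides ≈ 19–38×
for every family.

## Alignment model and copy-number estimators

The synthetic world is substitution-only, so every true local alignment
lies on a single diagonal and alignment columns equal aligned length. Hits
are **trimmed gapless local alignments**: each candidate diagonal's overlap
is clipped to its maximal-scoring segment (match +1, mismatch −2 — the
classic clipping of mismatching flanks; deterministic leftmost tie-breaks),
and the filters — identity strictly > 0.7 and aligned-query-fraction
strictly > 0.7 by default — apply to the trimmed segment. At most one hit
per diagonal and strand is reported. Small instances (diagonal space ≤
2×10⁷ cells) are scored on *every* diagonal, which is exact by
construction; larger targets are seeded with shared 12-mers, which in
principle can miss a borderline-identity segment containing no exact
12-mer — at the bench's planted identities (≥ 0.85) the expected number of
seeds per true hit is ≫ 10, and a dedicated test checks that seeding
recovers every planted copy in large targets. An independent pure-Python
exhaustive oracle defines the reference hit set.

Copy number is `total aligned length / contig length`, with the aligned
length summed two ways:

* default (**no merge**): every passing hit contributes its aligned length,
  the literal reading of the formula. For a query of k tandem monomers over
  an array of M monomers this yields ≈ M (one full-query hit per monomer
  phase) — overlapping hits multi-count, as raw alignment-tool output
  would.
* `merge_overlaps`: each base is counted once — union of target intervals
  for contig→assembly, per-read union of query intervals for read→contig.
  This removes the multi-counting of periodic references and of element
  terminal repeats and is the variant used for parameter-recovery scoring
  (recorded in every report row's parameter fingerprint).

For tandem monomers shorter than a read, `tandem_reference` concatenates
the monomer until every read phase fits inside (e.g. 3 × 140 bp for 150-bp
reads); estimates in reference units are converted back to monomer units by
the length ratio. Without this, boundary-phase reads systematically fail
the coverage filter and the estimate biases low by tens of percent.

The residual bias of the read estimator is the loss of sub-threshold
boundary overlaps, about −1.5% for a 5-kb element at 1×; per-seed noise is
Poisson in the family's read count (CV ≈ 2–5% for the standard cohort
families at 1× of 2 Mb).

`fold_change` is read-based copies / assembly-based copies (units cancel);
zero assembly copies raises an explicit absent-from-assembly condition and
is reported as "NA".

## Distribution rule

Hits are accumulated into fixed windows (default 10 kb) by target-side
coordinates. A repeat is **non-dispersed** iff at least
`concentration_fraction` (0.5) of its aligned bases lie in the smallest
window set covering at most `span_fraction` of the genome (windows chosen
greedily by descending signal; the minimal prefix reaching the
concentration level becomes the enriched-window set). The qualitative
dispersed/non-dispersed call this formalises has no published quantitative
equivalent, so both parameters are explicit and recorded. The library
default span is 1%; the **standard cohort uses 5%**, scaled from design
arithmetic: a planted toy array occupies up to ~7% of a 2-Mb genome whereas
a real array occupies ≪ 0.1% of a multi-Gb genome, and with a 5% span the
cohort's calls are correct by construction (a scattered family's 500 kb of
signal cannot fit half of itself into the 100-kb window budget, while every
tandem family can). **Terminal enrichment** requires half the signal within
`terminal_bp` (50 kb) of a chromosome end; **colocalization** is the
Jaccard index of enriched-window sets on a common grid.

## Comparative typing

Abundance of a repeat in a sample is its read-based copy number from that
sample's 1× read set; presence is abundance ≥ 10 copies (cytological
detectability implies many copies; the threshold is exposed). A presence
row over {reference, outgroup, ≥ 2 ingroup samples} is typed with
precedence: present in outgroup and all ingroup → type1; all ingroup but
not outgroup → type2; a proper nonempty subset of the ingroup (outgroup
either way) → type3; absent everywhere except possibly the reference →
type4; anything else → other. Every boolean row receives exactly one label.
Ploidy normalisation (copies per monoploid genome) is available as a flag
concept but off by default: the survey compares detectability, not rates.

## Annotation thresholds

Periodicity and terminal-repeat detection use 80% identity — tolerant of
the default 5% divergence doubled across two copies. Library matching
requires per-hit identity above the match threshold and ≥ 100 aligned bases
per hit (short chance segments must not fake coverage); coverage is the
union of passing hits on the contig, since a single local alignment cannot
cover a tandem contig spanning several copies of a one-unit library entry.
Precedence is telomere motif (≥ 10 consecutive TTTAGGG units, either
strand) > library match > periodicity > terminal repeat > Unknown;
periodicity must out-rank terminal repeats because a tandem array trivially
matches its own prefix/suffix. The bundled library (telomere motif,
140-bp satellite consensus, 3-kb rDNA-unit stand-in) is fully synthetic and
regenerable from fixed seeds; when the goal is to distinguish structural
classes of the standard cohort, only the rDNA entry is passed to
`classify` — a library containing the satellite consensus would (correctly)
claim the satellite as a library match instead of `Simple/Sat`.

## Problem sizes and seeds

The standard validation cohort is a 2-Mb, four-chromosome genome: a 140-bp
satellite ×1000 (one locus), a 3-kb rDNA-like unit ×50 (one locus), a 5-kb
LTR-like element ×100 (scattered, both strands), and TTTAGGG telomeres
(8.4 kb per chromosome end), all at 5% divergence, ≈ 43% repeat content.
Recovery uses 1× samples (13,333 reads), discovery a 5,000-read subsample,
and replicate seeds derive from one base via `numpy.random.SeedSequence`.
At these sizes the whole test suite and the reproduction script each run in
a few minutes on one CPU. The per-seed recovery band of 15% is ≈ 3σ for the
smallest family (the telomeres, 3.4% of the genome), so rare seeds can
breach it through coverage sampling noise alone — the estimator itself
tracks realised coverage to < 0.5%.

## Known limitations

* Gapless alignment: correct in the substitution-only bench, but real
  repeat copies contain indels; the engine's hit semantics would need a
  banded gapped extension for real data.
* Connected-component clustering cannot split chimeric components (nested
  or adjacent repeat structures in real genomes) and inherits the density
  caveats above.
* Consensus building assumes a single dominant layout per cluster; highly
  diverged subfamilies in one component will blend.
* The dispersed/non-dispersed rule is window-resolution and scale-dependent
  by design; its parameters must be chosen with the genome size in mind.
* Comparative typing treats samples symmetrically apart from the
  reference/outgroup roles; it does not model ploidy differences.
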