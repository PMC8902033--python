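"""Graph-based read clustering into repeat families, with consensus contigs.

Shotgun reads sampled from a genome are compared all-vs-all by a k-mer
similarity kernel; pairs above a similarity threshold become edges of a read
graph, and connected components of at least ``min_cluster_size`` reads are
reported as repeat clusters. Single-copy background yields reads with (almost)
no similar partners, so only repetitive families form components of any size.
A cluster's genome proportion is its share of all sampled reads, which for a
uniform read sample estimates the family's genomic fraction.

The similarity kernel is the overlap coefficient of distinct-k-mer sets,
maximised over the relative orientation of the two reads:

    sim(a, b) = max_orient |K(a) ∩ K(b')| / min(|K(a)|, |K(b')|)

It is symmetric, orientation-invariant and 1.0 for identical reads. With the
default k=10 the expected coefficient for two fully overlapping reads at
mismatch rate m is ≈ (1-m)^10 — about 0.36 at the ~10% read-to-read mismatch
implied by 5% intra-family divergence — so the default edge threshold of 0.2
links reads of one family while leaving unrelated reads (chance coefficient
< 0.01) unconnected. Candidate pairs are restricted to reads sharing a
canonical-k-mer minimizer, which prunes the quadratic all-pairs comparison;
on small instances the pruned graph is checkable against the exhaustive one.

Each cluster is summarised by a representative consensus contig: reads are
placed on a common coordinate axis by breadth-first traversal of the cluster
graph from the highest-degree read (each edge contributes the modal k-mer
offset between its oriented reads), and a per-column plurality call with
alphabetical tie-break gives the consensus. Low-agreement flanks, where reads
run off the repeat into unrelated flanking sequence, are trimmed.
"""

from __future__ import annotations

import heapq
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from ._seq import BASES, kmer_codes, kmer_set, minimizers, revcomp_array, to_array
from .read_sim import ReadSet

DEFAULT_K = 10
DEFAULT_SIMILARITY_THRESHOLD = 0.2
DEFAULT_MIN_CLUSTER_SIZE = 10
DEFAULT_MINIMIZER_WINDOW = 11


@dataclass
class ReadCluster:
    cluster_id: int
    member_read_ids: list[str]
    genome_proportion: float
    annotation_label: str = ""
    member_indices: list[int] = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


@dataclass
class RepresentativeContig:
    contig_id: str
    sequence: str
    mean_read_depth: float
    source_cluster_id: int


def read_similarity(a: str, b: str, k: int = DEFAULT_K) -> float:
    """Orientation-maximised overlap coefficient of distinct k-mer sets."""
    ka = kmer_set(a, k)
    arr_b = to_array(b)
    kb = frozenset(kmer_codes(arr_b, k).tolist())
    kbr = frozenset(kmer_codes(revcomp_array(arr_b), k).tolist())
    if not ka or not kb:
        return 0.0
    best = max(len(ka & kb), len(ka & kbr))
    return best / min(len(ka), len(kb))


def _similarity_edges(
    sequences: list[str],
    k: int,
    threshold: float,
    minimizer_w: int | None,
):
    """Edges (i, j, similarity, flip) with similarity >= threshold.

    ``flip`` records whether j matched i better in reverse-complement
    orientation. With ``minimizer_w`` set, candidate pairs are restricted to
    reads sharing a canonical-k-mer minimizer; with ``None`` all pairs are
    evaluated (the exhaustive oracle mode).
    """
    arrays = [to_array(s) for s in sequences]
    fwd = [frozenset(kmer_codes(a, k).tolist()) for a in arrays]
    rev = [frozenset(kmer_codes(revcomp_array(a), k).tolist()) for a in arrays]
    n = len(sequences)

    if minimizer_w is None:
        candidates = ((i, j) for i in range(n) for j in range(i + 1, n))
    else:
        buckets: dict[int, list[int]] = defaultdict(list)
        for i, a in enumerate(arrays):
            for m in minimizers(a, k, minimizer_w).tolist():
                buckets[m].append(i)
        seen: set[tuple[int, int]] = set()
        pairs: list[tuple[int, int]] = []
        for members in buckets.values():
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    key = (members[x], members[y])
                    if key not in seen:
                        seen.add(key)
                        pairs.append(key)
        candidates = iter(sorted(pairs))

    edges = []
    for i, j in candidates:
        fi, fj, rj = fwd[i], fwd[j], rev[j]
        if not fi or not fj:
            continue
        same = len(fi & fj)
        flip = len(fi & rj)
        denom = min(len(fi), len(fj))
        sim = max(same, flip) / denom
        if sim >= threshold:
            edges.append((i, j, sim, flip > same))
    return edges


def cluster_reads(
    reads: ReadSet,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    k: int = DEFAULT_K,
    minimizer_w: int | None = DEFAULT_MINIMIZER_WINDOW,
) -> list[ReadCluster]:
    """Cluster reads into repeat families via connected components.

    Genome proportions use *all* sampled reads as denominator, including
    reads discarded as singletons or small components.
    """
    if not reads.reads:
        raise ValueError("read set is empty")
    sequences = reads.sequences()
    edges = _similarity_edges(sequences, k, similarity_threshold, minimizer_w)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(sequences)))
    graph.add_edges_from((i, j) for i, j, _s, _f in edges)

    components = [sorted(c) for c in nx.connected_components(graph) if len(c) >= min_cluster_size]
    components.sort(key=lambda c: (-len(c), c[0]))
    total = len(sequences)
    clusters = []
    for idx, comp in enumerate(components, start=1):
        clusters.append(
            ReadCluster(
                cluster_id=idx,
                member_read_ids=[reads.reads[i].read_id for i in comp],
                genome_proportion=len(comp) / total,
                member_indices=comp,
            )
        )
    return clusters


def enriched_clusters(
    clusters: list[ReadCluster], min_proportion: float = 0.0001
) -> list[ReadCluster]:
    """Clusters with genome proportion strictly above the enrichment cutoff
    (default 0.01%), in descending-proportion order."""
    kept = [c for c in clusters if c.genome_proportion > min_proportion]
    kept.sort(key=lambda c: (-c.genome_proportion, c.cluster_id))
    return kept


def _modal_offset(a: np.ndarray, b: np.ndarray, k: int) -> int | None:
    """Most common (pos_in_a - pos_in_b) over shared k-mers, or None."""
    pos_a: dict[int, list[int]] = defaultdict(list)
    for p, code in enumerate(kmer_codes(a, k).tolist()):
        pos_a[code].append(p)
    diffs: Counter = Counter()
    for p, code in enumerate(kmer_codes(b, k).tolist()):
        for q in pos_a.get(code, ()):
            diffs[q - p] += 1
    if not diffs:
        return None
    # deterministic: highest count, then smallest |offset|, then smallest offset
    return min(diffs.items(), key=lambda kv: (-kv[1], abs(kv[0]), kv[0]))[0]


_BASE_TO_ROW = np.full(256, -1, dtype=np.int64)
for _r, _c in enumerate(b"ACGT"):
    _BASE_TO_ROW[_c] = _r


class _Layout:
    """Growable plurality-count matrix over a signed column axis."""

    def __init__(self, lo: int, hi: int):
        self.origin = -lo + 64
        self.counts = np.zeros((4, hi - lo + 128), dtype=np.int64)

    def _ensure(self, lo: int, hi: int) -> None:
        i_lo, i_hi = lo + self.origin, hi + self.origin
        grow_left = max(0, -i_lo)
        grow_right = max(0, i_hi - self.counts.shape[1])
        if grow_left or grow_right:
            pad = max(grow_left, 256), max(grow_right, 256)
            self.counts = np.pad(self.counts, ((0, 0), pad))
            self.origin += pad[0]

    def score(self, arr: np.ndarray, off: int) -> tuple[int, int]:
        """(matched, covered) columns of ``arr`` placed at ``off`` against the
        current plurality consensus. Columns covered by at least two reads
        carry a stable consensus and are preferred; depth-1 columns (single
        overhanging reads, e.g. flanking sequence beyond a repeat boundary)
        are consulted only when nothing better exists."""
        self._ensure(off, off + arr.size)
        block = self.counts[:, off + self.origin: off + self.origin + arr.size]
        depth = block.sum(axis=0)
        consensus = BASES[block.argmax(axis=0)]
        rows_ok = _BASE_TO_ROW[arr] >= 0
        eq = (consensus == arr) & rows_ok
        stable = depth >= 2
        if np.count_nonzero(stable) >= 10:
            return int(np.count_nonzero(eq & stable)), int(stable.sum())
        covered = depth > 0
        return int(np.count_nonzero(eq & covered)), int(covered.sum())

    def add(self, arr: np.ndarray, off: int) -> None:
        self._ensure(off, off + arr.size)
        rows = _BASE_TO_ROW[arr]
        cols = np.arange(off + self.origin, off + self.origin + arr.size)
        ok = rows >= 0
        np.add.at(self.counts, (rows[ok], cols[ok]), 1)


def build_representative_contig(
    cluster: ReadCluster,
    reads: ReadSet,
    k: int = DEFAULT_K,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    minimizer_w: int | None = DEFAULT_MINIMIZER_WINDOW,
    min_agreement: float = 0.6,
    min_place_identity: float = 0.75,
) -> RepresentativeContig:
    """Greedy verified overlap-layout plurality consensus of a cluster.

    Starting from the highest-degree read, reads are placed in order of their
    best edge similarity. A read's candidate offsets come from the modal
    k-mer offsets to *all* already-placed neighbours; the candidate matching
    the most consensus columns wins and is accepted only at
    >= ``min_place_identity`` agreement with the covered columns. The
    verification step keeps repeat-internal duplications (e.g. the two
    identical terminal repeats of an LTR element, which would otherwise fold
    the layout onto itself) from dragging reads to the wrong copy: a read
    whose context disagrees with the consensus at one candidate offset is
    placed at a better-supported one or retried later.
    """
    idx = cluster.member_indices
    if not idx:
        raise ValueError("cluster has no member indices; build it with cluster_reads")
    seqs = [reads.reads[i].sequence for i in idx]
    arrays = [to_array(s) for s in seqs]
    n = len(seqs)

    if n == 1:
        return RepresentativeContig(
            f"cl{cluster.cluster_id}_rep", seqs[0], 1.0, cluster.cluster_id
        )

    edges = _similarity_edges(seqs, k, similarity_threshold, minimizer_w)
    adj: dict[int, list[tuple[int, float, bool]]] = defaultdict(list)
    for i, j, sim, flip in edges:
        adj[i].append((j, sim, flip))
        adj[j].append((i, sim, flip))

    # Seed from the read of median positive degree: reads inside internally
    # duplicated regions (e.g. the two identical terminal repeats of an LTR
    # element) have roughly doubled degree, and seeding the layout there
    # linearizes the element's circular overlap graph at the wrong point.
    # A median-degree read lies in single-copy sequence, so flanking context
    # is laid down before any internal duplication is reached.
    degrees = {i: len(adj[i]) for i in range(n) if adj[i]}
    if not degrees:
        best_read = max(range(n), key=lambda i: (arrays[i].size, -i))
        return RepresentativeContig(
            f"cl{cluster.cluster_id}_rep", seqs[best_read], 1.0, cluster.cluster_id
        )
    median_degree = sorted(degrees.values())[len(degrees) // 2]
    seed = min(degrees, key=lambda i: (abs(degrees[i] - median_degree), -degrees[i], i))
    placed: dict[int, tuple[int, bool]] = {seed: (0, False)}
    layout = _Layout(0, arrays[seed].size)
    layout.add(arrays[seed], 0)
    oriented_cache: dict[tuple[int, bool], np.ndarray] = {}

    def oriented(i: int, rc: bool) -> np.ndarray:
        key = (i, rc)
        if key not in oriented_cache:
            oriented_cache[key] = revcomp_array(arrays[i]) if rc else arrays[i]
        return oriented_cache[key]

    frontier: list[tuple[float, int]] = []
    for v, sim, _f in adj[seed]:
        heapq.heappush(frontier, (-sim, v))
    offset_cache: dict[tuple[int, int, bool], int | None] = {}

    while frontier:
        _negsim, v = heapq.heappop(frontier)
        if v in placed:
            continue
        # candidate offsets from every placed neighbour
        candidates: dict[tuple[int, bool], None] = {}
        for u, _sim, flip in adj[v]:
            if u not in placed:
                continue
            off_u, rc_u = placed[u]
            rc_v = rc_u ^ flip
            key = (u, v, rc_v)
            if key not in offset_cache:
                offset_cache[key] = _modal_offset(oriented(u, rc_u), oriented(v, rc_v), k)
            shift = offset_cache[key]
            if shift is not None:
                candidates[(off_u + shift, rc_v)] = None
        best = None
        for off, rc_v in candidates:
            a_v = oriented(v, rc_v)
            matched, covered = layout.score(a_v, off)
            if covered >= k and matched / covered >= min_place_identity:
                score = (matched, -abs(off), off, not rc_v)
                if best is None or score > best[0]:
                    best = (score, off, rc_v, a_v)
        if best is None:
            continue  # may be retried when more neighbours are placed
        _score, off, rc_v, a_v = best
        placed[v] = (off, rc_v)
        layout.add(a_v, off)
        for w, sim, _f in adj[v]:
            if w not in placed:
                heapq.heappush(frontier, (-sim, w))

    used = np.flatnonzero(layout.counts.sum(axis=0) > 0)
    lo_i, hi_i = int(used.min()), int(used.max()) + 1
    counts = layout.counts[:, lo_i:hi_i]
    lo = lo_i - layout.origin
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    consensus = BASES[counts.argmax(axis=0)]

    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    good = (depth >= 2) & (agreement >= min_agreement)
    runs = _runs(good)
    read_length = reads.read_length or max(a.size for a in arrays)
    runs = [r for r in runs if r[1] - r[0] >= read_length] or _runs(depth >= 1)

    def run_depth(run):
        s, e = run
        return float(depth[s:e].mean())

    s, e = max(runs, key=lambda r: (run_depth(r), r[1] - r[0], -r[0]))
    chosen = _relinearize_fold(consensus[s:e], depth[s:e], read_length)
    sequence = chosen.tobytes().decode("ascii")
    return RepresentativeContig(
        f"cl{cluster.cluster_id}_rep",
        sequence,
        float(depth[s:e].mean()),
        cluster.cluster_id,
    )


def _relinearize_fold(consensus: np.ndarray, depth: np.ndarray,
                      read_length: int, min_arc: int = 100) -> np.ndarray:
    """Re-linearize a consensus whose layout collapsed a terminal repeat.

    An element flanked by two identical terminal repeats has a *circular*
    read-overlap graph (…body→TR→body…), so a greedy layout may linearize it
    at an arbitrary point and collapse both terminal-repeat copies onto one
    arc of roughly doubled read depth somewhere inside the contig. When the
    contig lacks a prefix/suffix terminal match but carries such an arc, the
    contig is treated as a ring: it is cut at the arc start and the arc is
    appended again at the end, restoring the terminal-repeat-flanked linear
    form. The repair is speculative and self-validating — it is kept only if
    the re-linearized sequence actually shows a terminal repeat. Tandem
    contigs have flat depth profiles and are never touched.
    """
    from .annotation import detect_terminal_repeat

    L = consensus.size
    if L < 4 * min_arc or L <= read_length or depth.size != L:
        return consensus
    seq = consensus.tobytes().decode("ascii")
    if detect_terminal_repeat(seq, min_len=min_arc) is not None:
        return consensus  # already terminal-repeat-flanked
    # ring closure: the contig's head re-occurs at its tail (the layout walked
    # once around the ring and overshot by the redundant overlap)
    closure = None
    for p in range(L - 30, L // 2, -1):
        w = L - p
        matches = int(np.count_nonzero(consensus[:w] == consensus[p:]))
        if matches / w >= 0.85:
            closure = p
            break
    if closure is None:
        return consensus
    # the collapsed terminal repeat: an arc of roughly doubled read depth.
    # A genuine tandem ring (e.g. an rDNA unit) also closes, but its depth
    # profile is flat, so no arc exists and it is left untouched.
    med = float(np.median(depth))
    if med <= 0:
        return consensus
    arcs = [(a, b) for a, b in _runs(depth >= 1.5 * med) if min_arc <= b - a <= L // 3]
    if not arcs:
        return consensus
    a, b = max(arcs, key=lambda r: (r[1] - r[0], -r[0]))
    return np.concatenate([consensus[a:], consensus[:a], consensus[a:b]])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def write_cluster_table(clusters: list[ReadCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tgenome_proportion\tannotation_label\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.size}\t{c.genome_proportion:.6f}\t{c.annotation_label}\n"
            )


def write_cluster_members(clusters: list[ReadCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tread_id\n")
        for c in clusters:
            for rid in c.member_read_ids:
                fh.write(f"{c.cluster_id}\t{rid}\n")
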