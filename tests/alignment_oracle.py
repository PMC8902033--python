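"""Independent exhaustive alignment oracle and randomized instance generator.

The oracle enumerates every diagonal of the gapless alignment space on both
strands in plain Python and applies the identity/coverage filters directly —
no k-mer seeding and no code shared with the engine. It defines the ground
truth the seed-and-extend engine must reproduce.
"""

import numpy as np

from repeatscope._seq import revcomp
from repeatscope.copy_estimation import local_align
from repeatscope.synthetic_genome import mutate_copy, random_sequence


def _best_segment_py(q, t, d, qs, qe, penalty=2):
    """Maximal-scoring gapless segment on one diagonal (match +1, mismatch
    -penalty); smallest maximizing end, then earliest attaining start."""
    prefix = [0]
    for i in range(qs, qe):
        prefix.append(prefix[-1] + (1 if q[i] == t[i + d] else -penalty))
    runmin, m = [], 0
    for p in prefix:
        m = min(m, p)
        runmin.append(m)
    gains = [p - r for p, r in zip(prefix, runmin)]
    best = max(gains)
    if best <= 0:
        return 0, 0, 0
    be = gains.index(best)
    target = prefix[be] - best
    bs = prefix[: be + 1].index(target)
    aligned = be - bs
    matches = (best + penalty * aligned) // (penalty + 1)
    return qs + bs, qs + be, matches


def oracle_hits(query: str, target: str, min_identity: float, min_coverage: float):
    Q, T = len(query), len(target)
    hits = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for d in range(-(Q - 1), T):
            qs = max(0, -d)
            qe = min(Q, T - d)
            if qe - qs <= min_coverage * Q:
                continue
            s, e, matches = _best_segment_py(q, target, d, qs, qe)
            aligned = e - s
            if aligned <= min_coverage * Q:
                continue
            if matches / aligned > min_identity:
                if strand == "-":
                    q0, q1 = Q - e, Q - s
                else:
                    q0, q1 = s, e
                hits.add((q0, q1, s + d, e + d, strand))
    return hits


def engine_hit_set(query, target, min_identity=0.7, min_coverage=0.7):
    return {
        (h.query_start, h.query_end, h.target_start, h.target_end, h.strand)
        for h in local_align(query, target, min_identity, min_coverage)
    }


def random_instance(rng: np.random.Generator):
    """A randomized target with planted full, truncated and reverse-strand
    copies of the query plus one far-below-threshold decoy."""
    tlen = int(rng.integers(1000, 3000))
    qlen = int(rng.integers(200, 500))
    target = list(random_sequence(rng, tlen))
    query = random_sequence(rng, qlen)
    for _ in range(int(rng.integers(0, 5))):
        copy = mutate_copy(query, float(rng.uniform(0.0, 0.12)), rng)
        cut = int(qlen * float(rng.uniform(0.5, 1.0)))
        piece = copy[:cut] if rng.random() < 0.5 else copy[-cut:]
        if rng.random() < 0.5:
            piece = revcomp(piece)
        pos = int(rng.integers(0, tlen - cut + 1))
        target[pos:pos + cut] = piece
    decoy = mutate_copy(query, 0.35, rng)
    pos = int(rng.integers(0, tlen - qlen + 1))
    target[pos:pos + qlen] = decoy
    return query, "".join(target)
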