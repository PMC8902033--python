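"""Shared fixtures: the standard synthetic cohort and its derived read sets.

Session-scoped because building the 2-Mb cohort and clustering a 5,000-read
sample are the expensive steps shared by the discovery, annotation and
acceptance tests.
"""

import pytest

from repeatscope.cohort import build_standard_cohort
from repeatscope.read_sim import simulate_reads, subsample
from repeatscope.repeat_discovery import (
    build_representative_contig,
    cluster_reads,
    enriched_clusters,
)

COHORT_GENOME_SEED = 0
COHORT_READ_SEED = 2
COHORT_SAMPLE_SEED = 3


@pytest.fixture(scope="session")
def cohort():
    """(genome, truth) of the standard 2-Mb four-family cohort."""
    return build_standard_cohort(seed=COHORT_GENOME_SEED)


@pytest.fixture(scope="session")
def cohort_reads_1x(cohort):
    genome, _truth = cohort
    return simulate_reads(genome, coverage=1.0, read_length=150,
                          error_rate=0.001, seed=COHORT_READ_SEED)


@pytest.fixture(scope="session")
def cohort_sample(cohort_reads_1x):
    """The 5,000-read discovery sample."""
    return subsample(cohort_reads_1x, 5000, seed=COHORT_SAMPLE_SEED)


@pytest.fixture(scope="session")
def discovery(cohort_sample):
    """Clusters of the discovery sample plus their representative contigs."""
    clusters = enriched_clusters(cluster_reads(cohort_sample))
    contigs = {c.cluster_id: build_representative_contig(c, cohort_sample)
               for c in clusters}
    return clusters, contigs
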