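"""Shared fixtures: one compact simulated genome reused across modules."""

import pytest

from coraldup import synthetic_data as sd
from coraldup import tdg


@pytest.fixture(scope="session")
def small_params():
    # 2 contigs x 60 genes, 12 planted clusters: enough structure to exercise
    # detection, ageing and validation while keeping the suite fast
    return sd.SimulationParams(seed=11, n_contigs=2, genes_per_contig=60,
                               n_clusters=12)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return sd.simulate_genome(small_params)


@pytest.fixture(scope="session")
def detected(small_sim):
    hits = tdg.similarity_search(small_sim.proteins)
    lengths = {g: len(p) for g, p in small_sim.proteins.items()}
    pairs = tdg.filter_similarity(hits, lengths)
    tandem = tdg.find_tandem_pairs(pairs, small_sim.models)
    clusters = tdg.cluster_single_linkage(tandem, small_sim.models)
    return {"hits": hits, "pairs": pairs, "tandem": tandem,
            "clusters": clusters}
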