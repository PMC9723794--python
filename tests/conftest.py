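import pytest

from degradomics import synthetic as sd
from degradomics.pangenome import all_vs_all, cluster_ogs, find_rbms, partition_pangenome


@pytest.fixture(scope="session")
def small_pangenome():
    """A planted 4-genome pangenome shared across orthology tests."""
    truth = sd.PangenomeTruth(n_genomes=4, core_ogs=12, accessory_ogs=8, seed=3)
    return sd.simulate_pangenome(truth)


@pytest.fixture(scope="session")
def small_pangenome_run(small_pangenome):
    """The full orthology pipeline run once on the planted pangenome."""
    sim = small_pangenome
    hits = all_vs_all(sim.proteomes)
    edges = find_rbms(hits)
    all_genes = [(g, gene) for g, prots in sim.proteomes.items() for gene in prots]
    ogs = cluster_ogs(edges, all_genes=all_genes)
    partition = partition_pangenome(ogs, sorted(sim.proteomes))
    return {"sim": sim, "hits": hits, "edges": edges, "ogs": ogs, "partition": partition}


@pytest.fixture(scope="session")
def diverged_30kb_pair():
    truth = sd.DivergencePairTruth(ancestor_length=30_000, per_site_divergence=0.05, seed=1)
    ancestor, derived = sd.diverged_pair(truth)
    return truth, ancestor, derived
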