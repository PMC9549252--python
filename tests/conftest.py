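import pytest

from hybvigor import simdata


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic study shared by read-only tests."""
    return simdata.simulate_all(simdata.SimConfig(seed=3))


@pytest.fixture(scope="session")
def bsj_sim():
    """50 kb back-splice benchmark: (genome, genes, reads, junction truth)."""
    cfg = simdata.bsj_benchmark_config(11)
    genome, genes, _te = simdata.simulate_genome(cfg)
    reads, truth, genome = simdata.simulate_bsj_reads(cfg, genome, genes)
    return genome, genes, reads, truth
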