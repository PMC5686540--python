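import pytest

from microdiv import pipeline, simdata


@pytest.fixture(scope="session")
def small_universe():
    """A tiny universe: 2 phyla x 2 genera x 2 genomes + 3 focal clades."""
    cfg = simdata.UniverseConfig(n_phyla=2, genera_per_phylum=2, genomes_per_genus=2,
                                 n_markers=4, marker_len=80, focal_clades=3, seed=7)
    return simdata.simulate_universe(cfg)


@pytest.fixture(scope="session")
def small_build(small_universe):
    return pipeline.build_reference(small_universe, seed=7)


@pytest.fixture(scope="session")
def small_run(small_universe, small_build):
    """A placed sample over the small universe with known truth."""
    u = small_universe
    comp = {g: 1.0 for g in u.genome_ids}
    reads, truth = simdata.simulate_reads(u, comp, 400, read_len=40,
                                          decoy_frac=0.1, seed=3)
    sr = pipeline.place_sample(small_build, reads, "S1", seed=7)
    ba = pipeline.branch_abundance(small_build, [sr])
    return reads, truth, sr, ba
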