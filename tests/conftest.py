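import pytest

from longatac import simulate


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment shared by read-only tests.

    30 cells x 300 reads over two 2 Mb chromosomes, 60 peaks of which
    10% are allele-specific at skew 0.9.
    """
    cfg = simulate.SimConfig(
        seed=7,
        n_cells=30,
        reads_per_cell=300,
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        n_peaks=60,
        frac_asp=0.1,
        asp_skew=0.9,
    )
    fragments, variants, truth = simulate.simulate_experiment(cfg)
    return cfg, fragments, variants, truth
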