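import numpy as np
import pytest

from hepadim import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """One compact synthetic genome bundle shared by read-only tests."""
    models, table, peaks, seqs, truth = sim.simulate_genome_and_response(
        seed=11, n_chrom=2, genes_per_chrom=60, cluster_size=8,
        cluster_log2fc=-4.0, background_de_rate=0.1, dre_density=0.5,
    )
    return {
        "models": models, "table": table, "peaks": peaks,
        "seqs": seqs, "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
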