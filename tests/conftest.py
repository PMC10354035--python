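import numpy as np
import pytest
from hypothesis import settings

from snptrace import (
    GenotypeMatrix,
    SimulationConfig,
    filter_call_rate,
    simulate_frequencies,
    simulate_genotypes,
)
from snptrace.feature_select import select_snps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """4 samples, 2 breeds, 3 SNPs, one missing genotype."""
    from snptrace import MISSING

    return GenotypeMatrix(
        samples=["s1", "s2", "s3", "s4"],
        breeds=["alpha", "alpha", "beta", "beta"],
        snp_ids=["snpA", "snpB", "snpC"],
        dosages=np.array(
            [
                [0, 1, 2],
                [0, 1, MISSING],
                [2, 1, 0],
                [2, 0, 1],
            ]
        ),
    )


@pytest.fixture(scope="session")
def sim_study():
    """Default-scale simulated study: frequencies, planted SNPs, QC'd panel."""
    cfg = SimulationConfig(seed=1)
    freqs, planted = simulate_frequencies(cfg)
    G = filter_call_rate(simulate_genotypes(freqs, cfg), 0.99)
    return cfg, freqs, planted, G


@pytest.fixture(scope="session")
def sim_rankings(sim_study):
    """One importance ranking per method on the simulated panel."""
    _, _, _, G = sim_study
    return {m: select_snps(G, m, chunk_size=1000) for m in ("dnn", "garson", "olden")}
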