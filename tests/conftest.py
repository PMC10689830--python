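import numpy as np
import pytest

from qsipgrowth.simulate import SimConfig, default_taxa, simulate_gradient_dataset


@pytest.fixture(scope="session")
def one_group_dataset():
    """40-taxon, one-group simulated gradient dataset (true EAF ~ U[0, 0.5])."""
    rng = np.random.default_rng(42)
    taxa = {("early", "control"): default_taxa(40, rng)}
    return simulate_gradient_dataset(taxa, SimConfig(seed=7))


@pytest.fixture(scope="session")
def two_site_dataset():
    """Small 2x2 design (8 taxa per group) for pipeline-level tests."""
    rng = np.random.default_rng(5)
    taxa = {}
    for site in ("early", "late"):
        for treat in ("control", "warmed"):
            taxa[(site, treat)] = default_taxa(
                8, rng, prefix=f"{site[:1]}{treat[:1]}ASV")
    return simulate_gradient_dataset(taxa, SimConfig(seed=9),
                                     include_copies=False)
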