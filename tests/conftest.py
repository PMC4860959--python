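import numpy as np
import pytest

from nucdyad import SimulationSpec, simulate


def small_spec(seed: int, **overrides) -> SimulationSpec:
    """A reduced study: 200 genes on 2×300 kb contigs, 50k tags per track."""
    defaults = dict(seed=seed, n_genes=200, n_contigs=2, contig_length=300_000,
                    n_tags=50_000)
    defaults.update(overrides)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_small")
    return simulate(small_spec(seed=11), out)


@pytest.fixture(scope="session")
def full_truth(tmp_path_factory):
    """One default-condition study (2000 genes, 4×1.2 Mb, 100k tags/track)."""
    out = tmp_path_factory.mktemp("sim_full")
    return simulate(SimulationSpec(seed=5), out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
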