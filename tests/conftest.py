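import numpy as np
import pytest

from thermotraj import SimulationSpec, make_paper_design, simulate_dataset


@pytest.fixture(scope="session")
def paper_design():
    return make_paper_design()


@pytest.fixture(scope="session")
def pt_g9_design(paper_design):
    return [d for d in paper_design if d.history == "PT" and d.generation == "G9"]


@pytest.fixture(scope="session")
def small_dataset(paper_design):
    """50 genes on the full 24-sample design, default generator settings."""
    spec = SimulationSpec(n_genes=50, seed=12345)
    return simulate_dataset(spec, paper_design)
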