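import numpy as np
import pytest

import axichain as ax


@pytest.fixture(scope="session")
def cfg12():
    return ax.default_config()


@pytest.fixture(scope="session")
def cfg6():
    return ax.ModelConfig(n_cells=6)


@pytest.fixture(scope="session")
def cfg4():
    return ax.ModelConfig(n_cells=4)


def random_state(cfg, seed=0, b_low=0.3, b_high=1.5):
    """A generic non-degenerate state; b is kept away from the damping kink
    at 0 so finite-difference oracles stay valid."""
    rng = np.random.default_rng(seed)
    n = cfg.n_cells
    st = ax.init_state(cfg)
    st.s[:] = rng.uniform(-1, 1, n)
    st.p[:] = rng.uniform(-1, 1, n)
    st.js[:] = rng.uniform(-1, 1, n)
    st.b[:] = rng.uniform(b_low, b_high, n)
    st.jg[:] = rng.uniform(-1, 1, n - 1)
    st.r[:] = rng.uniform(-1, 1, (cfg.ic_nodes, n))
    st.y[:] = rng.uniform(-1, 1, (cfg.bc_nodes, n))
    return st


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def trained():
    """The packaged reference genome (trained by this package's own BPTT
    search on the 12-cell chain; provenance inside the JSON)."""
    from importlib.resources import files
    path = files("axichain").joinpath("data/trained_genome_12cell.json")
    params = ax.Parameters.from_json(str(path))
    return ax.AxialPatternResults.from_params(params, config=ax.default_config())
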