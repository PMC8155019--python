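import numpy as np
import pytest

import rnapburst as rb


@pytest.fixture(scope="session")
def default_model():
    return rb.build_model("base", rb.DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def default_moments(default_model):
    return rb.solve_moments(default_model, lags=np.arange(0.0, 31.0))


@pytest.fixture(scope="session")
def small_traces(default_model):
    """A small but realistic synthetic trace set shared across tests."""
    return rb.sample_traces(default_model, n_cells=10, duration=200.0, seed=123)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """One full-scale synthetic experiment (20 cells x 200 min)."""
    cfg = rb.ExperimentConfig(seed=2024)
    traces, truth = rb.make_traces(cfg)
    corr = rb.aggregate_normalize(traces, max_lag=30)
    counts = rb.make_mrna_counts(cfg)
    return cfg, traces, corr, counts
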