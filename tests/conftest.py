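import numpy as np
import pytest

from fatkin import (
    CohortTable,
    FatigueSeries,
    TraceConfig,
    exp_decay,
    generate_nm_trace,
    load_table1_fixture,
)


@pytest.fixture(scope="session")
def table1() -> CohortTable:
    """The packaged 13-subject published-parameter table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def nm_trace():
    """Default noiseless neuromuscular-test trace with its ground truth."""
    return generate_nm_trace(TraceConfig())


def make_series(A, tau, times=None, subject="01", condition="HF", variable="IMVC"):
    """Noiseless exponential series on the standard test schedule."""
    times = np.arange(0.0, 161.0, 20.0) if times is None else np.asarray(times, float)
    return FatigueSeries(subject, condition, variable, times, exp_decay(times, A, tau))


def grid_search_sse(times, values, a_grid, tau_grid):
    """Brute-force SSE minimum over an (A, tau) lattice.

    Independent oracle for the least-squares fit: evaluates the model on
    the full cartesian grid and returns (min SSE, A*, tau*).
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    E = np.exp(-times[None, :] / tau_grid[:, None])          # (n_tau, n_t)
    A = a_grid[:, None, None]                                 # (n_A, 1, 1)
    model = A + (100.0 - A) * E[None, :, :]                   # (n_A, n_tau, n_t)
    sse = ((model - values[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(sse[i, j]), float(a_grid[i]), float(tau_grid[j])
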