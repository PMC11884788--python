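import numpy as np
import pytest

from teflow import ConditionMeta, PairedDataset, TimeGrid, TraceMatrix


def trace(values, times=None, channel="cause", ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if times is None:
        times = np.arange(values.shape[1], dtype=float)
    grid = TimeGrid(np.asarray(times, dtype=float))
    if ids is None:
        ids = [f"c{i}" for i in range(values.shape[0])]
    return TraceMatrix(values, grid, channel, tuple(ids))


def paired_from_columns(result_t, result_tr, cause_tc, tc=5.0, t=10.0):
    """Embed three per-cell columns into a minimal PairedDataset whose
    grid is [0, tc, t] (uniform), for single-query TE tests."""
    a = np.asarray(result_t, dtype=float)
    b = np.asarray(result_tr, dtype=float)
    c = np.asarray(cause_tc, dtype=float)
    n = a.size
    times = [0.0, tc, t]
    pad = np.zeros(n)
    res = trace(np.column_stack([pad, b, a]), times, channel="result")
    cau = trace(np.column_stack([pad, c, pad]), times, channel="cause")
    return PairedDataset(cau, res, ConditionMeta(egf_dose=10.0))


def lagged_dataset(n_cells, n_times=16, coupling=0.0, seed=0, condition=None):
    """Paired traces where result(t) = coupling * cause(t-1) + noise.

    ``coupling=0`` gives fully independent channels; nonzero coupling is
    a one-step cause->result information flow with known Gaussian TE
    -0.5*ln(1 - rho^2), rho = coupling / sqrt(1 + coupling^2).
    """
    rng = np.random.default_rng(seed)
    cause = rng.standard_normal((n_cells, n_times))
    noise = rng.standard_normal((n_cells, n_times))
    result = noise.copy()
    result[:, 1:] += coupling * cause[:, :-1]
    times = np.arange(n_times, dtype=float) - 3.0  # 3 pre-stim frames
    cond = condition or ConditionMeta(egf_dose=10.0)
    return PairedDataset(
        trace(cause, times, "cause"), trace(result, times, "result"), cond
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_paired():
    return lagged_dataset(60, coupling=1.0, seed=7)
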