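import numpy as np
import pytest
from hypothesis import settings

from prc2mem import ModelParams, SimulationConfig, engine

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fitted():
    """The fitted parameter set used throughout the analysis."""
    return ModelParams()


@pytest.fixture(scope="session")
def oracle_params():
    """Small, fast-mixing system for exact-oracle comparisons: N = 4, no
    exchange, no replication dilution, rates scaled up so the chain mixes in
    minutes of simulated time."""
    return ModelParams(
        n_histones=4,
        t_cc=3.2e5,
        k_me=2e-3,
        f_min=2e-3,
        f_max=1e-2,
        p_dem=0.3,
        p_ex=0.0,
        replication_survival=1.0,
    )


@pytest.fixture()
def short_run(fitted):
    """A short recorded trajectory from the repressed start (warm kernel)."""
    config = SimulationConfig(
        variant="main", initial_state="uniform_me3",
        equilibration_cycles=0, total_cycles=2, seed=7,
    )
    return engine.run(config, fitted)


def make_trajectory(t, n23, n, t_cc, t_final, p_t=1.0):
    """Construct a synthetic counts-only Trajectory for metric tests; the
    me2/me3 count is placed entirely in the me3 column."""
    t = np.asarray(t, dtype=float)
    n23 = np.asarray(n23, dtype=np.int64)
    counts = np.zeros((t.size, 4), dtype=np.int64)
    counts[:, 3] = n23
    counts[:, 0] = n - n23
    k = t.size
    return engine.Trajectory(
        t=t,
        event=np.zeros(k, dtype=np.int8),
        counts=counts,
        tx_cum=np.zeros(k, dtype=np.int64),
        promoter=np.ones(k, dtype=np.int8),
        alpha=np.ones(k, dtype=np.float32),
        exch=np.zeros(k, dtype=np.int64),
        protein=np.zeros(k, dtype=np.int64),
        n=n,
        t_cc=t_cc,
        t_final=t_final,
        meta={"params": {"p_t": p_t}},
    )
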