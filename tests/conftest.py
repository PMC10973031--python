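import numpy as np
import pytest

import polarmix as pm

# problem sizes used throughout the suite: production physics runs use
# N=64 (grid spacing 0.78, resolving the interface profile scale 1.0), unit
# tests use small grids
ACCEPT_N = 64
ACCEPT_T_END = 60.0
ACCEPT_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def params():
    return pm.reference_params()


@pytest.fixture
def grid32(params):
    return pm.Grid(32, params.L)


def _run(kind, seed, K_p=1.0, T_end=ACCEPT_T_END):
    p = pm.reference_params(seed=seed, K_p=K_p)
    cfg = pm.SimulationConfig(
        params=p,
        N=ACCEPT_N,
        T_end=T_end,
        save_every=1.0,
        initial_condition=pm.InitialConditionSpec(kind=kind, seed=seed),
    )
    return pm.run_simulation(cfg)


@pytest.fixture(scope="session")
def mixed_runs():
    """Paper-default mixed-population runs, one per seed."""
    return {seed: _run("random_mixed", seed) for seed in ACCEPT_SEEDS}


@pytest.fixture(scope="session")
def segregated_runs():
    """Completely segregated two-stripe runs, one per seed."""
    return {seed: _run("segregated", seed) for seed in ACCEPT_SEEDS}


@pytest.fixture(scope="session")
def mixed_runs_low_kp():
    """Mixed runs with weak polarity alignment K_p = 2e-2."""
    return {seed: _run("random_mixed", seed, K_p=2.0e-2) for seed in ACCEPT_SEEDS}


@pytest.fixture(scope="session")
def short_mixed_traj():
    """Short mixed run used by consistency checks that need a converged flow."""
    return _run("random_mixed", seed=7, T_end=5.0)
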