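"""Shared fixtures: simulated ensembles reused across the test modules.

The heavier ensembles are session-scoped so that the acceptance tests and
the engine invariant tests share one simulation run per condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from glassyclutch import CellParams, simulate_ensemble

N_CELLS = 100          # replicates per headline condition
SEED_GLASSY_FAST = 101
SEED_GLASSY_SLOW = 102
SEED_CONST_FAST = 103
SEED_CONST_SLOW = 104


def _params(mode: str, tau_s: float) -> CellParams:
    return CellParams(off_time_mode=mode, tau_s=tau_s, dimensionality=1)


@pytest.fixture(scope="session")
def glassy_fast():
    """Glassy model (beta=1.5) on the fast-relaxing substrate, 100 cells."""
    return simulate_ensemble(_params("glassy", 10.0), N_CELLS, SEED_GLASSY_FAST)


@pytest.fixture(scope="session")
def glassy_slow():
    """Glassy model (beta=1.5) on the slow-relaxing substrate, 100 cells."""
    return simulate_ensemble(_params("glassy", 1000.0), N_CELLS, SEED_GLASSY_SLOW)


@pytest.fixture(scope="session")
def const_fast():
    """Constant-off-time (conventional) model, fast substrate, 100 cells."""
    return simulate_ensemble(_params("constant", 10.0), N_CELLS, SEED_CONST_FAST)


@pytest.fixture(scope="session")
def const_slow():
    """Constant-off-time (conventional) model, slow substrate, 100 cells."""
    return simulate_ensemble(_params("constant", 1000.0), N_CELLS, SEED_CONST_SLOW)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
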