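"""Shared fixtures: the demo model and seeded screening campaigns.

The campaigns are expensive (thousands of stiff ODE integrations), so
they are session-scoped and shared across test modules.  ``campaign``
is the screening-grade run (r = 50 repeats per direction over the nine
demo parameters); ``small_campaign`` is a fast variant for bookkeeping
and round-trip checks.
"""

import numpy as np
import pytest
from hypothesis import settings

from eescreen import AlivenessBounds, GridConfig, ProtocolConfig, run_campaign
from eescreen.demo_model import DemoModel, demo_parameter_set

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: the demo fixture's acceptance rate is low by design (survival bounds kill
#: most of parameter space), so campaign runs get an ample restart budget
RESTART_BUDGET = 5000


@pytest.fixture(scope="session")
def model():
    return DemoModel()


@pytest.fixture(scope="session")
def pset():
    return demo_parameter_set()


@pytest.fixture(scope="session")
def grid():
    return GridConfig(levels=11, delta=0.1)


@pytest.fixture(scope="session")
def bounds():
    return AlivenessBounds.default()


@pytest.fixture(scope="session")
def protocol():
    """Protocol settings for one-off steady/perturbed runs in tests."""
    return ProtocolConfig(repeats_per_direction=1, seed=0, max_restarts=RESTART_BUDGET)


@pytest.fixture(scope="session")
def small_campaign(model, pset, grid, bounds):
    cfg = ProtocolConfig(repeats_per_direction=5, seed=1234, max_restarts=RESTART_BUDGET)
    return run_campaign(model, pset, grid, cfg, bounds)


@pytest.fixture(scope="session")
def campaign(model, pset, grid, bounds):
    """The screening-grade demo campaign: k = 9, r = 50, fixed seed."""
    cfg = ProtocolConfig(repeats_per_direction=50, seed=20260922, max_restarts=RESTART_BUDGET)
    return run_campaign(model, pset, grid, cfg, bounds)
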