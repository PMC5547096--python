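"""Shared fixtures: seeded microscale ensembles reused across the suite.

The ensembles are the expensive inputs (compiled kernels, thousands of
Gillespie runs); computing them once per session keeps the suite fast while
every test still exercises the real engines.
"""

import pytest

from fibrolysis.distributions import build_pack
from fibrolysis.experiments import scenario_parameters
from fibrolysis.kinetics import KineticParameters
from fibrolysis.microscale import run_ensemble


@pytest.fixture(scope="session")
def baseline_fine():
    """Baseline ensemble on the fine (97.5 nm) fiber: (results, summary)."""
    params = KineticParameters()
    return run_ensemble(params, 97.5, 2000, 101)


@pytest.fixture(scope="session")
def baseline_fine_pack(baseline_fine):
    results, summary = baseline_fine
    return build_pack(results, summary, metadata={"scenario": "baseline-fine"})


@pytest.fixture(scope="session")
def baseline_coarse_pack():
    params = KineticParameters()
    results, summary = run_ensemble(params, 195.0, 2000, 202)
    return build_pack(results, summary, metadata={"scenario": "baseline-coarse"})


@pytest.fixture(scope="session")
def large_tpa_ensemble():
    """tPA rate constants two orders of magnitude above baseline."""
    params = scenario_parameters("large_tpa")
    return run_ensemble(params, 97.5, 2000, 303)
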