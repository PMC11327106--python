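"""Shared fixtures: the packaged desk-scale locus, one simulated cohort
under the default study conditions, and its full pipeline result.

Session-scoped because the cohort is deterministic (fixed seed) and
read-only across tests.
"""

import pytest

from igklocus.fixture import default_locus, tiny_locus
from igklocus.pipeline import run_pipeline
from igklocus.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def desk_locus():
    return default_locus()


@pytest.fixture(scope="session")
def desk_cohort(desk_locus):
    locus, ref = desk_locus
    return simulate_cohort(locus, ref, SimConfig(seed=1))


@pytest.fixture(scope="session")
def desk_result(desk_cohort):
    return run_pipeline(desk_cohort)


@pytest.fixture(scope="session")
def small_locus():
    return tiny_locus()
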