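"""Shared fixtures.

Cohort simulations are expensive, so every cohort used by the acceptance
suite is computed once per session (lazily) and shared across tests.
"""

from __future__ import annotations

import pytest

from habitloops import build_model, build_task, preset, run_cohort

COHORT_N = 20
COHORT_BASE_SEED = 100


class CohortCache:
    def __init__(self):
        self._cache = {}

    def get(self, preset_name: str):
        if preset_name not in self._cache:
            self._cache[preset_name] = run_cohort(
                preset(preset_name), COHORT_N, COHORT_BASE_SEED)
        return self._cache[preset_name]


@pytest.fixture(scope="session")
def cohorts() -> CohortCache:
    return CohortCache()


@pytest.fixture()
def task6():
    return build_task(1)


@pytest.fixture()
def control_model(task6):
    return build_model(task6, preset("control"), seed=1)
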