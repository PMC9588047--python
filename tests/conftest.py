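"""Shared simulation batches for the statistical test suites.

The condition-level batches are expensive (a second or two per trial),
so they are simulated once per session at reduced scale and shared by
all tests that need them.  Counts are chosen to keep the default test
run within a desk-time budget while leaving enough trials per condition
for stable mixture fits and sign tests.
"""

import numpy as np
import pytest

from dfvwm.analysis import fit_by_condition, run_simulated_participants

SEED = 20220901


def _pooled(variant, condition, counts, seed=SEED):
    runs = run_simulated_participants(
        variant, condition, n_runs=1, base_seed=seed, counts=counts,
        preset="fast")
    return runs[0]


@pytest.fixture(scope="session")
def m1_delay_results():
    return _pooled("m1", "delay",
                   {"SINGLE": 25, "UNIQUE": 25, "CW": 30, "CCW": 30})


@pytest.fixture(scope="session")
def m1_delay_fits(m1_delay_results):
    return fit_by_condition(m1_delay_results)


@pytest.fixture(scope="session")
def m2_delay_results():
    return _pooled("m2", "delay",
                   {"SINGLE": 20, "UNIQUE": 30, "CW": 30, "CCW": 30})


@pytest.fixture(scope="session")
def m2_delay_fits(m2_delay_results):
    return fit_by_condition(m2_delay_results)


@pytest.fixture(scope="session")
def m2_control_results():
    return _pooled("m2", "control",
                   {"SINGLE": 0, "UNIQUE": 20, "CW": 22, "CCW": 22})


@pytest.fixture(scope="session")
def m2_control_fits(m2_control_results):
    return fit_by_condition(m2_control_results)
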