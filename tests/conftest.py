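"""Shared fixtures: the built-in design and one simulated default cohort.

The cohort fixtures are session-scoped because simulating and analyzing the
full 18-participant, 11-trial dataset takes tens of seconds; tests share a
single deterministic realization (master seed 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import ccmotion as cm

MASTER_SEED = 1


@pytest.fixture(scope="session")
def design():
    return cm.builtin_design()


@pytest.fixture(scope="session")
def built_trials(design):
    """trial_id -> (Trajectory, annotations) for all 11 built-in trials."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")      # (0.25 Hz, 46.6 cm/s) workspace
        for spec in design:
            out[spec.trial_id] = cm.build_trial(spec, sample_rate=100.0)
    return out


@pytest.fixture(scope="session")
def cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cm.simulate_cohort(n_participants=18, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def cohort_analysis(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cm.analyze_cohort(cohort)
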