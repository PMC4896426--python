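"""Shared fixtures: the planted-structure cohort analyzed once per session."""

import numpy as np
import pytest

from dynfc import io as tsio
from dynfc.pipeline import RunConfig, RunResult, run_pipeline
from dynfc.simulate import SimSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort_spec() -> SimSpec:
    """Default planted cohort: 40 nodes, 3x12 stable hosts + 4-node flexible
    coalition, 1,200 frames at TR 0.72 s, within/between corr 0.5/0.05."""
    return SimSpec(seed=7)


@pytest.fixture(scope="session")
def cohort_config(cohort_spec) -> RunConfig:
    # step 6 frames and 20 community initializations per window keep the
    # twin-session analysis to a few seconds without changing the science
    return RunConfig(sim=cohort_spec, n_subjects=20, sessions=2,
                     step_frames=6, n_init=20, seed=13)


@pytest.fixture(scope="session")
def cohort_run(cohort_config) -> RunResult:
    """Full two-session pipeline on the planted cohort (computed once)."""
    return run_pipeline(cohort_config)


@pytest.fixture(scope="session")
def preprocessed_session1(cohort_spec):
    """Session-1 signals after frame discard and high-pass filtering."""
    raw = simulate_cohort(cohort_spec, 20, 1)[0]
    return tsio.highpass(tsio.discard_initial_frames(raw, 20), 0.008)


@pytest.fixture(scope="session")
def planted_flexible(cohort_spec):
    return {f"n{i:03d}" for i in cohort_spec.flexible_nodes}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
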