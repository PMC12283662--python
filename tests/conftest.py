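"""Shared fixtures: small, fast synthetic studies and trials."""

import numpy as np
import pytest

from strengthsense import SimConfig, assemble, simulate_study, simulate_trial


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study: 4 subjects x 5 trials at 1 kHz, 1.5 s trials."""
    return SimConfig(
        n_subjects=4,
        trials_per_subject=5,
        fs_emg=1000.0,
        trial_duration=1.5,
        n_unusable=2,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_table(small_study):
    return assemble(small_study)


@pytest.fixture()
def one_trial(small_cfg):
    rng = np.random.default_rng(1)
    return simulate_trial(4, 1.0, small_cfg, rng, subject_id="S01", trial_id="T01")
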